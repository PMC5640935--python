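"""Classify organ-site event timelines into first-metastasis patterns.

Builds a handful of patient timelines and prints the pattern each maps to.
A gap of at most 183 days (~6 months) between the first bone-category and
first visceral-category event makes the spread metasynchronous
("bone_and_visceral"); larger gaps give a single-site pattern with the
later site recorded separately.
"""

from organotrope import OrganEvent, PatternConfig, classify_first_pattern

timelines = {
    "metasynchronous": [OrganEvent("p1", "bone", 365), OrganEvent("p1", "liver", 485)],
    "visceral_then_late_bone": [OrganEvent("p2", "liver", 300),
                                OrganEvent("p2", "bone", 550)],
    "hypercalcaemia_counts_as_bone": [OrganEvent("p3", "hypercalcaemia", 150)],
    "never_metastasized": [],
    "boundary_183_days": [OrganEvent("p5", "bone", 100), OrganEvent("p5", "lung", 283)],
}

cfg = PatternConfig(window_days=183)
for name, events in timelines.items():
    label = classify_first_pattern(events, cfg)
    print(f"{name:32s} -> {label.pattern:18s} "
          f"t_first={label.t_first} t_other_site={label.t_other_site}")

print("\nEach line shows the assigned first-spread pattern, the day of first")
print("distant metastasis, and (for single-site patterns) the day the other")
print("organ category was reached when that fell outside the 6-month window.")
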