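"""Matched-pair odds ratios for module scores: the core inference step.

Simulates a cohort in which one module truly doubles both site hazards per
unit score, draws a metasynchronous (BV) case-control series, and fits
conditional (matched) and unconditional logistic models per module, with
BH adjustment across the panel.  A quartile analysis and a matched-pair
Wilcoxon test on the same scores are printed alongside.
"""

import numpy as np
import pandas as pd

from organotrope import (
    SimulationConfig,
    StudyConfig,
    quartile_or_analysis,
    run_full_study,
    wald_or_ci,
    weighted_sum_score,
    wilcoxon_signed_rank,
)

sim = SimulationConfig(n_patients=3000, seed=41)
cfg = StudyConfig(
    seed=41, simulation=sim, n_cases=150,
    modules=tuple(m.as_gene_module() for m in sim.modules),
)
report = run_full_study(cfg)

tab = report.or_tables[("BV", "conditional")]
print("BV series, conditional logistic (per unit scaled module score):")
print(tab[["OR", "CI_low", "CI_high", "p", "adj_p"]].round(3).to_string())

# quartile analysis and paired rank test for the causal module
from organotrope.simulate import generate_cohort
cohort, _, expr = generate_cohort(sim)
pairs = report.pairs["BV"]
scores = weighted_sum_score(expr, cfg.modules[0])
case_s = pd.Series([scores[p.case_id] for p in pairs])
ctrl_s = pd.Series([scores[p.control_id] for p in pairs])

quart = quartile_or_analysis(case_s, ctrl_s)
print("\nquartile ORs vs first quartile (control-series thresholds):")
print(wald_or_ci(quart.fit)[["OR", "CI_low", "CI_high"]].round(2).to_string())

w = wilcoxon_signed_rank((case_s - ctrl_s).to_numpy())
print(f"\nmatched-pair Wilcoxon on case-minus-control scores: "
      f"W={w.statistic:.0f}, p={w.p_value:.2e}")
print("\nThe proliferation-like module shows an elevated OR with a monotone")
print("quartile trend; the null module's interval covers 1.")
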