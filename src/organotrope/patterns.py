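"""Classification of organ-site metastasis timelines into first-spread patterns.

A patient's distant recurrences are reduced to two organ categories —
*bone* (bone, bone marrow, spinal cord compression, pathological fracture,
hypercalcaemia) and *visceral* (lung, liver, brain, ascites) — and the
timeline of first events per category is classified into one of four
mutually exclusive patterns:

* ``bone_only``       — first spread to bone, no visceral event within the window
* ``visceral_only``   — first spread to viscera, no bone event within the window
* ``bone_and_visceral`` — both categories reached within the metasynchronicity
  window (default 183 days ≈ 6 months) of each other
* ``none``            — no distant bone or visceral event

Sites outside the two categories are ignored and never influence the label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "BONE_SITES",
    "VISCERAL_SITES",
    "SITE_CATEGORY",
    "OrganEvent",
    "PatternConfig",
    "PatternLabel",
    "PATTERNS",
    "categorize_site",
    "classify_first_pattern",
]

BONE_SITES = frozenset(
    {
        "bone",
        "bone_marrow",
        "spinal_cord_compression",
        "pathological_fracture",
        "hypercalcaemia",
    }
)
VISCERAL_SITES = frozenset({"lung", "liver", "brain", "ascites"})
IGNORED_SITES = frozenset({"other"})

SITE_CATEGORY = {
    **{s: "bone" for s in BONE_SITES},
    **{s: "visceral" for s in VISCERAL_SITES},
    **{s: "ignored" for s in IGNORED_SITES},
}

PATTERNS = ("bone_only", "visceral_only", "bone_and_visceral", "none")

#: Days in the default metasynchronicity window ("6 months").
DEFAULT_WINDOW_DAYS = 183


@dataclass(frozen=True)
class OrganEvent:
    """A timestamped site-specific distant-metastasis record.

    ``t`` is measured in days since histological diagnosis and must be
    non-negative.
    """

    patient_id: str
    site: str
    t: float

    def __post_init__(self) -> None:
        if self.site not in SITE_CATEGORY:
            raise ValueError(f"unknown organ site code: {self.site!r}")
        if not (self.t >= 0):
            raise ValueError(f"event time must be >= 0, got {self.t!r}")


@dataclass(frozen=True)
class PatternConfig:
    """Metasynchronicity window configuration (boundary inclusive)."""

    window_days: int = DEFAULT_WINDOW_DAYS

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")


@dataclass(frozen=True)
class PatternLabel:
    """First-metastasis pattern with its anchor times.

    ``t_first`` is the day of first bone/visceral distant metastasis
    (``None`` iff ``pattern == 'none'``).  ``t_other_site`` is the day of
    the first event in the *other* category when that event falls beyond
    the window (only set for the single-site patterns).
    """

    pattern: str
    t_first: Optional[float] = None
    t_other_site: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern: {self.pattern!r}")
        if (self.pattern == "none") != (self.t_first is None):
            raise ValueError("t_first must be absent exactly when pattern is 'none'")


def categorize_site(site: str) -> str:
    """Map an organ-site code to its category: ``bone``, ``visceral`` or ``ignored``.

    Raises ``ValueError`` for codes outside the controlled vocabulary.
    """
    try:
        return SITE_CATEGORY[site]
    except KeyError:
        raise ValueError(f"unknown organ site code: {site!r}") from None


def classify_first_pattern(
    events: Iterable[OrganEvent], cfg: PatternConfig = PatternConfig()
) -> PatternLabel:
    """Classify one patient's event timeline into a first-metastasis pattern.

    Let ``t_b`` be the earliest bone-category event time and ``t_v`` the
    earliest visceral-category time (either may be absent).  The label is

    * ``bone_and_visceral`` iff both exist and ``|t_b - t_v| <= window_days``
      (boundary inclusive; simultaneous events are metasynchronous),
    * ``bone_only`` iff ``t_b`` exists and ``t_v`` is absent or lags by more
      than the window (and symmetrically for ``visceral_only``),
    * ``none`` iff neither category occurs.

    Events at ignored sites never influence the result.
    """
    events = list(events)
    pids = {e.patient_id for e in events}
    if len(pids) > 1:
        raise ValueError(f"events span multiple patients: {sorted(pids)}")

    t_b: Optional[float] = None
    t_v: Optional[float] = None
    for e in events:
        cat = categorize_site(e.site)
        if cat == "bone":
            t_b = e.t if t_b is None else min(t_b, e.t)
        elif cat == "visceral":
            t_v = e.t if t_v is None else min(t_v, e.t)

    w = cfg.window_days
    if t_b is None and t_v is None:
        return PatternLabel("none")
    if t_b is not None and t_v is not None:
        if abs(t_b - t_v) <= w:
            return PatternLabel("bone_and_visceral", t_first=min(t_b, t_v))
        if t_b < t_v:
            return PatternLabel("bone_only", t_first=t_b, t_other_site=t_v)
        return PatternLabel("visceral_only", t_first=t_v, t_other_site=t_b)
    if t_b is not None:
        return PatternLabel("bone_only", t_first=t_b)
    return PatternLabel("visceral_only", t_first=t_v)
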