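"""Incidence-density (risk-set) nested case-control sampling.

For each case with a distant-metastasis event at calendar time ``T``,
controls are drawn uniformly from the cohort members who are still under
follow-up and event-free at ``T``.  A patient sampled as a control at one
time may later become a case, and may serve as a control in several sets;
odds ratios estimated from such data by conditional logistic regression
approximate hazard (rate) ratios.

Conventions (half-open at-risk predicate):

* at risk at ``T`` requires ``diagnosis_date <= T``, ``exit_date > T`` and
  any metastasis event date strictly ``> T`` — a candidate whose own event
  falls on the case's event day is excluded;
* controls are drawn without replacement within a set, with replacement
  across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .patterns import PatternLabel

__all__ = [
    "CohortPatient",
    "CaseControlSet",
    "MatchedPair",
    "risk_set",
    "sample_case_controls",
    "build_case_control_series",
    "reduce_to_pairs",
]

logger = logging.getLogger(__name__)

#: Series labels for the three metastatic populations.
SERIES = ("V", "BV", "B")

_PATTERN_TO_SERIES = {"visceral_only": "V", "bone_and_visceral": "BV", "bone_only": "B"}
SERIES_TO_PATTERN = {v: k for k, v in _PATTERN_TO_SERIES.items()}


@dataclass
class CohortPatient:
    """A cohort member: calendar follow-up interval, pattern label, covariates."""

    patient_id: str
    diagnosis_date: int
    exit_date: int
    pattern: PatternLabel
    covariates: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exit_date < self.diagnosis_date:
            raise ValueError(
                f"{self.patient_id}: exit_date precedes diagnosis_date"
            )
        ev = self.event_date
        if ev is not None and ev > self.exit_date:
            raise ValueError(
                f"{self.patient_id}: event date {ev} after exit date {self.exit_date}"
            )

    @property
    def event_date(self) -> Optional[float]:
        """Calendar day of first distant metastasis, or None for pattern 'none'."""
        if self.pattern.pattern == "none":
            return None
        return self.diagnosis_date + self.pattern.t_first

    @property
    def series(self) -> Optional[str]:
        return _PATTERN_TO_SERIES.get(self.pattern.pattern)


@dataclass
class CaseControlSet:
    """One case, its index time T, and the controls drawn from the risk set."""

    case_id: str
    index_time_T: float
    control_ids: List[str]
    series: str
    deficit: int = 0  # requested m minus controls actually available

    def __post_init__(self) -> None:
        if self.case_id in self.control_ids:
            raise ValueError("case cannot be its own control")
        if len(set(self.control_ids)) != len(self.control_ids):
            raise ValueError("controls within a set must be distinct")


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    series: str
    index_time_T: float


def risk_set(
    cohort: Sequence[CohortPatient], T: float, exclude: Optional[str] = None
) -> List[str]:
    """Identifiers of cohort members at risk of distant metastasis at time ``T``.

    At risk means under follow-up (``diagnosis_date <= T < exit_date``) with
    no metastasis event on or before ``T``.  ``exclude`` (normally the case)
    is always omitted.  An empty result is a legal return.
    """
    out = []
    for p in cohort:
        if p.patient_id == exclude:
            continue
        if not (p.diagnosis_date <= T < p.exit_date):
            continue
        ev = p.event_date
        if ev is not None and ev <= T:
            continue
        out.append(p.patient_id)
    return out


def sample_case_controls(
    cohort: Sequence[CohortPatient],
    case: CohortPatient,
    m: int,
    rng: np.random.Generator,
) -> CaseControlSet:
    """Draw ``m`` controls for ``case`` from the risk set at its event date.

    Controls are sampled uniformly without replacement.  If fewer than ``m``
    candidates are at risk, all of them are returned and the deficit is
    flagged on the set; an empty risk set yields an unmatched (zero-control)
    set, also flagged.
    """
    if case.pattern.pattern == "none":
        raise ValueError(f"{case.patient_id} has no metastasis event; not a case")
    if m < 1:
        raise ValueError("m must be >= 1")
    T = case.event_date
    candidates = risk_set(cohort, T, exclude=case.patient_id)
    if len(candidates) <= m:
        chosen = list(candidates)
        if len(chosen) < m:
            logger.warning(
                "case %s at T=%s: risk set has %d < m=%d members",
                case.patient_id, T, len(chosen), m,
            )
    else:
        idx = rng.choice(len(candidates), size=m, replace=False)
        chosen = [candidates[i] for i in sorted(idx)]
    return CaseControlSet(
        case_id=case.patient_id,
        index_time_T=T,
        control_ids=chosen,
        series=case.series,
        deficit=m - len(chosen),
    )


def build_case_control_series(
    cohort: Sequence[CohortPatient],
    series: str,
    n_cases: int,
    m: int,
    rng: np.random.Generator,
) -> List[CaseControlSet]:
    """Build a case-control series for one metastatic population.

    A uniform random subset of ``n_cases`` cases with the series' pattern is
    selected and each matched by :func:`sample_case_controls`.  Deterministic
    under a fixed generator state.
    """
    if series not in SERIES_TO_PATTERN:
        raise ValueError(f"unknown series {series!r}; expected one of {SERIES}")
    pattern = SERIES_TO_PATTERN[series]
    eligible = [p for p in cohort if p.pattern.pattern == pattern]
    if not eligible:
        raise ValueError(f"no cases with pattern {pattern!r} in cohort")
    if n_cases < len(eligible):
        idx = rng.choice(len(eligible), size=n_cases, replace=False)
        selected = [eligible[i] for i in sorted(idx)]
    else:
        if n_cases > len(eligible):
            logger.warning(
                "series %s: requested %d cases but only %d eligible; using all",
                series, n_cases, len(eligible),
            )
        selected = list(eligible)
    return [sample_case_controls(cohort, c, m, rng) for c in selected]


def reduce_to_pairs(
    sets: Sequence[CaseControlSet], rng: np.random.Generator
) -> List[MatchedPair]:
    """Reduce 1:m case-control sets to 1:1 matched pairs.

    One control is chosen uniformly at random per set; sets with no control
    are dropped with a log entry.  Series label and index time are retained.
    """
    pairs: List[MatchedPair] = []
    for s in sets:
        if not s.control_ids:
            logger.warning("dropping unmatched case %s (no controls)", s.case_id)
            continue
        ctrl = s.control_ids[int(rng.integers(len(s.control_ids)))]
        pairs.append(MatchedPair(s.case_id, ctrl, s.series, s.index_time_T))
    return pairs
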