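"""Worked-example data: summary counts from the motivating clinical cohort.

These are published summary counts of a hospital-based breast-cancer cohort
(5061 patients accrued over three decades) and of the discovery-set
case-control series nested within it.  They let the contingency-table and
arithmetic machinery be exercised on real printed numbers without any
patient-level data.

``CASE_SERIES_TABLES`` holds cases-only r x 3 contingency tables (columns:
visceral-only, bone-and-visceral, bone-only case series) for the discovery
expression dataset; 'Unknown' rows are included as categories where the
source summary tabulates them (grade, HER2).
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

__all__ = [
    "COHORT_COUNTS",
    "PAIR_COUNTS",
    "CASE_SERIES_TABLES",
    "metastasis_proportions",
    "total_pairs",
]

#: Cohort-level event counts: patients, metastasizers, and the first-pattern split.
COHORT_COUNTS: Dict[str, int] = {
    "patients": 5061,
    "any_distant_metastasis": 1598,
    "bone_only": 413,
    "visceral_only": 747,
    "bone_and_visceral": 438,
}

#: 1:1 case-control pairs with extracted RNA, per series.
PAIR_COUNTS: Dict[str, int] = {"V": 246, "BV": 258, "B": 238}

#: Cases-only contingency tables for the discovery-set series (V, BV, B columns).
CASE_SERIES_TABLES: Dict[str, np.ndarray] = {
    "grade": np.array([
        [3, 3, 8],      # grade 1
        [27, 44, 44],   # grade 2
        [68, 55, 38],   # grade 3
        [7, 4, 8],      # unknown
    ]),
    "er_status": np.array([
        [57, 69, 77],   # positive
        [48, 37, 21],   # negative
    ]),
    "pr_status": np.array([
        [39, 53, 59],
        [66, 53, 39],
    ]),
    "her2_status": np.array([
        [31, 22, 15],   # positive
        [44, 51, 45],   # negative
        [30, 33, 38],   # unknown
    ]),
    "hormone_treatment": np.array([
        [84, 97, 92],   # yes
        [21, 9, 6],     # no
    ]),
    "radiotherapy": np.array([
        [79, 84, 82],   # yes
        [26, 22, 16],   # no
    ]),
}


def metastasis_proportions() -> Dict[str, float]:
    """Percentages (rounded as printed) derived from the cohort counts.

    ``any`` is a percentage of the whole cohort; the three pattern keys are
    percentages of the metastasising patients.
    """
    c = COHORT_COUNTS
    met = c["any_distant_metastasis"]
    return {
        "any": round(100.0 * met / c["patients"]),
        "bone_only": round(100.0 * c["bone_only"] / met),
        "visceral_only": round(100.0 * c["visceral_only"] / met),
        "bone_and_visceral": round(100.0 * c["bone_and_visceral"] / met),
    }


def total_pairs() -> int:
    """Total 1:1 pairs across the three series."""
    return sum(PAIR_COUNTS.values())
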