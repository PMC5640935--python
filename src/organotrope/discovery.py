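"""Derivation of a metasynchronous-spread gene module from matched-pair data.

The procedure mirrors how an organ-spread signature is extracted from a
case-control expression study of ER-positive disease:

1. reduce the matched pairs to those where case and control share the
   requested IHC-defined ER stratum (discordant or unknown pairs dropped);
2. per gene, an unpaired two-sided Mann-Whitney U test between the
   metasynchronous case group and a no-metastasis reference group;
3. Benjamini-Hochberg adjustment across all tested genes; genes below the
   FDR threshold (default 0.2) enter the module with weight +1 (up in
   cases) or -1 (down);
4. evaluation of the module's weighted-sum score by ROC/AUC, with
   resubstitution (same samples used for derivation) flagged as
   optimistically biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .riskset import MatchedPair
from .scoring import GeneModule, weighted_sum_score
from .stats import TestResult, bh_adjust, mann_whitney_u, roc_auc

__all__ = [
    "DiscoveryConfig",
    "DifferentialResult",
    "er_concordant_pairs",
    "per_gene_differential",
    "derive_module",
    "evaluate_module",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Knobs of the derivation: FDR threshold and the ER stratum analysed."""

    fdr_threshold: float = 0.2
    er_stratum: str = "positive"
    #: reference group: 'never_metastasizing' keeps only controls with no
    #: distant event during their whole follow-up; 'all_controls' keeps every
    #: ER-matched control.
    reference: str = "never_metastasizing"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.er_stratum not in ("positive", "negative"):
            raise ValueError("er_stratum must be 'positive' or 'negative'")
        if self.reference not in ("never_metastasizing", "all_controls"):
            raise ValueError("unknown reference group rule")


@dataclass
class DifferentialResult:
    """Per-gene rank-test outcome with its BH-adjusted p and direction."""

    gene: str
    u_statistic: float
    p_value: float
    adj_p: float
    direction: int  # +1 up in cases, -1 down


def er_concordant_pairs(
    pairs: Sequence[MatchedPair],
    er_status: Mapping[str, str],
    stratum: str = "positive",
) -> List[MatchedPair]:
    """Keep pairs whose case AND control both belong to the ER stratum.

    Pairs with a member of unknown ER status are dropped with a warning;
    zero surviving pairs is an error.
    """
    kept: List[MatchedPair] = []
    n_unknown = 0
    for p in pairs:
        ec = er_status.get(p.case_id)
        ek = er_status.get(p.control_id)
        if ec is None or ek is None:
            n_unknown += 1
            continue
        if ec == stratum and ek == stratum:
            kept.append(p)
    if n_unknown:
        logger.warning("%d pair(s) dropped for unknown ER status", n_unknown)
    if not kept:
        raise ValueError(f"no ER-concordant pairs in stratum {stratum!r}")
    return kept


def _mw_matrix(case: np.ndarray, ref: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised row-wise Mann-Whitney U (normal approximation, tie-corrected,
    continuity-corrected) for a genes x samples split.

    Matches :func:`organotrope.stats.mann_whitney_u` in its large-sample
    branch; used so that genome-scale scans stay fast.
    """
    n1 = case.shape[1]
    n2 = ref.shape[1]
    pooled = np.concatenate([case, ref], axis=1)
    ranks = rankdata(pooled, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    N = n1 + n2
    srt = np.sort(pooled, axis=1)
    # per-row tie correction sum(t^3 - t) via run lengths of equal values
    tie_sum = np.zeros(pooled.shape[0])
    boundaries = np.diff(srt, axis=1) != 0
    for i in range(pooled.shape[0]):
        idx = np.flatnonzero(boundaries[i])
        runs = np.diff(np.concatenate([[-1], idx, [N - 1]]))
        tie_sum[i] = float((runs.astype(float) ** 3 - runs).sum())
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_sum / (N * (N - 1)))
    mean_u = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
    p = np.where(var_u > 0, 2.0 * _norm.sf(np.abs(z)), 1.0)
    return u, np.minimum(p, 1.0)


def per_gene_differential(
    expr: pd.DataFrame,
    group_case: Sequence[str],
    group_ref: Sequence[str],
) -> List[DifferentialResult]:
    """Unpaired Mann-Whitney per gene between case and reference samples.

    Both groups need >= 3 samples.  Constant genes are skipped with a note.
    Direction is the sign of the case-minus-reference median difference
    (mean difference as tie-break).  Adjusted p-values are BH across all
    tested genes.
    """
    group_case = list(group_case)
    group_ref = list(group_ref)
    if len(group_case) < 3 or len(group_ref) < 3:
        raise ValueError("both groups need >= 3 samples")
    overlap = set(group_case) & set(group_ref)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)[:5]}")

    case = expr[group_case].to_numpy(dtype=float)
    ref = expr[group_ref].to_numpy(dtype=float)
    pooled_ptp = np.ptp(np.concatenate([case, ref], axis=1), axis=1)
    tested = np.flatnonzero(pooled_ptp > 0)
    skipped = expr.index[pooled_ptp == 0]
    if len(skipped):
        logger.info("%d constant gene(s) skipped", len(skipped))
    if tested.size == 0:
        raise ValueError("no non-constant genes to test")

    u, p = _mw_matrix(case[tested], ref[tested])
    adj = bh_adjust(p)
    med_diff = np.median(case[tested], axis=1) - np.median(ref[tested], axis=1)
    mean_diff = case[tested].mean(axis=1) - ref[tested].mean(axis=1)
    direction = np.sign(med_diff)
    direction = np.where(direction == 0, np.sign(mean_diff), direction)
    direction = np.where(direction == 0, 1, direction).astype(int)

    genes = expr.index[tested]
    return [
        DifferentialResult(str(g), float(u[i]), float(p[i]), float(adj[i]),
                           int(direction[i]))
        for i, g in enumerate(genes)
    ]


def derive_module(
    results: Sequence[DifferentialResult],
    cfg: DiscoveryConfig = DiscoveryConfig(),
    name: str = "BV",
) -> Optional[GeneModule]:
    """Select genes below the FDR threshold into a ±1-weighted module.

    Weight +1 for genes up in cases, -1 for down.  An empty selection is a
    legal outcome and returns ``None`` with a log entry.
    """
    if not results:
        raise ValueError("no differential results supplied")
    members = [
        (r.gene, r.direction) for r in results if r.adj_p < cfg.fdr_threshold
    ]
    if not members:
        logger.info("no gene passed FDR < %g; empty module", cfg.fdr_threshold)
        return None
    return GeneModule(name, members)


def evaluate_module(
    expr: pd.DataFrame,
    module: GeneModule,
    group_case: Sequence[str],
    group_ref: Sequence[str],
    resubstitution: bool = False,
) -> Dict[str, object]:
    """Score the module and evaluate case/reference discrimination by ROC.

    Returns the AUC, the ROC point list, per-group score summaries (for
    density plotting) and a ``resubstitution`` flag marking evaluations on
    the derivation samples as optimistically biased.
    """
    samples = list(group_case) + list(group_ref)
    scores = weighted_sum_score(expr[samples], module)
    labels = np.array([1] * len(group_case) + [0] * len(group_ref))
    curve, auc = roc_auc(scores.to_numpy(), labels)

    def _summ(v: pd.Series) -> Dict[str, float]:
        a = v.to_numpy(dtype=float)
        return {
            "n": int(a.size), "mean": float(a.mean()), "sd": float(a.std(ddof=1)),
            "median": float(np.median(a)),
            "q25": float(np.quantile(a, 0.25)), "q75": float(np.quantile(a, 0.75)),
        }

    return {
        "auc": auc,
        "roc": curve,
        "scores": scores,
        "case_summary": _summ(scores.iloc[: len(group_case)]),
        "ref_summary": _summ(scores.iloc[len(group_case):]),
        "resubstitution": bool(resubstitution),
    }
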