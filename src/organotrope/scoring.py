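"""Gene-module scoring, centroid subtyping and NanoString-style normalization.

Expression matrices are plain :class:`pandas.DataFrame` objects, genes (or
probes) as rows and samples as columns, values on a log scale.  A gene
module is a named list of ``(gene_id, weight)`` members with weights
restricted to ±1 — the direction of expression in the signature — and a
sample's module score is the directional sum of its member-gene values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GeneModule",
    "NanoStringRun",
    "resolve_module_probes",
    "weighted_sum_score",
    "scale_scores_95",
    "assign_nearest_centroid",
    "nanostring_normalize",
    "bv_nanostring_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModule:
    """A gene set with ±1 direction weights."""

    name: str
    members: Sequence[Tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"module {self.name!r}: members must be non-empty")
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            raise ValueError(f"module {self.name!r}: duplicate gene ids")
        if any(w not in (+1, -1) for _, w in self.members):
            raise ValueError(f"module {self.name!r}: weights must be +1 or -1")

    @property
    def genes(self) -> List[str]:
        return [g for g, _ in self.members]

    @property
    def weights(self) -> Dict[str, int]:
        return dict(self.members)


def resolve_module_probes(
    module: GeneModule,
    annotation: Mapping[str, str],
    expr: pd.DataFrame,
) -> GeneModule:
    """Map a gene-level module onto a probe-level expression matrix.

    For a gene measured by several probes, the probe with the largest
    sample standard deviation in ``expr`` is retained (most-variable-probe
    rule); ties are broken by lowest-lexicographic probe id and logged.
    Genes with no mappable probe are dropped and reported; a module with
    zero mappable genes is rejected.
    """
    gene_to_probes: Dict[str, List[str]] = {}
    for probe in expr.index:
        gene = annotation.get(probe)
        if gene is not None:
            gene_to_probes.setdefault(gene, []).append(probe)

    members: List[Tuple[str, int]] = []
    dropped: List[str] = []
    sds = expr.std(axis=1, ddof=1)
    for gene, w in module.members:
        probes = sorted(gene_to_probes.get(gene, []))
        if not probes:
            dropped.append(gene)
            continue
        probe_sd = sds.loc[probes]
        best = probe_sd.max()
        winners = sorted(probe_sd.index[probe_sd == best])
        if len(winners) > 1:
            logger.info(
                "module %s gene %s: SD tie among %s; keeping %s",
                module.name, gene, winners, winners[0],
            )
        members.append((winners[0], w))
    if dropped:
        logger.warning(
            "module %s: %d gene(s) with no probe dropped: %s",
            module.name, len(dropped), dropped,
        )
    if not members:
        raise ValueError(f"module {module.name!r}: no mappable genes in matrix")
    return GeneModule(module.name, members)


def weighted_sum_score(
    expr: pd.DataFrame, module: GeneModule
) -> pd.Series:
    """Per-sample module score: the ±1-weighted sum over present member genes.

    Missing member genes are skipped (their count is logged); if no member
    gene is present the module cannot be scored and a ``ValueError`` is
    raised.
    """
    present = [(g, w) for g, w in module.members if g in expr.index]
    if not present:
        raise ValueError(f"module {module.name!r}: no member gene present in matrix")
    n_missing = len(module.members) - len(present)
    if n_missing:
        logger.info("module %s: %d member gene(s) missing", module.name, n_missing)
    w = np.array([w for _, w in present], dtype=float)
    x = expr.loc[[g for g, _ in present]].to_numpy()
    return pd.Series(w @ x, index=expr.columns, name=module.name)


def scale_scores_95(
    scores: pd.Series, reference: Optional[pd.Series] = None
) -> pd.Series:
    """Affine-scale scores so ~95% of the reference lies within [-1, 1].

    With ``c`` the midpoint and ``h`` the half-width of the reference's
    central 95% interval (2.5th and 97.5th percentiles, linear-interpolation
    quantiles), the map ``x -> (x - c) / h`` is applied to ``scores``.  The
    reference defaults to the scores themselves, matching the convention of
    scaling within a case-control series.  Order-preserving, so rank
    statistics of the scores are unchanged.
    """
    ref = scores if reference is None else reference
    if len(ref) < 20:
        raise ValueError("reference needs >= 20 values to anchor 95% quantiles")
    q_lo, q_hi = np.quantile(np.asarray(ref, dtype=float), [0.025, 0.975])
    h = (q_hi - q_lo) / 2.0
    if h == 0:
        raise ValueError("constant reference: cannot scale (zero half-width)")
    c = (q_hi + q_lo) / 2.0
    return (scores - c) / h


def _spearman_to_centroids(sample: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Spearman correlation of one sample vector against each centroid column."""
    rs = rankdata(sample)
    rs = rs - rs.mean()
    out = np.empty(centroids.shape[1])
    for j in range(centroids.shape[1]):
        rc = rankdata(centroids[:, j])
        rc = rc - rc.mean()
        denom = np.sqrt((rs**2).sum() * (rc**2).sum())
        out[j] = (rs @ rc) / denom if denom > 0 else 0.0
    return out


def assign_nearest_centroid(
    expr: pd.DataFrame, centroids: pd.DataFrame, median_center: bool = True
) -> pd.DataFrame:
    """Nearest-centroid subtyping by Spearman correlation on median-centred data.

    ``centroids`` holds one column per subtype over a shared gene list.
    Genes are intersected with the matrix, rows median-centred across
    samples (``median_center=False`` skips this dataset-level preprocessing
    step), and each sample is assigned the subtype whose centroid has the
    highest rank correlation.  Returns a DataFrame indexed by sample with a
    ``subtype`` column and one correlation column per subtype.

    The Spearman assignment itself is a rank statistic: it is invariant to
    any strictly increasing transform of the (centred) sample values.
    """
    shared = [g for g in centroids.index if g in expr.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} gene(s) shared with centroids; need >= 3"
        )
    sub = expr.loc[shared]
    if median_center:
        sub = sub.sub(sub.median(axis=1), axis=0)
    cent = centroids.loc[shared].to_numpy()
    labels = []
    corrs = np.empty((sub.shape[1], centroids.shape[1]))
    for i, s in enumerate(sub.columns):
        r = _spearman_to_centroids(sub[s].to_numpy(), cent)
        corrs[i] = r
        labels.append(centroids.columns[int(np.argmax(r))])
    out = pd.DataFrame(corrs, index=sub.columns, columns=list(centroids.columns))
    out.insert(0, "subtype", labels)
    return out


@dataclass
class NanoStringRun:
    """Raw nCounter counts with probe classes.

    ``counts`` is probes × samples; ``probe_class`` labels each probe as
    ``endogenous``, ``negative`` (no-target background controls) or
    ``housekeeping``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probe_class.index):
            raise ValueError("counts and probe_class must share the probe index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        classes = set(self.probe_class)
        if not {"negative", "housekeeping"} <= classes:
            raise ValueError("need >= 1 negative and >= 1 housekeeping probe")


def nanostring_normalize(run: NanoStringRun) -> pd.DataFrame:
    """NanoString count normalization chain → log2 expression of endogenous probes.

    Per sample: (1) background ``b = mean(neg) + 2*sd(neg)`` is subtracted
    and counts floored at zero ('mean.2sd' rule); (2) counts are rescaled so
    every sample's housekeeping geometric mean equals the grand mean of
    those geometric means; (3) values are log2(count + 1) transformed;
    (4) each sample is centred by its mean log2 endogenous value — the
    log-domain equivalent of dividing by the sample geometric mean.

    Samples whose housekeeping geometric mean is zero after background
    subtraction are flagged and excluded.
    """
    neg = run.counts[run.probe_class == "negative"]
    hk_idx = run.probe_class.index[run.probe_class == "housekeeping"]
    endo_idx = run.probe_class.index[run.probe_class == "endogenous"]

    b = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1).fillna(0.0)
    corrected = (run.counts - b).clip(lower=0.0)

    hk = corrected.loc[hk_idx]
    # geometric mean over housekeeping probes, per sample
    with np.errstate(divide="ignore"):
        log_hk = np.log(hk.to_numpy())
    hk_geo = pd.Series(np.exp(log_hk.mean(axis=0)), index=corrected.columns)
    bad = hk_geo[(hk_geo == 0) | ~np.isfinite(hk_geo)].index
    if len(bad):
        logger.warning("excluding %d sample(s) with zero housekeeping geomean: %s",
                       len(bad), list(bad))
        corrected = corrected.drop(columns=bad)
        hk_geo = hk_geo.drop(bad)
    if corrected.shape[1] == 0:
        raise ValueError("no sample survived housekeeping normalization")

    grand = float(np.exp(np.log(hk_geo).mean()))
    factors = grand / hk_geo
    normalized = corrected.mul(factors, axis=1)

    logged = np.log2(normalized.loc[endo_idx] + 1.0)
    return logged.sub(logged.mean(axis=0), axis=1)


def bv_nanostring_score(
    expr: pd.DataFrame,
    module: GeneModule,
    er_mask: pd.Series,
) -> pd.Series:
    """Module score among ER-positive samples from standardised gene values.

    Each member gene is mean-centred and SD-scaled across the ER-positive
    samples, then combined by the module's ±1 weights.  Genes with zero SD
    in that stratum carry no information and are excluded with a warning.
    """
    er_samples = [s for s in expr.columns if bool(er_mask.get(s, False))]
    if len(er_samples) < 2:
        raise ValueError("need >= 2 ER-positive samples to standardise")
    sub = expr.loc[[g for g in module.genes if g in expr.index], er_samples]
    if sub.empty:
        raise ValueError(f"module {module.name!r}: no member gene present")
    sd = sub.std(axis=1, ddof=1)
    keep = sd[sd > 0].index
    dropped = [g for g in sub.index if g not in set(keep)]
    if dropped:
        logger.warning("module %s: zero-SD gene(s) excluded: %s", module.name, dropped)
    if len(keep) == 0:
        raise ValueError(f"module {module.name!r}: all member genes constant")
    z = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(sd.loc[keep], axis=0)
    w = pd.Series(module.weights).loc[keep].astype(float)
    return pd.Series(w.to_numpy() @ z.to_numpy(), index=er_samples, name=module.name)
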