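"""Self-contained statistical core for matched and unmatched case-control inference.

Everything here is implemented from first principles — the likelihoods, the
rank tests and their exact small-sample enumerations, the step-up false-
discovery adjustment and the ROC rank statistic — with SciPy used only for
distribution tails/quantiles and midranks:

* unconditional logistic regression by iteratively reweighted least squares
  (IRLS), with Wald odds ratios and confidence intervals;
* conditional logistic regression for matched sets (one case, >= 1 controls
  per stratum) by Newton-Raphson on the conditional likelihood
  ``prod_s exp(b'x_case) / sum_{j in s} exp(b'x_j)``;
* Pearson chi-square on r x c contingency tables (no continuity correction);
* Mann-Whitney U (midranks; exact enumeration for small untied samples,
  otherwise tie-corrected normal approximation with continuity correction);
* Wilcoxon signed-rank for matched pairs (zeros dropped, exact for n <= 25
  without ties);
* Benjamini-Hochberg step-up FDR adjustment;
* ROC curve and AUC via the rank formula (ties counted 1/2), so that
  ``AUC * n1 * n0`` equals the Mann-Whitney U of the positive class exactly;
* the quartile odds-ratio analysis (cases binned at control-series quartile
  thresholds, conditional fit of Q2-Q4 against Q1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata

__all__ = [
    "FitResult",
    "TestResult",
    "QuartileResult",
    "fit_logistic",
    "fit_conditional_logistic",
    "wald_or_ci",
    "pearson_chi_square",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "roc_auc",
    "quartile_or_analysis",
]

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_SCORE_TOL = 1e-8      # primary: maximal absolute score component
_LL_STAG = 1e-14       # stagnation guard on the relative log-likelihood change
_SEPARATION_BETA = 15.0  # |beta| on SD-standardised covariates flags separation


@dataclass
class FitResult:
    """Maximum-likelihood fit with Wald inference.

    ``converged=False`` marks estimates as non-reportable; ``separation``
    indicates complete or quasi-complete separation was detected.
    """

    names: List[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation: bool = False
    n_strata_informative: Optional[int] = None

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return wald_or_ci(self, level=level)


@dataclass
class TestResult:
    """A rank or chi-square test: statistic, p, direction and method note."""

    statistic: float
    p_value: float
    direction: int = 0  # sign of the x-minus-y (or observed) location shift
    method: str = ""
    degenerate: bool = False
    df: Optional[int] = None


@dataclass
class QuartileResult:
    """Quartile odds-ratio analysis against the first (reference) quartile."""

    thresholds: np.ndarray                  # 25/50/75th control percentiles
    fit: Optional[FitResult]
    estimable: Dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _as_design(X) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_separation(beta: np.ndarray, X: np.ndarray) -> bool:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # intercept / constant columns judged on raw scale
    return bool(np.any(np.abs(beta * sd) > _SEPARATION_BETA))


def fit_logistic(X, y, add_intercept: bool = True) -> FitResult:
    """Binary logistic regression by IRLS with Wald standard errors.

    Converges when the maximal absolute score falls below 1e-8 or the
    relative log-likelihood change falls below 1e-10; standard errors come
    from the inverse observed information.  Diverging coefficients
    (|beta| > 15 on SD-standardised covariates) flag separation and mark
    the fit non-converged; an exactly singular information matrix is
    rejected with the offending columns named.
    """
    Xm, names = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if not (set(np.unique(y)) <= {0.0, 1.0}):
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        Xm = np.column_stack([np.ones(y.size), Xm])
        names = ["intercept"] + names
        # a one-class outcome only degenerates when an intercept absorbs it
        # (the intercept-free paired-difference model has y identically 1)
        if len(set(np.unique(y))) < 2:
            raise ValueError("outcome has a single class; cannot fit")

    n, p = Xm.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    separation = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = Xm @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = Xm.T @ (y - mu)
        info = (Xm * w[:, None]).T @ Xm
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            bad = [names[i] for i in range(p)]
            raise ValueError(f"singular information matrix; columns: {bad}") from None
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        # recompute at the new beta for the convergence checks
        eta = Xm @ beta
        ll = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, -700, 700)))))
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = Xm.T @ (y - mu)
        if _check_separation(beta, Xm):
            separation = True
            break
        if np.max(np.abs(score)) < _SCORE_TOL or (
            np.isfinite(ll_old) and abs(ll - ll_old) <= _LL_STAG * (abs(ll_old) + 1.0)
        ):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    mu = 1.0 / (1.0 + np.exp(-(Xm @ beta)))
    w = mu * (1.0 - mu)
    info = (Xm * w[:, None]).T @ Xm
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    if separation:
        logger.warning("separation detected; estimates are non-reportable")
    return FitResult(names, beta, se, ll, it, converged and not separation,
                     separation=separation)


def fit_conditional_logistic(X, y, strata) -> FitResult:
    """Conditional logistic regression for matched sets (one case per stratum).

    Maximises ``sum_s [b'x_case - log sum_{j in s} exp(b'x_j)]`` by
    Newton-Raphson.  Strata with no within-stratum covariate variation
    contribute nothing to the likelihood and are counted as uninformative;
    if every stratum is uninformative the fit is rejected.  For 1:1 strata
    this likelihood coincides with an intercept-free logistic model on
    within-pair covariate differences.
    """
    Xm, names = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    strata = np.asarray(strata)
    if not (Xm.shape[0] == y.size == strata.size):
        raise ValueError("X, y and strata have incompatible shapes")

    groups: Dict[object, np.ndarray] = {}
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        ys = y[idx]
        if ys.sum() != 1 or idx.size < 2:
            raise ValueError(
                f"stratum {s!r} must contain exactly one case and >= 1 control"
            )
        groups[s] = idx
    informative = []
    for s, idx in groups.items():
        if np.any(np.ptp(Xm[idx], axis=0) > 0):
            informative.append(idx)
    if not informative:
        raise ValueError("all strata are uninformative (no covariate variation)")

    p = Xm.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    separation = False
    it = 0

    def _ll_grad_hess(b: np.ndarray):
        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        for idx in informative:
            Xs = Xm[idx]
            eta = Xs @ b
            eta -= eta.max()  # overflow guard; cancels in the ratio
            w = np.exp(eta)
            w /= w.sum()
            case = np.flatnonzero(y[idx] == 1)[0]
            ll += float(np.log(w[case]))
            xbar = w @ Xs
            g += Xs[case] - xbar
            H -= (Xs * w[:, None]).T @ Xs - np.outer(xbar, xbar)
        return ll, g, H

    for it in range(1, _MAX_ITER + 1):
        ll, g, H = _ll_grad_hess(beta)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            raise ValueError(f"singular information matrix; columns: {names}") from None
        beta = beta + step
        ll_new, g_new, _ = _ll_grad_hess(beta)
        if _check_separation(beta, Xm):
            separation = True
            break
        if np.max(np.abs(g_new)) < _SCORE_TOL or (
            np.isfinite(ll_old)
            and abs(ll_new - ll_old) <= _LL_STAG * (abs(ll_old) + 1.0)
        ):
            converged = True
            break
        ll_old = ll_new

    ll, g, H = _ll_grad_hess(beta)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    if separation:
        logger.warning("separation detected in conditional fit")
    return FitResult(
        names, beta, se, float(ll), it, converged and not separation,
        separation=separation, n_strata_informative=len(informative),
    )


def wald_or_ci(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios with Wald confidence limits, ``exp(beta ± z * SE)``."""
    if not fit.converged:
        logger.warning("wald_or_ci on a non-converged fit; estimates flagged")
    z = _norm.ppf(0.5 + level / 2.0)
    with np.errstate(over="ignore"):
        or_ = np.exp(fit.beta)
        lo = np.exp(fit.beta - z * fit.se)
        hi = np.exp(fit.beta + z * fit.se)
    wald_z = np.divide(fit.beta, fit.se, out=np.full_like(fit.beta, np.nan),
                       where=fit.se > 0)
    pvals = 2.0 * _norm.sf(np.abs(wald_z))
    return pd.DataFrame(
        {
            "beta": fit.beta, "se": fit.se, "OR": or_,
            "CI_low": lo, "CI_high": hi, "p": pvals,
            "converged": fit.converged,
        },
        index=fit.names,
    )


# ---------------------------------------------------------------------------
# contingency and rank tests
# ---------------------------------------------------------------------------

def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction.

    Empty rows/columns are dropped with a warning; df = (r-1)(c-1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping empty rows/columns from contingency table")
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table needs >= 2 non-empty rows and columns")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(_chi2.sf(stat, df))
    return TestResult(stat, p, method="pearson chi-square", df=df)


def _mw_exact_sf_table(n1: int, n2: int) -> np.ndarray:
    """Counts of rank-subsets of size n1 from 1..n1+n2 by rank-sum (DP)."""
    N = n1 + n2
    max_sum = N * (N + 1) // 2
    # f[k][s] = number of k-subsets of {1..N} with sum s
    f = np.zeros((n1 + 1, max_sum + 1))
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            f[k, r:] += f[k - 1, :-r] if r > 0 else f[k - 1]
    return f[n1]


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks).

    Exact by enumeration when ``n_x + n_y <= 12`` and there are no ties
    (two-sided p doubles the smaller tail, capped at 1); otherwise a normal
    approximation with tie-corrected variance and 0.5 continuity
    correction.  ``U`` is reported for the x side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2.0)

    if np.ptp(pooled) == 0:
        return TestResult(u, 1.0, 0, "mann-whitney (degenerate: all tied)",
                          degenerate=True)

    _, counts = np.unique(pooled, return_counts=True)
    has_ties = bool((counts > 1).any())
    direction = int(np.sign(np.median(x) - np.median(y))) or int(
        np.sign(np.mean(x) - np.mean(y))
    )

    if n1 + n2 <= 12 and not has_ties:
        dist = _mw_exact_sf_table(n1, n2)
        total = dist.sum()
        offset = n1 * (n1 + 1) // 2
        sums = np.arange(dist.size)
        us = sums - offset
        p_le = dist[us <= u].sum() / total
        p_ge = dist[us >= u].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u, float(p), direction, "mann-whitney (exact)")

    N = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:
        return TestResult(u, 1.0, 0, "mann-whitney (degenerate variance)",
                          degenerate=True)
    z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * _norm.sf(abs(z))))
    return TestResult(u, p, direction,
                      "mann-whitney (normal approx, tie-corrected, cc)")


def _signed_rank_exact_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for W+ by enumeration of the 2^n sign assignments (DP)."""
    total_sum = int(round(ranks.sum()))
    f = np.zeros(total_sum + 1)
    f[0] = 1.0
    for r in ranks:
        r = int(round(r))
        f[r:] += f[:-r] if r > 0 else f
    total = f.sum()
    sums = np.arange(f.size)
    p_le = f[sums <= w].sum() / total
    p_ge = f[sums >= w].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Exact for n <= 25 without ties in |d|,
    otherwise normal approximation with tie correction and 0.5 continuity
    correction.  Statistic ``W`` is the positive-rank sum.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon (degenerate: all zero)",
                          degenerate=True)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    direction = int(np.sign(np.median(d))) or int(np.sign(d.mean()))

    _, counts = np.unique(np.abs(d), return_counts=True)
    has_ties = bool((counts > 1).any())
    if n <= 25 and not has_ties:
        p = _signed_rank_exact_p(w_pos, ranks)
        return TestResult(w_pos, float(p), direction, "wilcoxon (exact)")

    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if var_w <= 0:
        return TestResult(w_pos, 1.0, 0, "wilcoxon (degenerate variance)",
                          degenerate=True)
    z = (w_pos - mean_w - 0.5 * np.sign(w_pos - mean_w)) / np.sqrt(var_w)
    p = float(min(1.0, 2.0 * _norm.sf(abs(z))))
    return TestResult(w_pos, p, direction,
                      "wilcoxon (normal approx, tie-corrected, cc)")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    ``p~_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def roc_auc(scores, labels) -> Tuple[pd.DataFrame, float]:
    """ROC curve and AUC via the rank formula (ties counted 1/2).

    Returns ``(curve, auc)`` where the curve lists (threshold, fpr, tpr)
    with thresholds descending.  ``auc * n_pos * n_neg`` equals the
    Mann-Whitney U statistic of the positive-class scores exactly.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    if not (set(np.unique(lab)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    n1 = int(lab.sum())
    n0 = lab.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    ranks = rankdata(s)
    u = ranks[lab == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    thresholds = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    thr = [np.inf]
    for t in thresholds:
        tpr.append(float((s[lab == 1] >= t).sum() / n1))
        fpr.append(float((s[lab == 0] >= t).sum() / n0))
        thr.append(float(t))
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, auc


# ---------------------------------------------------------------------------
# quartile analysis
# ---------------------------------------------------------------------------

def quartile_or_analysis(
    case_scores: pd.Series, control_scores: pd.Series
) -> QuartileResult:
    """Quartile odds ratios from 1:1 matched scores.

    ``case_scores`` and ``control_scores`` are aligned by pair (same index
    order = same pair).  Thresholds are the 25/50/75th percentiles of the
    *control* series; both members of every pair are binned at those
    thresholds, exposure is coded as indicators Q2, Q3, Q4 against the
    first quartile, and a conditional logistic model is fitted.  A quartile
    indicator with no discordant pair is non-estimable and dropped with a
    flag.
    """
    cs = np.asarray(case_scores, dtype=float)
    ks = np.asarray(control_scores, dtype=float)
    if cs.size != ks.size:
        raise ValueError("case and control score vectors must align by pair")
    if ks.size < 8:
        raise ValueError("need >= 8 controls to define quartile thresholds")
    thresholds = np.quantile(ks, [0.25, 0.5, 0.75])

    def _bin(v: np.ndarray) -> np.ndarray:
        return np.searchsorted(thresholds, v, side="right")  # 0..3

    qc = _bin(cs)
    qk = _bin(ks)
    n_pairs = cs.size
    names = ["Q2", "Q3", "Q4"]
    cols = {}
    estimable = {}
    for q, nm in zip((1, 2, 3), names):
        col = np.concatenate([(qc == q).astype(float), (qk == q).astype(float)])
        discordant = np.any((qc == q) != (qk == q))
        estimable[nm] = bool(discordant)
        if discordant:
            cols[nm] = col
        else:
            logger.warning("quartile %s has no discordant pair; OR non-estimable", nm)
    if not cols:
        return QuartileResult(thresholds, None, estimable)
    X = pd.DataFrame(cols)
    y = np.concatenate([np.ones(n_pairs), np.zeros(n_pairs)])
    strata = np.concatenate([np.arange(n_pairs), np.arange(n_pairs)])
    fit = fit_conditional_logistic(X, y, strata)
    return QuartileResult(thresholds, fit, estimable)
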