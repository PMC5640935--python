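"""Synthetic cohort and expression generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage — pattern classification, risk-set sampling,
module scoring, matched-set regression, signature discovery — can be tested
against a known truth without any external data:

* a calendar cohort: diagnosis dates uniform over a multi-decade accrual
  window, administrative end of study, and exponential drop-out;
* latent per-patient module scores ``s_j`` (standard normal, optionally
  correlated) and a Bernoulli oestrogen-receptor (ER) status;
* cause-specific first-metastasis times for bone and viscera from
  exponential hazards ``lambda_site = lambda0_site * exp(sum beta_site,k z_k)``;
  after the earlier event the other site's hazard is multiplied by a
  coupling factor ``rho`` (``rho > 1`` induces metasynchronous spread);
* a genes-by-samples log-expression matrix in which member genes of each
  module co-vary with its latent score
  (``x_g = direction_g * tau_j * s_j + noise``).

Classification of the simulated timelines is performed by
:mod:`organotrope.patterns`, never by the generator itself, so the
classifier is exercised end to end.  The :class:`TruthRecord` is consumed
only by tests and validation scripts, never by pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .patterns import (
    BONE_SITES,
    VISCERAL_SITES,
    OrganEvent,
    PatternConfig,
    classify_first_pattern,
)
from .riskset import CohortPatient
from .scoring import GeneModule

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "TruthRecord",
    "generate_covariates",
    "generate_expression",
    "simulate_event_times",
    "generate_cohort",
    "expand_to_probes",
]

_BONE_CODES = sorted(BONE_SITES)
_VISC_CODES = sorted(VISCERAL_SITES)


@dataclass(frozen=True)
class ModuleSpec:
    """A ground-truth gene module: members with ±1 directions and effect size.

    ``tau`` is the expression shift (log-expression units) per unit latent
    score for member genes; ``beta_bone``/``beta_visc`` are the per-unit log
    hazard ratios the latent score exerts on each site's metastasis hazard.
    """

    name: str
    members: Tuple[Tuple[str, int], ...]
    tau: float = 1.0
    beta_bone: float = 0.0
    beta_visc: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"module {self.name}: empty member list")
        seen: Dict[str, int] = {}
        for g, d in self.members:
            if d not in (+1, -1):
                raise ValueError(f"module {self.name}: weight for {g} must be ±1")
            if g in seen and seen[g] != d:
                raise ValueError(
                    f"module {self.name}: conflicting directions for gene {g}"
                )
            seen[g] = d

    def as_gene_module(self) -> GeneModule:
        return GeneModule(self.name, list(dict(self.members).items()))


def _default_modules() -> Tuple[ModuleSpec, ...]:
    # One proliferation-like module driving both sites (hazard ratio ~2 per
    # unit score, the magnitude regime the matched-set models are powered
    # for) plus a null module for calibration checks.
    prolif = tuple(
        (f"PRO{i:03d}", +1 if i < 16 else -1) for i in range(20)
    )
    null = tuple((f"NUL{i:03d}", +1) for i in range(10))
    return (
        ModuleSpec("proliferation", prolif, tau=1.0,
                   beta_bone=float(np.log(2.0)), beta_visc=float(np.log(2.0))),
        ModuleSpec("null_module", null, tau=1.0, beta_bone=0.0, beta_visc=0.0),
    )


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with cohort-realistic defaults.

    Defaults target the regime of the motivating clinical cohort: accrual
    over three decades, about two-thirds ER-positive disease, roughly a
    third of patients developing distant metastasis during follow-up, and a
    visceral-first rate about twice the bone-first rate, with hazard
    coupling strong enough that a quarter of metastasising patients spread
    to both organ categories within the six-month window.
    """

    n_patients: int = 2000
    accrual_start: int = 0
    accrual_end: int = 10957          # 30-year accrual window, in days
    admin_end: int = 14610            # administrative end of study (day index)
    n_genes: int = 500
    modules: Tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    noise_sd: float = 1.0             # per-gene residual SD, log-expression units
    er_positive_prob: float = 0.68
    lam0_bone: float = 3.9e-5         # baseline events/day
    lam0_visc: float = 5.8e-5
    er_beta_bone: float = 0.0         # optional ER shift on the bone hazard
    er_beta_visc: float = 0.0
    rho: float = 25.0                 # other-site hazard multiplier after first event
    dropout_rate: float = 1.0 / 5475  # censorings/day (mean 15 years)
    score_corr: Optional[np.ndarray] = None  # inter-module score correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.er_positive_prob <= 1:
            raise ValueError("er_positive_prob must be in [0, 1]")
        for r in (self.lam0_bone, self.lam0_visc, self.dropout_rate, self.rho):
            if r < 0:
                raise ValueError("rates and rho must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.accrual_end < self.accrual_start or self.admin_end < self.accrual_end:
            raise ValueError("require accrual_start <= accrual_end <= admin_end")
        member_genes = {g for m in self.modules for g, _ in m.members}
        if len(member_genes) > self.n_genes:
            raise ValueError("modules reference more genes than n_genes")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests; never read by the pipeline."""

    scores: pd.DataFrame                 # patients × modules latent scores
    latent_bone_time: np.ndarray         # uncensored first-bone times (days)
    latent_visc_time: np.ndarray
    censor_time: np.ndarray
    betas: Dict[str, Dict[str, float]]   # site -> {covariate: log hazard ratio}
    seed: int


def generate_covariates(
    cfg: SimulationConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ER status and latent module scores.

    Returns ``(covariates, scores)``; scores are standard normal per module,
    independent unless ``cfg.score_corr`` supplies a correlation matrix.
    """
    n = cfg.n_patients
    ids = [f"P{i:05d}" for i in range(n)]
    er = (rng.random(n) < cfg.er_positive_prob).astype(int)
    k = len(cfg.modules)
    z = rng.standard_normal((n, k))
    if cfg.score_corr is not None:
        corr = np.asarray(cfg.score_corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError("score_corr must be k×k for k modules")
        z = z @ np.linalg.cholesky(corr).T
    scores = pd.DataFrame(z, index=ids, columns=[m.name for m in cfg.modules])
    cov = pd.DataFrame({"ER": er}, index=ids)
    return cov, scores


def generate_expression(
    cfg: SimulationConfig, scores: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Genes × samples log-expression matrix tied to the latent scores.

    Member genes of module ``j`` receive ``direction * tau_j * s_j`` on top
    of N(0, sigma²) noise; genes belonging to several modules accumulate
    each contribution; all remaining genes are pure noise.
    """
    n = len(scores)
    member_genes: List[str] = []
    seen = set()
    for m in cfg.modules:
        for g, _ in m.members:
            if g not in seen:
                seen.add(g)
                member_genes.append(g)
    n_bg = cfg.n_genes - len(member_genes)
    genes = member_genes + [f"BG{i:05d}" for i in range(n_bg)]
    x = rng.standard_normal((cfg.n_genes, n)) * cfg.noise_sd
    gidx = {g: i for i, g in enumerate(genes)}
    for m in cfg.modules:
        s = scores[m.name].to_numpy()
        for g, d in m.members:
            x[gidx[g]] += d * m.tau * s
    return pd.DataFrame(x, index=genes, columns=scores.index)


def _linear_predictor(
    cfg: SimulationConfig, cov: pd.DataFrame, scores: pd.DataFrame, site: str
) -> np.ndarray:
    eta = np.zeros(len(cov))
    er_beta = cfg.er_beta_bone if site == "bone" else cfg.er_beta_visc
    eta += er_beta * cov["ER"].to_numpy()
    for m in cfg.modules:
        b = m.beta_bone if site == "bone" else m.beta_visc
        if b:
            eta += b * scores[m.name].to_numpy()
    return eta


def simulate_event_times(
    cfg: SimulationConfig,
    cov: pd.DataFrame,
    scores: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[Dict[str, List[OrganEvent]], np.ndarray, np.ndarray, TruthRecord]:
    """Draw per-patient organ-site event times, diagnosis dates and exits.

    First-bone and first-visceral times come from independent exponential
    cause-specific hazards; after the earlier of the two the other site's
    residual waiting time is redrawn with its hazard multiplied by
    ``cfg.rho`` (memorylessness makes this equivalent to a piecewise-
    constant coupled hazard).  Censoring is the minimum of an exponential
    drop-out draw and the administrative horizon; events after censoring
    are discarded.

    Returns ``(events_by_patient, diagnosis_dates, exit_dates, truth)``.
    """
    n = cfg.n_patients
    ids = list(cov.index)
    diag = rng.integers(cfg.accrual_start, cfg.accrual_end + 1, size=n)

    lam_b = cfg.lam0_bone * np.exp(_linear_predictor(cfg, cov, scores, "bone"))
    lam_v = cfg.lam0_visc * np.exp(_linear_predictor(cfg, cov, scores, "visc"))

    t_b = rng.exponential(1.0, n) / np.maximum(lam_b, 1e-300)
    t_v = rng.exponential(1.0, n) / np.maximum(lam_v, 1e-300)
    if cfg.rho != 1.0:
        # redraw the later site's residual time under the boosted hazard
        first_is_bone = t_b <= t_v
        resid = rng.exponential(1.0, n)
        t_v = np.where(
            first_is_bone, t_b + resid / np.maximum(cfg.rho * lam_v, 1e-300), t_v
        )
        t_b = np.where(
            ~first_is_bone, t_v + resid / np.maximum(cfg.rho * lam_b, 1e-300), t_b
        )

    admin_fu = (cfg.admin_end - diag).astype(float)
    if cfg.dropout_rate > 0:
        drop = rng.exponential(1.0 / cfg.dropout_rate, n)
    else:
        drop = np.full(n, np.inf)
    censor = np.minimum(drop, admin_fu)
    exit_dates = diag + np.ceil(censor).astype(int)

    events: Dict[str, List[OrganEvent]] = {}
    for i, pid in enumerate(ids):
        ev: List[OrganEvent] = []
        if t_b[i] <= censor[i]:
            site = _BONE_CODES[int(rng.integers(len(_BONE_CODES)))]
            ev.append(OrganEvent(pid, site, float(t_b[i])))
        if t_v[i] <= censor[i]:
            site = _VISC_CODES[int(rng.integers(len(_VISC_CODES)))]
            ev.append(OrganEvent(pid, site, float(t_v[i])))
        events[pid] = ev

    truth = TruthRecord(
        scores=scores,
        latent_bone_time=t_b,
        latent_visc_time=t_v,
        censor_time=censor,
        betas={
            "bone": {m.name: m.beta_bone for m in cfg.modules} | {"ER": cfg.er_beta_bone},
            "visc": {m.name: m.beta_visc for m in cfg.modules} | {"ER": cfg.er_beta_visc},
        },
        seed=cfg.seed,
    )
    return events, diag, exit_dates, truth


def generate_cohort(
    cfg: SimulationConfig,
    pattern_cfg: PatternConfig = PatternConfig(),
    with_expression: bool = True,
) -> Tuple[List[CohortPatient], TruthRecord, Optional[pd.DataFrame]]:
    """Generate a classified cohort, its ground truth and (optionally) expression.

    Pattern labels are assigned by :func:`classify_first_pattern` on the
    simulated event lists, so the classifier runs end to end on every
    generated cohort.
    """
    rng = cfg.rng()
    cov, scores = generate_covariates(cfg, rng)
    expr = generate_expression(cfg, scores, rng) if with_expression else None
    events, diag, exits, truth = simulate_event_times(cfg, cov, scores, rng)

    cohort: List[CohortPatient] = []
    for i, pid in enumerate(cov.index):
        label = classify_first_pattern(events[pid], pattern_cfg)
        exit_date = int(exits[i])
        if label.t_first is not None:
            # keep the recorded event inside the follow-up interval
            exit_date = max(exit_date, int(np.ceil(diag[i] + label.t_first)))
        cohort.append(
            CohortPatient(
                patient_id=pid,
                diagnosis_date=int(diag[i]),
                exit_date=exit_date,
                pattern=label,
                covariates={"ER": int(cov.loc[pid, "ER"])},
            )
        )
    return cohort, truth, expr


def expand_to_probes(
    expr: pd.DataFrame,
    rng: np.random.Generator,
    max_probes: int = 3,
    extra_sd: float = 0.5,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Duplicate genes into 1..max_probes probes with differing noise.

    Emulates a probe-level array where several probes map to one gene with
    unequal measurement quality.  Returns the probe-level matrix and the
    probe → gene annotation map.
    """
    rows = []
    index = []
    ann: Dict[str, str] = {}
    for g in expr.index:
        k = int(rng.integers(1, max_probes + 1))
        for j in range(1, k + 1):
            pid = f"{g}_p{j}"
            sd = extra_sd * j  # later probes are noisier
            rows.append(expr.loc[g].to_numpy() + rng.standard_normal(expr.shape[1]) * sd)
            index.append(pid)
            ann[pid] = g
    return pd.DataFrame(rows, index=index, columns=expr.columns), ann
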