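"""End-to-end study orchestration.

``run_full_study`` ties the stages together: simulate (or load) a cohort →
classify first-metastasis patterns → draw incidence-density case-control
series → score gene modules and scale scores within each series → fit
conditional (matched pairs) and unconditional logistic models per module →
BH-adjust p-values across the module panel within each series × model
family → optional signature discovery on the metasynchronous series.

Ground-truth records from the simulator are never consumed here; they exist
only for tests and validation scripts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .discovery import (
    DiscoveryConfig,
    derive_module,
    er_concordant_pairs,
    evaluate_module,
    per_gene_differential,
)
from .riskset import (
    CohortPatient,
    MatchedPair,
    build_case_control_series,
    reduce_to_pairs,
)
from .scoring import GeneModule, scale_scores_95, weighted_sum_score
from .simulate import SimulationConfig, generate_cohort
from .stats import (
    bh_adjust,
    fit_conditional_logistic,
    fit_logistic,
    pearson_chi_square,
    wald_or_ci,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_full_study",
    "series_module_or",
    "subtype_or_table",
    "pattern_subtype_crosstab",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """One end-to-end run: data source, sampling design, module panel."""

    seed: int
    simulation: Optional[SimulationConfig] = None
    cohort: Optional[Sequence[CohortPatient]] = None
    expression: Optional[pd.DataFrame] = None
    series: Tuple[str, ...] = ("V", "BV", "B")
    n_cases: int = 400
    m_controls: int = 3
    modules: Tuple[GeneModule, ...] = ()
    run_discovery: bool = False
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_data = self.cohort is not None
        if has_sim == has_data:
            raise ValueError("exactly one of simulation / cohort inputs required")

    def config_hash(self) -> str:
        payload = repr(
            (self.seed, self.series, self.n_cases, self.m_controls,
             tuple(m.name for m in self.modules), self.run_discovery,
             self.discovery, self.simulation)
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class StudyReport:
    """All study outputs plus a provenance block."""

    or_tables: Dict[Tuple[str, str], pd.DataFrame]   # (series, family) -> table
    pairs: Dict[str, List[MatchedPair]]
    stage_counts: Dict[str, int]
    discovery: Optional[Dict[str, object]]
    provenance: Dict[str, object]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for (series, family), tab in self.or_tables.items():
            tab.to_csv(out / f"or_{series}_{family}.csv")
        for series, pairs in self.pairs.items():
            pd.DataFrame(
                [{"case_id": p.case_id, "control_id": p.control_id,
                  "series": p.series, "index_time_T": p.index_time_T}
                 for p in pairs]
            ).to_csv(out / f"pairs_{series}.csv", index=False)
        meta = {"provenance": self.provenance, "stage_counts": self.stage_counts}
        if self.discovery is not None:
            meta["discovery"] = {
                "module_size": self.discovery["module_size"],
                "auc": self.discovery["auc"],
                "resubstitution": self.discovery["resubstitution"],
            }
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=str))


def series_module_or(
    expr: pd.DataFrame,
    pairs: Sequence[MatchedPair],
    modules: Sequence[GeneModule],
) -> Dict[str, pd.DataFrame]:
    """Per-module odds ratios for one case-control series, both model families.

    Module scores are computed on the whole matrix, scaled within the
    series (cases + controls of these pairs) so ~95% of values lie in
    [-1, 1], then fitted per unit scaled score by conditional (matched
    pairs) and unconditional logistic regression.  BH adjustment runs
    across the module panel within each family.
    """
    case_ids = [p.case_id for p in pairs]
    ctrl_ids = [p.control_id for p in pairs]
    rows_cond, rows_unc = [], []
    for mod in modules:
        scores = weighted_sum_score(expr, mod)
        series_vals = scores.loc[case_ids + ctrl_ids]
        scaled = scale_scores_95(series_vals)
        x_case = scaled.iloc[: len(case_ids)].to_numpy()
        x_ctrl = scaled.iloc[len(case_ids):].to_numpy()
        x = np.concatenate([x_case, x_ctrl])
        y = np.concatenate([np.ones(len(case_ids)), np.zeros(len(ctrl_ids))])
        strata = np.concatenate([np.arange(len(pairs)), np.arange(len(pairs))])

        fit_c = fit_conditional_logistic(x[:, None], y, strata)
        sc = wald_or_ci(fit_c).iloc[0]
        rows_cond.append({"module": mod.name, **sc.to_dict()})

        fit_u = fit_logistic(x[:, None], y)
        su = wald_or_ci(fit_u).loc["x0"]
        rows_unc.append({"module": mod.name, **su.to_dict()})

    out = {}
    for family, rows in (("conditional", rows_cond), ("unconditional", rows_unc)):
        tab = pd.DataFrame(rows).set_index("module")
        tab["adj_p"] = bh_adjust(tab["p"].to_numpy())
        out[family] = tab
    return out


def subtype_or_table(
    labels: Mapping[str, str],
    pairs: Sequence[MatchedPair],
    baseline: str,
) -> Dict[str, pd.DataFrame]:
    """Dummy-coded subtype odds ratios against a declared baseline level.

    Returns conditional and unconditional fit tables; the baseline's OR is
    1 by construction and is not a row.
    """
    case_ids = [p.case_id for p in pairs]
    ctrl_ids = [p.control_id for p in pairs]
    ids = case_ids + ctrl_ids
    levels = sorted({labels[i] for i in ids if i in labels})
    if baseline not in levels:
        raise ValueError(f"baseline level {baseline!r} absent from labels")
    others = [l for l in levels if l != baseline]
    X = pd.DataFrame(
        {l: [1.0 if labels[i] == l else 0.0 for i in ids] for l in others}
    )
    y = np.concatenate([np.ones(len(case_ids)), np.zeros(len(ctrl_ids))])
    strata = np.concatenate([np.arange(len(pairs)), np.arange(len(pairs))])
    out = {}
    out["conditional"] = wald_or_ci(fit_conditional_logistic(X, y, strata))
    out["unconditional"] = wald_or_ci(fit_logistic(X, y)).drop(index="intercept")
    return out


def pattern_subtype_crosstab(
    cohort: Sequence[CohortPatient], labels: Mapping[str, str]
) -> Dict[str, object]:
    """Pattern × subtype contingency: counts, row/column proportions, chi-square."""
    rows = [
        {"pattern": p.pattern.pattern, "subtype": labels[p.patient_id]}
        for p in cohort
        if p.patient_id in labels
    ]
    df = pd.DataFrame(rows)
    counts = pd.crosstab(df["pattern"], df["subtype"])
    test = pearson_chi_square(counts.to_numpy())
    return {
        "counts": counts,
        "row_prop": counts.div(counts.sum(axis=1), axis=0),
        "col_prop": counts.div(counts.sum(axis=0), axis=1),
        "chi2": test,
    }


def run_full_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full study pipeline deterministically under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    counts: Dict[str, int] = {}

    if cfg.simulation is not None:
        cohort, _truth, expr = generate_cohort(cfg.simulation)
    else:
        cohort, expr = list(cfg.cohort), cfg.expression
    if expr is None:
        raise ValueError("an expression matrix is required to score modules")
    counts["patients"] = len(cohort)
    counts["cases_total"] = sum(1 for p in cohort if p.pattern.pattern != "none")

    or_tables: Dict[Tuple[str, str], pd.DataFrame] = {}
    pairs_by_series: Dict[str, List[MatchedPair]] = {}
    for series in cfg.series:
        sets = build_case_control_series(
            cohort, series, cfg.n_cases, cfg.m_controls, rng
        )
        pairs = reduce_to_pairs(sets, rng)
        pairs_by_series[series] = pairs
        counts[f"sets_{series}"] = len(sets)
        counts[f"pairs_{series}"] = len(pairs)
        if cfg.modules:
            for family, tab in series_module_or(expr, pairs, cfg.modules).items():
                or_tables[(series, family)] = tab

    discovery_out: Optional[Dict[str, object]] = None
    if cfg.run_discovery:
        er_status = {
            p.patient_id: ("positive" if p.covariates.get("ER") else "negative")
            for p in cohort
        }
        bv_pairs = er_concordant_pairs(
            pairs_by_series["BV"], er_status, cfg.discovery.er_stratum
        )
        counts["discovery_pairs"] = len(bv_pairs)
        by_id = {p.patient_id: p for p in cohort}
        case_ids = [p.case_id for p in bv_pairs]
        if cfg.discovery.reference == "never_metastasizing":
            ref_ids = sorted(
                {p.control_id for p in bv_pairs
                 if by_id[p.control_id].pattern.pattern == "none"}
            )
        else:
            ref_ids = sorted({p.control_id for p in bv_pairs})
        ref_ids = [r for r in ref_ids if r not in set(case_ids)]
        results = per_gene_differential(expr, case_ids, ref_ids)
        module = derive_module(results, cfg.discovery)
        discovery_out = {
            "results": results,
            "module": module,
            "module_size": 0 if module is None else len(module.members),
        }
        if module is not None:
            ev = evaluate_module(expr, module, case_ids, ref_ids,
                                 resubstitution=True)
            discovery_out.update(
                {"auc": ev["auc"], "resubstitution": ev["resubstitution"]}
            )
        else:
            discovery_out.update({"auc": None, "resubstitution": True})

    provenance = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
    }
    return StudyReport(or_tables, pairs_by_series, counts, discovery_out, provenance)
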