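"""File I/O for the pipeline's plain-text formats.

* expression matrices: TSV, first column the gene/probe id, header row the
  sample ids;
* gene modules: GMT with a direction-suffix dialect — each gene token may
  carry ``|+`` or ``|-`` (no suffix means +1), e.g. ``AURKA|+  BTG2|-``;
* cohorts and organ events: CSV;
* centroid sets: TSV, genes as rows, one column per subtype;
* NanoString runs: CSV with a ``probe_class`` column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import pandas as pd
import yaml

from .patterns import OrganEvent, PatternLabel
from .riskset import CaseControlSet, CohortPatient, MatchedPair
from .scoring import GeneModule, NanoStringRun

__all__ = [
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "read_events", "write_events",
    "read_cohort", "write_cohort",
    "read_centroids",
    "read_nanostring",
    "write_pairs", "read_pairs",
    "write_sets",
    "load_simulation_config",
]

PathLike = Union[str, Path]

_COVARIATE_PREFIX = "cov_"


def load_simulation_config(path: PathLike):
    """Build a :class:`~organotrope.simulate.SimulationConfig` from YAML.

    Scalar fields map directly; ``modules`` entries are mappings with
    ``name``, ``tau``, ``beta_bone``, ``beta_visc`` and a ``members`` list
    of ``[gene, weight]`` pairs.
    """
    from .simulate import ModuleSpec, SimulationConfig

    raw = yaml.safe_load(Path(path).read_text())
    if "modules" in raw:
        raw["modules"] = tuple(
            ModuleSpec(
                name=m["name"],
                members=tuple((g, int(w)) for g, w in m["members"]),
                tau=float(m.get("tau", 1.0)),
                beta_bone=float(m.get("beta_bone", 0.0)),
                beta_visc=float(m.get("beta_visc", 0.0)),
            )
            for m in raw["modules"]
        )
    return SimulationConfig(**raw)


def read_expression(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t")


def read_gmt(path: PathLike) -> List[GeneModule]:
    """Parse GMT lines ``name <tab> description <tab> gene[|+/-] ...``."""
    modules: List[GeneModule] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name = parts[0]
        members: List[Tuple[str, int]] = []
        for tok in parts[2:]:
            if not tok:
                continue
            if tok.endswith("|+"):
                members.append((tok[:-2], +1))
            elif tok.endswith("|-"):
                members.append((tok[:-2], -1))
            else:
                members.append((tok, +1))
        modules.append(GeneModule(name, members))
    return modules


def write_gmt(modules: Sequence[GeneModule], path: PathLike) -> None:
    lines = []
    for m in modules:
        toks = [f"{g}|{'+' if w > 0 else '-'}" for g, w in m.members]
        lines.append("\t".join([m.name, "organotrope"] + toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path: PathLike) -> Dict[str, List[OrganEvent]]:
    """Event CSV with columns patient_id, site, days_since_diagnosis."""
    df = pd.read_csv(path)
    out: Dict[str, List[OrganEvent]] = {}
    for row in df.itertuples(index=False):
        ev = OrganEvent(str(row.patient_id), str(row.site),
                        float(row.days_since_diagnosis))
        out.setdefault(ev.patient_id, []).append(ev)
    return out


def write_events(events: Dict[str, List[OrganEvent]], path: PathLike) -> None:
    rows = [
        {"patient_id": e.patient_id, "site": e.site, "days_since_diagnosis": e.t}
        for evs in events.values()
        for e in evs
    ]
    pd.DataFrame(rows, columns=["patient_id", "site", "days_since_diagnosis"]).to_csv(
        path, index=False
    )


def write_cohort(cohort: Sequence[CohortPatient], path: PathLike) -> None:
    rows = []
    for p in cohort:
        row = {
            "patient_id": p.patient_id,
            "diagnosis_date": p.diagnosis_date,
            "exit_date": p.exit_date,
            "pattern": p.pattern.pattern,
            "t_first": p.pattern.t_first,
            "t_other_site": p.pattern.t_other_site,
        }
        for k, v in p.covariates.items():
            row[_COVARIATE_PREFIX + k] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: PathLike) -> List[CohortPatient]:
    df = pd.read_csv(path)
    cov_cols = [c for c in df.columns if c.startswith(_COVARIATE_PREFIX)]
    cohort = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        t_first = d.get("t_first")
        t_other = d.get("t_other_site")
        label = PatternLabel(
            d["pattern"],
            None if pd.isna(t_first) else float(t_first),
            None if pd.isna(t_other) else float(t_other),
        )
        cov = {c[len(_COVARIATE_PREFIX):]: d[c] for c in cov_cols}
        cohort.append(
            CohortPatient(str(d["patient_id"]), int(d["diagnosis_date"]),
                          int(d["exit_date"]), label, cov)
        )
    return cohort


def read_centroids(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_nanostring(path: PathLike) -> NanoStringRun:
    """CSV: first column probe id, a ``probe_class`` column, then counts."""
    df = pd.read_csv(path, index_col=0)
    if "probe_class" not in df.columns:
        raise ValueError("NanoString CSV needs a 'probe_class' column")
    probe_class = df["probe_class"].astype(str)
    counts = df.drop(columns=["probe_class"]).astype(float)
    return NanoStringRun(counts, probe_class)


def write_sets(sets: Sequence[CaseControlSet], path: PathLike) -> None:
    rows = [
        {
            "case_id": s.case_id, "index_time_T": s.index_time_T,
            "series": s.series, "control_ids": ";".join(s.control_ids),
            "deficit": s.deficit,
        }
        for s in sets
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pairs(pairs: Sequence[MatchedPair], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"case_id": p.case_id, "control_id": p.control_id,
             "series": p.series, "index_time_T": p.index_time_T}
            for p in pairs
        ]
    ).to_csv(path, index=False)


def read_pairs(path: PathLike) -> List[MatchedPair]:
    df = pd.read_csv(path)
    return [
        MatchedPair(str(r.case_id), str(r.control_id), str(r.series),
                    float(r.index_time_T))
        for r in df.itertuples(index=False)
    ]
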