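"""Longitudinal cohort containers and delimited-text / JSON I/O.

Canonical layout is long format, one row per visit, with header
``patient_id,subtype,age_onset,time_months,edss[,bv]``.  Times are months
from disease onset (onset = month 0); EDSS lives on the half-point grid
{0, 0.5, ..., 10}; brain volume (BV) is an optional positive normalized
volume.  Excel workbooks with the same columns are accepted for
supplementary-style files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Visit",
    "PatientRecord",
    "Cohort",
    "ValidationIssue",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "write_results",
]

SUBTYPES = ("RRMS", "SPMS", "PPMS", "unknown")

_REQUIRED = ("patient_id", "time_months", "edss")

#: Default tolerant column mapping; keys are canonical names, values are
#: accepted aliases (case-insensitive, matched after stripping spaces/_).
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "patient_id": ("patient_id", "patient", "id", "subject", "subjectid", "pid"),
    "subtype": ("subtype", "mstype", "type", "course", "phenotype"),
    "age_onset": ("age_onset", "ageatonset", "onsetage", "age"),
    "time_months": ("time_months", "time", "month", "months", "visitmonth", "t"),
    "edss": ("edss", "edssscore", "score"),
    "bv": ("bv", "brainvolume", "normalizedbv", "nbv", "volume"),
}


@dataclass(frozen=True)
class Visit:
    time: float  # months from onset
    edss: float  # 0..10 in 0.5 steps
    bv: float | None = None  # normalized brain volume, > 0


@dataclass
class PatientRecord:
    patient_id: str
    visits: list[Visit]
    subtype: str = "unknown"
    age_onset: float | None = None

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"patient {self.patient_id}: at least 1 visit required")
        times = [v.time for v in self.visits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"patient {self.patient_id}: visit times must be strictly increasing"
            )
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")

    @property
    def times(self) -> np.ndarray:
        return np.array([v.time for v in self.visits])

    @property
    def edss(self) -> np.ndarray:
        return np.array([v.edss for v in self.visits])

    @property
    def bv(self) -> np.ndarray:
        """BV per visit with NaN where missing."""
        return np.array(
            [v.bv if v.bv is not None else math.nan for v in self.visits]
        )


@dataclass
class Cohort:
    patients: list[PatientRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass(frozen=True)
class ValidationIssue:
    patient_id: str
    kind: str  # edss_range | edss_step | bv_nonpositive | duplicate_time
    detail: str


def _on_half_grid(x: float, tol: float = 1e-9) -> bool:
    return abs(x * 2 - round(x * 2)) <= tol


def _normalize_header(name: str) -> str:
    return str(name).strip().lower().replace(" ", "").replace("_", "").replace("-", "")


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical field names to actual dataframe columns."""
    resolved: dict[str, str] = {}
    if column_map:
        for canon, actual in column_map.items():
            if actual in columns:
                resolved[canon] = actual
    norm = {_normalize_header(c): c for c in columns}
    for canon, aliases in DEFAULT_COLUMN_ALIASES.items():
        if canon in resolved:
            continue
        for alias in aliases:
            key = _normalize_header(alias)
            if key in norm:
                resolved[canon] = norm[key]
                break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return resolved


def read_cohort(
    path: str | Path,
    fmt: str | None = None,
    round_edss: bool = False,
    label: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a long-format cohort table (CSV, TSV or Excel workbook).

    Rows are grouped by patient in file order and sorted by visit time within
    each patient.  EDSS values off the half-point grid are rejected unless
    ``round_edss`` is set, which rounds to the nearest 0.5 with ties toward
    higher disability (the clinically conservative direction).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"csv": "csv", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            suffix, "xlsx" if suffix in (".xlsx", ".xls") else "csv"
        )
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif fmt in ("xlsx", "excel", "xlsx-like"):
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.empty:
        raise ValueError("no records")
    cols = _resolve_columns(list(df.columns), column_map)

    def _num(series: pd.Series, name: str) -> pd.Series:
        out = pd.to_numeric(series, errors="coerce")
        bad = out.isna() & series.notna()
        if bad.any():
            raise ValueError(
                f"unparseable numeric value in column {name!r}: "
                f"{series[bad].iloc[0]!r}"
            )
        return out

    ids = df[cols["patient_id"]].astype(str)
    times = _num(df[cols["time_months"]], "time_months")
    edss = _num(df[cols["edss"]], "edss")
    bv = (
        _num(df[cols["bv"]], "bv")
        if "bv" in cols
        else pd.Series([math.nan] * len(df))
    )
    subtype = (
        df[cols["subtype"]].astype(str)
        if "subtype" in cols
        else pd.Series(["unknown"] * len(df))
    )
    age = (
        _num(df[cols["age_onset"]], "age_onset")
        if "age_onset" in cols
        else pd.Series([math.nan] * len(df))
    )

    patients: list[PatientRecord] = []
    for pid in ids.unique():
        mask = ids == pid
        sub = pd.DataFrame(
            {
                "time": times[mask],
                "edss": edss[mask],
                "bv": bv[mask],
                "subtype": subtype[mask],
                "age": age[mask],
            }
        ).sort_values("time", kind="stable")
        if sub["time"].duplicated().any():
            t_dup = float(sub["time"][sub["time"].duplicated()].iloc[0])
            raise ValueError(f"duplicate (patient, time) row: ({pid!r}, {t_dup})")
        visits = []
        for _, row in sub.iterrows():
            e = float(row["edss"])
            if not _on_half_grid(e):
                if round_edss:
                    e = math.floor(e * 2 + 0.5) / 2
                else:
                    raise ValueError(
                        f"patient {pid!r}: EDSS {e} not on the 0.5-step grid "
                        "(pass round_edss=True to round)"
                    )
            b = float(row["bv"])
            visits.append(
                Visit(
                    time=float(row["time"]),
                    edss=min(max(e, 0.0), 10.0) if round_edss else e,
                    bv=None if math.isnan(b) else b,
                )
            )
        st = str(sub["subtype"].iloc[0]).strip()
        st = st if st in SUBTYPES else "unknown"
        a = float(sub["age"].iloc[0])
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                visits=visits,
                subtype=st,
                age_onset=None if math.isnan(a) else a,
            )
        )
    return Cohort(patients=patients, label=label if label is not None else path.stem)


def write_cohort(cohort: Cohort, path: str | Path, fmt: str = "csv") -> None:
    """Write a cohort back to long-format delimited text (lossless)."""
    rows = []
    for p in cohort:
        for v in p.visits:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "subtype": p.subtype,
                    "age_onset": "" if p.age_onset is None else repr(p.age_onset),
                    "time_months": repr(v.time),
                    "edss": repr(v.edss),
                    "bv": "" if v.bv is None else repr(v.bv),
                }
            )
    df = pd.DataFrame(rows)
    sep = "\t" if fmt == "tsv" else ","
    df.to_csv(path, sep=sep, index=False)


def validate_cohort(cohort: Cohort) -> list[ValidationIssue]:
    """Report EDSS range/step, non-positive BV and duplicate-time violations
    without mutating the cohort.  (Within-patient ordering is the reader's
    contract, so only true duplicate times are flagged here.)"""
    issues: list[ValidationIssue] = []
    for p in cohort:
        seen_times: set[float] = set()
        for v in p.visits:
            if not (0 <= v.edss <= 10):
                issues.append(
                    ValidationIssue(p.patient_id, "edss_range", f"EDSS {v.edss}")
                )
            elif not _on_half_grid(v.edss):
                issues.append(
                    ValidationIssue(p.patient_id, "edss_step", f"EDSS {v.edss}")
                )
            if v.bv is not None and v.bv <= 0:
                issues.append(
                    ValidationIssue(p.patient_id, "bv_nonpositive", f"BV {v.bv}")
                )
            if v.time in seen_times:
                issues.append(
                    ValidationIssue(p.patient_id, "duplicate_time", f"t {v.time}")
                )
            seen_times.add(v.time)
    return issues


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return None
    return obj


def write_results(obj: Any, path: str | Path) -> None:
    """Serialize a pipeline result: trajectories and tables as delimited text,
    structured results (ensembles, cluster models, indices) as JSON with full
    float precision."""
    path = Path(path)
    from .core_model import Trajectory  # local import to avoid cycles

    if isinstance(obj, Trajectory):
        df = pd.DataFrame(
            {
                "t": obj.t,
                "Am": obj.am,
                "Ad": obj.ad,
                "M": obj.m,
                "D": obj.d,
                "Vs": obj.vs,
            }
        )
        df.to_csv(path, index=False, float_format="%.12g")
        return
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format="%.12g")
        return
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)


def read_results_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
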