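"""Delimited-text input/output with schema validation.

All tables are RFC-4180 CSV with a header row, UTF-8, written with at
least six significant digits.  Readers validate column presence, numeric
cells and duplicate keys, and report offending rows by line number
(1-based, counting the header as line 1).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .kinetics import TTRSeries

__all__ = ["read_cohort", "write_cohort", "write_table", "file_digest",
           "ttr_series_to_long"]

_FLOAT_FMT = "%.10g"

TTR_COLUMNS = ("subject_id", "tracer", "time_min", "ttr")
DOSE_COLUMNS = ("tracer", "dose_umol")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")
    return path


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path):
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ParseError(f"{path}: non-numeric value(s) in column "
                         f"{col!r} at line(s) {lines}")
    return out


def ttr_series_to_long(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, v in zip(s.times_min, s.ttr):
            rows.append({"subject_id": s.subject_id, "tracer": s.tracer,
                         "time_min": t, "ttr": v})
    return pd.DataFrame(rows, columns=list(TTR_COLUMNS))


def read_cohort(subjects_path, ttr_path, doses_path):
    """Read and validate a cohort's input files.

    Returns ``(subjects, ttr_series_list, ttr_long, doses)``.  Row-level
    violations (duplicate time points, non-numeric cells) raise
    :class:`ParseError` naming the offending lines.
    """
    subjects = pd.read_csv(subjects_path)
    _require_columns(subjects, ("subject_id", "group"), subjects_path)

    ttr = pd.read_csv(ttr_path)
    _require_columns(ttr, TTR_COLUMNS, ttr_path)
    if ttr.empty:
        raise ParseError(f"{ttr_path}: no series (file has no data rows)")
    ttr["time_min"] = _numeric(ttr, "time_min", ttr_path)
    ttr["ttr"] = _numeric(ttr, "ttr", ttr_path)
    dup = ttr.duplicated(subset=["subject_id", "tracer", "time_min"])
    if dup.any():
        lines = [int(i) + 2 for i in ttr.index[dup][:5]]
        raise ParseError(f"{ttr_path}: duplicate (subject, tracer, time) "
                         f"row(s) at line(s) {lines}")

    doses = pd.read_csv(doses_path)
    _require_columns(doses, DOSE_COLUMNS, doses_path)
    doses["dose_umol"] = _numeric(doses, "dose_umol", doses_path)
    dose_map = dict(zip(doses["tracer"].astype(str), doses["dose_umol"]))

    series = []
    for (sid, tracer), grp in ttr.groupby(["subject_id", "tracer"],
                                          sort=True):
        grp = grp.sort_values("time_min")
        series.append(TTRSeries(
            subject_id=str(sid), tracer=str(tracer),
            times_min=grp["time_min"].to_numpy(),
            ttr=grp["ttr"].to_numpy(),
            dose_umol=float(dose_map.get(str(tracer), np.nan))))
    return subjects, series, ttr, doses


def write_cohort(cohort, outdir) -> dict:
    """Write subjects.csv, ttr_long.csv, doses.csv and truth.csv for a
    :class:`~aminoflux.synthetic.SimulatedCohort`; returns path map."""
    outdir = Path(outdir)
    paths = {
        "subjects": write_table(cohort.subjects, outdir / "subjects.csv"),
        "ttr_long": write_table(ttr_series_to_long(cohort.ttr_series),
                                outdir / "ttr_long.csv"),
        "doses": write_table(cohort.doses, outdir / "doses.csv"),
        "truth": write_table(cohort.truth, outdir / "truth.csv"),
    }
    return paths
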