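"""CSV schemas and (de)serialization for raw inputs and analysis outputs.

Raw inputs are four UTF-8 CSV tables with fixed column names:

=============  =========================================================
file           columns
=============  =========================================================
rainfall       date (ISO-8601 day), rain_mm (>= 0)
ranks          female_id, month (YYYY-MM), rank (in [0, 1])
females        female_id, mother_id, birth_date, death_date, group_id
states         female_id, month (YYYY-MM), state, group_id
pregnancies    female_id, conception_date, end_date (blank = in progress),
               live (0/1)
infants        infant_id, mother_id, birth_date, death_date (blank = alive)
census         group_id, month (YYYY-MM), mean_size
=============  =========================================================

Analysis tables serialize with two comment header lines carrying the
outcome and environment kinds followed by the fixed record columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError
from .panel_builder import (
    OUTCOME_KINDS,
    ENV_KINDS,
    RECORD_COLUMNS,
    STATES,
    AnalysisTable,
    RainSeries,
    RankSeries,
    ReproData,
)
from .raw_records import RawTables

RAW_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "rainfall": ("date", "rain_mm"),
    "ranks": ("female_id", "month", "rank"),
    "females": ("female_id", "mother_id", "birth_date", "death_date", "group_id"),
    "states": ("female_id", "month", "state", "group_id"),
    "pregnancies": ("female_id", "conception_date", "end_date", "live"),
    "infants": ("infant_id", "mother_id", "birth_date", "death_date"),
    "census": ("group_id", "month", "mean_size"),
}


def validate_raw_tables(tables: Mapping[str, pd.DataFrame]) -> list[str]:
    """Return a list of schema-violation messages (empty = valid)."""
    problems: list[str] = []
    for name, cols in RAW_SCHEMAS.items():
        if name not in tables:
            problems.append(f"{name}: table missing")
            continue
        df = tables[name]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            problems.append(f"{name}: missing column(s) {missing}")
            continue
        if name == "rainfall" and len(df):
            mm = pd.to_numeric(df["rain_mm"], errors="coerce")
            if mm.isna().any() or (mm < 0).any():
                problems.append("rainfall: rain_mm must be numeric and >= 0")
            if pd.to_datetime(df["date"], errors="coerce").isna().any():
                problems.append("rainfall: unparseable date(s)")
        if name == "ranks" and len(df):
            r = pd.to_numeric(df["rank"], errors="coerce")
            if r.isna().any() or (r < 0).any() or (r > 1).any():
                problems.append("ranks: rank must lie in [0, 1]")
            if df.duplicated(["female_id", "month"]).any():
                problems.append("ranks: duplicate female-month entries")
        if name == "states" and len(df):
            bad = sorted(set(df["state"].dropna()) - set(STATES))
            if bad:
                problems.append(f"states: unknown state(s) {bad}")
        if name == "pregnancies" and len(df):
            if pd.to_datetime(df["conception_date"], errors="coerce").isna().any():
                problems.append("pregnancies: missing/unparseable conception date(s)")
    return problems


def read_raw_tables(paths: Mapping[str, str | Path]) -> RawTables:
    """Read the raw tables from a name -> path mapping (schema-checked)."""
    frames = {}
    for name in RAW_SCHEMAS:
        if name not in paths:
            raise SchemaError(f"no path given for the {name!r} table")
        frames[name] = pd.read_csv(paths[name])
    problems = validate_raw_tables(frames)
    if problems:
        raise SchemaError("; ".join(problems))
    return RawTables(
        rain=frames["rainfall"], ranks=frames["ranks"], females=frames["females"],
        states=frames["states"], pregnancies=frames["pregnancies"],
        infants=frames["infants"], census=frames["census"],
    )


def write_raw_tables(tables: RawTables, outdir: str | Path) -> dict[str, Path]:
    """Write the raw tables under ``outdir``; returns the path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {
        "rainfall": tables.rain, "ranks": tables.ranks, "females": tables.females,
        "states": tables.states, "pregnancies": tables.pregnancies,
        "infants": tables.infants, "census": tables.census,
    }
    paths = {}
    for name, df in frames.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def load_environment(tables: RawTables) -> tuple[RainSeries, RankSeries, ReproData]:
    """Typed wrappers for a raw-table bundle."""
    return tables.rain_series(), tables.rank_series(), tables.repro_data()


def write_analysis_table(table: AnalysisTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# outcome_kind: {table.outcome_kind}\n")
        fh.write(f"# environment_kind: {table.environment_kind}\n")
        table.df.to_csv(fh, index=False)
    return path


def read_analysis_table(path: str | Path) -> AnalysisTable:
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for _ in range(2):
            line = fh.readline()
            if not line.startswith("#"):
                raise SchemaError(f"{path}: expected metadata header lines")
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
        df = pd.read_csv(fh)
    if meta.get("outcome_kind") not in OUTCOME_KINDS:
        raise SchemaError(f"{path}: bad outcome_kind {meta.get('outcome_kind')!r}")
    if meta.get("environment_kind") not in ENV_KINDS:
        raise SchemaError(f"{path}: bad environment_kind {meta.get('environment_kind')!r}")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return AnalysisTable(df, meta["outcome_kind"], meta["environment_kind"])


def write_fit_result(fit, prefix: str | Path) -> tuple[Path, Path]:
    """Tidy coefficient CSV (term, estimate, se, absorbed) plus a vcov CSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    coef_path = prefix.with_suffix(".coef.csv")
    vcov_path = prefix.with_suffix(".vcov.csv")
    fit.tidy().to_csv(coef_path, index=False)
    fit.vcov.to_csv(vcov_path)
    return coef_path, vcov_path
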