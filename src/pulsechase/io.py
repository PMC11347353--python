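"""CSV schemas and row-level validation for pipeline inputs.

All inputs are UTF-8 comma-separated files with a header row and "."
decimals; months/stages are labels (``Jul`` ... ``Oct``), not numbers.
Validation never mutates inputs: it returns a list of issue records
``(file, row, column, level, message)`` where ``row`` is the 0-based
data row index (-1 for file-level issues) and ``level`` is ``error`` or
``warning``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "validate_table", "validate_file"]


def _check_readings(df: pd.DataFrame, issues: list, fname: str) -> None:
    has_rs = "rs" in df.columns
    has_delta = "delta13c" in df.columns
    if not (has_rs or has_delta):
        issues.append(_issue(fname, -1, "rs/delta13c", "error", "need an rs or delta13c column"))
        return
    rs = df["rs"] if has_rs else pd.Series(np.nan, index=df.index)
    delta = df["delta13c"] if has_delta else pd.Series(np.nan, index=df.index)
    for i in df.index[rs.isna() & delta.isna()]:
        issues.append(_issue(fname, i, "rs/delta13c", "error", "neither rs nor delta13c given"))
    for i in df.index[rs.notna() & delta.notna()]:
        issues.append(
            _issue(fname, i, "rs/delta13c", "warning",
                   "both rs and delta13c given; delta13c takes precedence")
        )
    for i in df.index[rs.notna() & (rs < 0)]:
        issues.append(_issue(fname, i, "rs", "error", "rs must be >= 0"))
    for i in df.index[delta.notna() & (delta <= -1000)]:
        issues.append(_issue(fname, i, "delta13c", "error", "delta13c must be > -1000"))
    for i in df.index[df["time_h"] < 0]:
        issues.append(_issue(fname, i, "time_h", "error", "time_h must be >= 0"))


def _check_pools(df: pd.DataFrame, issues: list, fname: str) -> None:
    for i in df.index[df["biomass_g"] < 0]:
        issues.append(_issue(fname, i, "biomass_g", "error", "biomass_g must be >= 0"))
    bad = ~df["carbon_fraction"].between(0, 1)
    for i in df.index[bad]:
        issues.append(_issue(fname, i, "carbon_fraction", "error", "carbon_fraction must be in [0, 1]"))
    bad = ~((df["fn_atom_percent"] >= 0) & (df["fn_atom_percent"] < 100))
    for i in df.index[bad]:
        issues.append(_issue(fname, i, "fn_atom_percent", "error", "fn_atom_percent must be in [0, 100)"))


def _check_colorimetric(df: pd.DataFrame, issues: list, fname: str) -> None:
    bad = ~df["assay"].isin(["soluble_sugar", "starch"])
    for i in df.index[bad]:
        issues.append(_issue(fname, i, "assay", "error", "assay must be soluble_sugar or starch"))
    for i in df.index[df["fresh_weight_g"] <= 0]:
        issues.append(_issue(fname, i, "fresh_weight_g", "error", "fresh_weight_g must be > 0"))


def _check_standards(df: pd.DataFrame, issues: list, fname: str) -> None:
    for i in df.index[df["concentration_mg_ml"] <= 0]:
        issues.append(_issue(fname, i, "concentration_mg_ml", "error", "concentration must be > 0"))


def _check_hplc_samples(df: pd.DataFrame, issues: list, fname: str) -> None:
    for i in df.index[df["sample_mass_g"] <= 0]:
        issues.append(_issue(fname, i, "sample_mass_g", "error", "sample_mass_g must be > 0"))
    for i in df.index[df["extract_volume_ml"] <= 0]:
        issues.append(_issue(fname, i, "extract_volume_ml", "error", "extract_volume_ml must be > 0"))


def _check_expression(df: pd.DataFrame, issues: list, fname: str) -> None:
    for i in df.index[df["fpkm"] < 0]:
        issues.append(_issue(fname, i, "fpkm", "error", "fpkm must be >= 0"))


def _check_deg(df: pd.DataFrame, issues: list, fname: str) -> None:
    bad = ~df["fdr"].between(0, 1)
    for i in df.index[bad]:
        issues.append(_issue(fname, i, "fdr", "error", "fdr must be in [0, 1]"))


def _check_enzymes(df: pd.DataFrame, issues: list, fname: str) -> None:
    for col in df.columns:
        if col in ("organ", "month", "replicate"):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.notna() & (vals < 0)]:
            issues.append(_issue(fname, i, col, "error", "activity must be >= 0"))


#: file kind -> (required columns, row-check function)
SCHEMAS: dict[str, tuple[tuple[str, ...], Callable]] = {
    "isotope_readings": (("organ", "month", "time_h"), _check_readings),
    "organ_pools": (
        ("organ", "month", "biomass_g", "carbon_fraction", "fn_atom_percent"),
        _check_pools,
    ),
    "colorimetric": (
        ("sample_id", "organ", "month", "assay", "absorbance_620", "fresh_weight_g"),
        _check_colorimetric,
    ),
    "hplc_standards": (("analyte", "concentration_mg_ml", "peak_area"), _check_standards),
    "hplc_samples": (
        ("sample_id", "analyte", "peak_area", "extract_volume_ml", "sample_mass_g"),
        _check_hplc_samples,
    ),
    "enzyme_panels": (("organ", "month", "replicate"), _check_enzymes),
    "expression_fpkm": (("gene_id", "stage", "replicate", "fpkm"), _check_expression),
    "deg_table": (("gene_id", "comparison", "log2fc", "fdr"), _check_deg),
}


def _issue(file: str, row: int, column: str, level: str, message: str) -> dict:
    return dict(file=file, row=row, column=column, level=level, message=message)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read one input CSV (UTF-8, comma-separated, header required)."""
    return pd.read_csv(path)


def validate_table(df: pd.DataFrame, kind: str, fname: str = "<memory>") -> list[dict]:
    """Validate an in-memory table against a schema; returns issues."""
    if kind not in SCHEMAS:
        raise KeyError(f"unknown table kind {kind!r}")
    required, checker = SCHEMAS[kind]
    issues: list[dict] = []
    missing = [c for c in required if c not in df.columns]
    if missing:
        issues.append(
            _issue(fname, -1, ",".join(missing), "error", f"missing required columns: {missing}")
        )
        return issues
    checker(df, issues, fname)
    return issues


def validate_file(path: str | Path, kind: str) -> list[dict]:
    """Validate one CSV file; unreadable files yield a fatal issue."""
    path = Path(path)
    try:
        df = read_table(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        return [_issue(str(path), -1, "", "fatal", f"unreadable file: {exc}")]
    return validate_table(df, kind, str(path))
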