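"""End-to-end orchestration: simulate or load inputs, run every stage.

``run_all`` produces, in one output directory: ``allocation.csv``,
``sugar_profiles.csv``, ``correlations_<organ>.csv``,
``gene_screen.csv``, ``deg_summary.csv``, ``letters.csv``,
``manifest.json`` and a plain-text ``report.txt`` with an allocation
block and a starred correlation matrix.  All randomness flows from the
single config seed, so re-running on the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from pulsechase import assays, io as pio, screens, simulate as sim
from pulsechase.isotope import IsotopeConstants, allocation_table

logger = logging.getLogger(__name__)

__all__ = ["build_sugar_profiles", "run_all", "validate_inputs"]

_VERSION = "0.1.0"


def build_sugar_profiles(
    colorimetric: pd.DataFrame,
    standards: pd.DataFrame,
    hplc_samples: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble per-sample sugar profiles from raw assay tables.

    Colorimetric rows give soluble sugar and starch via the kit
    calibrations; HPLC rows are quantified against per-analyte standard
    curves fitted from the standard series.  Negative contents are kept
    and flagged (``qc_flags`` column).
    """
    curves = {}
    for analyte, sub in standards.groupby("analyte"):
        series = assays.StandardSeries(
            analyte=str(analyte),
            concentrations=sub["concentration_mg_ml"].to_list(),
            peak_areas=sub["peak_area"].to_list(),
        )
        curves[str(analyte)] = assays.fit_standard_curve(series)

    records: dict[str, dict] = {}

    def rec(sid, row) -> dict:
        if sid not in records:
            records[sid] = dict(
                sample_id=sid,
                organ=row.get("organ", ""),
                month=row.get("month", ""),
                qc_flags=[],
            )
        return records[sid]

    for _, row in colorimetric.iterrows():
        reading = assays.ColorimetricReading(
            sample_id=str(row["sample_id"]),
            assay=str(row["assay"]),
            absorbance_620=float(row["absorbance_620"]),
            fresh_weight_g=float(row["fresh_weight_g"]),
        )
        if reading.assay == "soluble_sugar":
            content, flagged = assays.soluble_sugar_content(reading)
        else:
            content, flagged = assays.starch_content(reading)
        entry = rec(reading.sample_id, row)
        entry[reading.assay] = content
        if flagged:
            entry["qc_flags"].append(f"negative_{reading.assay}")

    for _, row in hplc_samples.iterrows():
        analyte = str(row["analyte"])
        if analyte not in curves:
            raise KeyError(f"no standard curve for analyte {analyte!r}")
        content, flagged = assays.quantify_sugar(
            float(row["peak_area"]),
            curves[analyte],
            extract_volume_ml=float(row["extract_volume_ml"]),
            sample_mass_g=float(row["sample_mass_g"]),
        )
        entry = rec(str(row["sample_id"]), row)
        entry[analyte] = content
        if flagged:
            entry["qc_flags"].append(f"negative_{analyte}")

    rows = []
    for entry in records.values():
        soluble = entry.get("soluble_sugar", np.nan)
        starch = entry.get("starch", np.nan)
        if not (np.isnan(soluble) or np.isnan(starch)) and soluble >= 0 and starch >= 0:
            total, ratio, dominant = assays.nsc_summary(soluble, starch)
        else:
            total, ratio, dominant = np.nan, np.nan, False
        rows.append(
            dict(
                sample_id=entry["sample_id"],
                organ=entry["organ"],
                month=entry["month"],
                sucrose=entry.get("sucrose", np.nan),
                glucose=entry.get("glucose", np.nan),
                fructose=entry.get("fructose", np.nan),
                soluble_sugar=soluble,
                starch=starch,
                nsc_total=total,
                soluble_to_starch_ratio=ratio,
                soluble_dominant=dominant,
                qc_flags=";".join(entry["qc_flags"]),
            )
        )
    return pd.DataFrame(rows)


def validate_inputs(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Validate input CSVs; returns a per-issue report DataFrame.

    ``paths`` maps a table kind (see :data:`pulsechase.io.SCHEMAS`) to a
    file path.  The report has columns ``file, row, column, level,
    message``; an empty report means every file passed.
    """
    issues: list[dict] = []
    for kind, path in paths.items():
        issues.extend(pio.validate_file(path, kind))
    return pd.DataFrame(issues, columns=["file", "row", "column", "level", "message"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _month_order(months) -> list[str]:
    calendar = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
    known = [m for m in calendar if m in set(months)]
    rest = [m for m in months if m not in calendar]
    return known + sorted(set(rest))


def _report_text(allocation: pd.DataFrame, correlations: Mapping[str, pd.DataFrame]) -> str:
    lines = ["pulsechase run report", "=" * 60, "", "Allocation of excess 13C (% per organ, end of chase)", ""]
    organs = sorted(allocation["organ"].unique())
    months = _month_order(allocation["month"].unique())
    header = f"{'month':<8}" + "".join(f"{o:>15}" for o in organs) + f"{'total mg':>12}"
    lines.append(header)
    for month in months:
        sub = allocation[allocation["month"] == month].set_index("organ")
        cells = "".join(
            f"{sub.loc[o, 'allocation_percent']:>15.2f}" if o in sub.index else f"{'-':>15}"
            for o in organs
        )
        total = sub["total13c_mg"].iloc[0] if len(sub) else float("nan")
        lines.append(f"{month:<8}{cells}{total:>12.3f}")
    lines.append("")
    for organ, mat in correlations.items():
        lines.append(f"Sugar x enzyme correlations, {organ} (r with stars)")
        if mat.empty:
            lines.append("  (no usable cells)")
            continue
        wide = mat.pivot(index="sugar", columns="enzyme", values="r")
        starw = mat.pivot(index="sugar", columns="enzyme", values="star")
        lines.append(f"{'':<16}" + "".join(f"{e:>12}" for e in wide.columns))
        for sugar in wide.index:
            cells = "".join(
                f"{wide.loc[sugar, e]:>10.3f}{starw.loc[sugar, e] or '':<2}"
                for e in wide.columns
            )
            lines.append(f"{sugar:<16}{cells}")
        lines.append("")
    return "\n".join(lines) + "\n"


def run_all(config_path: str | Path, outdir: str | Path, seed: int | None = None) -> Path:
    """Run the full pipeline as configured and write all outputs.

    The YAML config either describes a synthetic study (the
    :class:`~pulsechase.simulate.SimConfig` schema) or, under an
    ``inputs:`` mapping, points at existing CSVs (kinds as in
    :data:`pulsechase.io.SCHEMAS`).  ``seed`` overrides the config seed.

    Returns the output directory path.  Raises on schema violations.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)

    input_checksums: dict[str, str] = {}
    if "inputs" in raw:
        paths = {k: Path(v) for k, v in raw["inputs"].items()}
        report = validate_inputs(paths)
        errors = report[report["level"].isin(["error", "fatal"])]
        if not errors.empty:
            msg = "; ".join(
                f"{r.file}:{r.row}:{r.column}: {r.message}" for r in errors.itertuples()
            )
            raise ValueError(f"input validation failed: {msg}")
        tables = {k: pio.read_table(p) for k, p in paths.items()}
        input_checksums = {k: _sha256(p) for k, p in paths.items()}
        cfg = None
        truth = None
        readings = tables.get("isotope_readings")
        pools = tables.get("organ_pools")
        colorimetric = tables.get("colorimetric")
        standards = tables.get("hplc_standards")
        hplc_samples = tables.get("hplc_samples")
        panels = tables.get("enzyme_panels")
        expr = tables.get("expression_fpkm")
        deg = tables.get("deg_table")
        constants = IsotopeConstants(Rc=float(raw.get("rc", IsotopeConstants().Rc)))
        seed_used = seed
    else:
        cfg = sim._config_from_dict(raw)
        if seed is not None:
            cfg = cfg.with_(seed=int(seed))
        seed_used = cfg.seed
        constants = cfg.constants
        readings, pools, truth = sim.simulate_pulse_chase(cfg)
        colorimetric, standards, hplc_samples = sim.simulate_assays(None, cfg)
        panels = sim.simulate_enzyme_panels(cfg)
        seed_truth = sim.DEFAULT_SUGAR_TRUTH
        series = (
            seed_truth[seed_truth["organ"] == "seed_kernels"]
            .set_index("month")["sucrose"]
            .to_dict()
        )
        expr, planted = sim.simulate_expression(cfg, series)
        deg = sim.simulate_deg_table(cfg, sorted(expr["gene_id"].unique())[:200])
        for name, df in [
            ("isotope_readings", readings),
            ("organ_pools", pools),
            ("colorimetric", colorimetric),
            ("hplc_standards", standards),
            ("hplc_samples", hplc_samples),
            ("enzyme_panels", panels),
            ("expression_fpkm", expr),
            ("deg_table", deg),
        ]:
            _write_csv(df, outdir / f"{name}.csv")
        truth_payload = dict(
            pulse_mg=truth.pulse_mg,
            planted_genes=planted,
            isotope=truth.isotope.to_dict(orient="list"),
            respired=truth.respired.to_dict(orient="list"),
        )
        (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1))

    stage_counts: dict[str, int] = {}
    qc_flag_count = 0

    # 1. isotope allocation
    allocation = allocation_table(readings, pools, constants)
    _write_csv(allocation, outdir / "allocation.csv")
    stage_counts["allocation"] = len(allocation)
    qc_flag_count += int(allocation["negative_excess"].sum())

    # 2. sugar profiles
    profiles = build_sugar_profiles(colorimetric, standards, hplc_samples)
    _write_csv(profiles, outdir / "sugar_profiles.csv")
    stage_counts["sugar_profiles"] = len(profiles)
    qc_flag_count += int((profiles["qc_flags"] != "").sum())

    # 3. sugar x enzyme correlations per organ
    sugar_cols = ["organ", "month", "replicate", "soluble_sugar", "fructose", "glucose", "sucrose"]
    prof_rep = profiles.copy()
    if "replicate" not in prof_rep.columns:
        prof_rep["replicate"] = (
            prof_rep["sample_id"].astype(str).str.extract(r"r(\d+)$")[0].astype(float)
        )
    correlations = screens.enzyme_sugar_matrix(
        panels, prof_rep[[c for c in sugar_cols if c in prof_rep.columns]]
    )
    for organ, mat in correlations.items():
        _write_csv(mat, outdir / f"correlations_{organ}.csv")
    stage_counts["correlation_organs"] = len(correlations)

    # 4. gene-vs-sucrose screen (seed kernels carry the sucrose signal)
    screen = pd.DataFrame(columns=["gene_id", "r", "p", "star", "n"])
    if expr is not None and not profiles.empty:
        focus = "seed_kernels" if (profiles["organ"] == "seed_kernels").any() else profiles["organ"].iloc[0]
        suc = (
            profiles[profiles["organ"] == focus]
            .groupby("month")["sucrose"]
            .mean()
            .to_dict()
        )
        suc = {k: v for k, v in suc.items() if not np.isnan(v)}
        if len(suc) >= 3:
            screen = screens.gene_sucrose_screen(expr, suc)
    _write_csv(screen, outdir / "gene_screen.csv")
    stage_counts["gene_screen"] = len(screen)

    # 5. DEG filter + Venn overlaps
    deg_rows = []
    venn = {}
    if deg is not None and not deg.empty:
        kept_sets = {}
        for comparison, sub in deg.groupby("comparison"):
            kept, counts = screens.deg_filter(sub)
            kept_sets[str(comparison)] = set(kept["gene_id"])
            deg_rows.append(
                dict(comparison=comparison, kept=len(kept), up=counts["up"], down=counts["down"])
            )
        if len(kept_sets) >= 2:
            venn = {
                "|".join(k): v for k, v in screens.venn_overlap(kept_sets).items()
            }
    deg_summary = pd.DataFrame(deg_rows, columns=["comparison", "kept", "up", "down"])
    _write_csv(deg_summary, outdir / "deg_summary.csv")
    stage_counts["deg_comparisons"] = len(deg_summary)

    # 6. significance letters: months compared within organ for each sugar
    letter_rows = []
    for (organ, assay_col) in [
        (o, c)
        for o in sorted(profiles["organ"].unique())
        for c in ("soluble_sugar", "starch", "sucrose")
    ]:
        sub = profiles[profiles["organ"] == organ]
        groups = {
            m: g[assay_col].dropna().to_numpy()
            for m, g in sub.groupby("month")
        }
        groups = {m: v for m, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        letters = screens.anova_lsd_letters(groups)
        for month, letter in letters.items():
            letter_rows.append(
                dict(organ=organ, variable=assay_col, month=month, letters=letter)
            )
    letters_df = pd.DataFrame(letter_rows, columns=["organ", "variable", "month", "letters"])
    _write_csv(letters_df, outdir / "letters.csv")
    stage_counts["letter_rows"] = len(letters_df)

    # 7. manifest + report
    manifest = dict(
        pipeline_version=_VERSION,
        config_sha256=_sha256(config_path),
        input_checksums=input_checksums,
        stage_row_counts=stage_counts,
        qc_flag_count=qc_flag_count,
        seed=seed_used,
        venn_regions=venn,
        output_checksums={},
    )
    report_path = outdir / "report.txt"
    report_path.write_text(_report_text(allocation, correlations))
    for p in sorted(outdir.glob("*.csv")):
        manifest["output_checksums"][p.name] = _sha256(p)
    manifest["output_checksums"][report_path.name] = _sha256(report_path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return outdir
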