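"""Calibrated sugar and starch quantification.

Two assay families are supported:

* anthrone-type colorimetric kits read at 620 nm, with fixed affine
  calibrations — soluble sugar ``2.34 * (A + 0.07) / W`` and starch
  ``0.578 * (A + 0.0295) / W`` in mg per gram fresh weight;
* HPLC sugar components (sucrose, glucose, fructose) quantified against
  an external standard series by unweighted ordinary least squares.

Negative computed contents are flagged rather than truncated so that
questionable readings stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SOLUBLE_SUGAR_SLOPE",
    "SOLUBLE_SUGAR_OFFSET",
    "STARCH_SLOPE",
    "STARCH_OFFSET",
    "STANDARD_GRADIENT_MG_ML",
    "ColorimetricReading",
    "StandardSeries",
    "StandardCurve",
    "SugarProfile",
    "soluble_sugar_content",
    "starch_content",
    "fit_standard_curve",
    "quantify_sugar",
    "nsc_summary",
]

# kit calibration constants (content = slope * (A + offset) / W)
SOLUBLE_SUGAR_SLOPE = 2.34
SOLUBLE_SUGAR_OFFSET = 0.07
STARCH_SLOPE = 0.578
STARCH_OFFSET = 0.0295

#: Six-point external standard gradient in mg/ml.
STANDARD_GRADIENT_MG_ML = (0.625, 1.25, 2.5, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class ColorimetricReading:
    """One 620 nm absorbance with the fresh weight that produced it."""

    sample_id: str
    assay: str  # "soluble_sugar" | "starch"
    absorbance_620: float
    fresh_weight_g: float

    def __post_init__(self) -> None:
        if self.assay not in ("soluble_sugar", "starch"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.fresh_weight_g <= 0:
            raise ValueError(
                f"fresh_weight_g must be > 0, got {self.fresh_weight_g}"
            )


@dataclass(frozen=True)
class StandardSeries:
    """External standard measurements for one analyte."""

    analyte: str
    concentrations: Sequence[float]  # mg/ml
    peak_areas: Sequence[float]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) != len(self.peak_areas):
            raise ValueError("concentrations and peak_areas differ in length")
        if len(conc) < 3:
            raise ValueError("standard series needs at least 3 points")
        if np.any(conc <= 0):
            raise ValueError("standard concentrations must be positive")
        if len(np.unique(conc)) != len(conc):
            raise ValueError("standard concentrations must be distinct")


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line ``area = slope * conc + intercept``."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class SugarProfile:
    """Per-sample sugar composition in mg per gram fresh weight."""

    sample_id: str
    organ: str
    month: str
    sucrose: float
    glucose: float
    fructose: float
    soluble_sugar: float
    starch: float
    nsc_total: float
    soluble_to_starch_ratio: float


def soluble_sugar_content(reading: ColorimetricReading) -> tuple[float, bool]:
    """Soluble sugar in mg/g FW from the anthrone 620 nm absorbance.

    Returns ``(content, flagged)`` where ``flagged`` marks a negative
    result (absorbance below the calibration zero point).
    """
    if reading.assay != "soluble_sugar":
        raise ValueError(f"expected a soluble_sugar reading, got {reading.assay!r}")
    content = (
        SOLUBLE_SUGAR_SLOPE
        * (reading.absorbance_620 + SOLUBLE_SUGAR_OFFSET)
        / reading.fresh_weight_g
    )
    return content, content < 0


def starch_content(reading: ColorimetricReading) -> tuple[float, bool]:
    """Starch in mg/g FW: ``0.578 * (A + 0.0295) / W``; flags negatives."""
    if reading.assay != "starch":
        raise ValueError(f"expected a starch reading, got {reading.assay!r}")
    content = (
        STARCH_SLOPE
        * (reading.absorbance_620 + STARCH_OFFSET)
        / reading.fresh_weight_g
    )
    return content, content < 0


def fit_standard_curve(series: StandardSeries) -> StandardCurve:
    """Fit an unweighted OLS calibration line to a standard series.

    Raises on degenerate input: fewer than three points, zero variance
    in concentration, or a non-positive fitted slope (the detector must
    respond to the analyte for the curve to be invertible).
    """
    conc = np.asarray(series.concentrations, dtype=float)
    areas = np.asarray(series.peak_areas, dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("zero variance in standard concentrations")
    fit = stats.linregress(conc, areas)
    if fit.slope <= 0:
        raise ValueError(
            f"unusable standard curve for {series.analyte}: "
            f"slope {fit.slope:.6g} <= 0"
        )
    # rvalue**2 is residual-based r^2 for simple linear regression
    return StandardCurve(
        analyte=series.analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantify_sugar(
    area: float,
    curve: StandardCurve,
    extract_volume_ml: float = 10.0,
    sample_mass_g: float = 1.0,
) -> tuple[float, bool]:
    """Convert a sample peak area to mg analyte per gram fresh weight.

    The extract concentration ``(area - intercept) / slope`` in mg/ml is
    scaled by the extraction bookkeeping (default: 1 g of tissue diluted
    to 10 ml).  An area below the intercept yields a negative content,
    which is flagged but not clamped.
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be > 0")
    if sample_mass_g <= 0:
        raise ValueError("sample_mass_g must be > 0")
    if extract_volume_ml <= 0:
        raise ValueError("extract_volume_ml must be > 0")
    conc = (area - curve.intercept) / curve.slope
    content = conc * extract_volume_ml / sample_mass_g
    return content, content < 0


def nsc_summary(soluble: float, starch: float) -> tuple[float, float, bool]:
    """Non-structural carbohydrate total, soluble/starch ratio and flag.

    Returns ``(nsc_total, ratio, soluble_dominant)``.  The flag is True
    only when soluble sugars strictly exceed half the NSC total (the
    boundary itself does not count as dominance).  ``ratio`` is ``inf``
    when starch is zero but soluble is not, and ``nan`` when both are
    zero (undefined).
    """
    if soluble < 0 or starch < 0:
        raise ValueError("contents must be >= 0")
    total = soluble + starch
    if total == 0:
        return 0.0, float("nan"), False
    ratio = soluble / starch if starch > 0 else float("inf")
    return total, ratio, soluble / total > 0.5
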