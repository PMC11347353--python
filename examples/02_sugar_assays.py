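"""Calibrated sugar quantification: colorimetric kits and HPLC.

Shows the two assay paths on hand-made signals: the fixed-calibration
anthrone (soluble sugar) and starch formulas, and an HPLC standard
curve fitted over the six-point gradient then inverted for a sample
peak area.
"""

from pulsechase import (
    ColorimetricReading,
    StandardSeries,
    fit_standard_curve,
    nsc_summary,
    quantify_sugar,
    soluble_sugar_content,
    starch_content,
)
from pulsechase.assays import STANDARD_GRADIENT_MG_ML

# --- colorimetric kits: content = slope * (A + offset) / fresh weight
soluble, _ = soluble_sugar_content(
    ColorimetricReading("seed_Sep", "soluble_sugar", absorbance_620=1.68, fresh_weight_g=0.1)
)
starch, _ = starch_content(
    ColorimetricReading("seed_Sep", "starch", absorbance_620=4.47, fresh_weight_g=0.1)
)
total, ratio, soluble_dominant = nsc_summary(soluble, starch)
print(f"soluble sugar: {soluble:6.2f} mg/g FW   starch: {starch:6.2f} mg/g FW")
print(f"NSC total:     {total:6.2f} mg/g FW   soluble/starch ratio: {ratio:.2f} "
      f"(soluble > 50% of NSC: {soluble_dominant})")

# --- HPLC: fit the external standard series, then invert it
slope_true, intercept_true = 118000.0, 1500.0
series = StandardSeries(
    "sucrose",
    STANDARD_GRADIENT_MG_ML,
    [slope_true * c + intercept_true for c in STANDARD_GRADIENT_MG_ML],
)
curve = fit_standard_curve(series)
print(f"\nstandard curve: area = {curve.slope:.1f} * conc + {curve.intercept:.1f} "
      f"(r^2 = {curve.r_squared:.6f})")

# a September seed-kernel extract: 1 g tissue brought to 10 ml
area = slope_true * 2.593 + intercept_true  # 2.593 mg/ml in the extract
content, _ = quantify_sugar(area, curve, extract_volume_ml=10.0, sample_mass_g=1.0)
print(f"sample peak area {area:.0f} -> sucrose {content:.2f} mg/g FW "
      "(extract concentration times the 10 ml / 1 g bookkeeping)")
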