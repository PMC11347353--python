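# Methods

## The measurement chain

A pulse-chase labeling study feeds ¹³CO₂ to source leaves and follows
the labeled photosynthate into sink organs.  The package's isotope
module implements the standard chain from raw ratio to allocation:

* **δ¹³C** is the per-mil deviation of a sample's ¹³C/¹²C ratio from
  the VPDB standard ratio `R_c = 0.0112372`.  The atom-percent
  conversion `Atom% = (δ+1000)·R_c / ((δ+1000)·R_c + 1000) × 100` is
  the exact algebraic identity between the delta scale and the fraction
  of carbon atoms that are ¹³C (no approximation for small enrichment).
* **Excess tracer mass** multiplies the atom-percent excess over the
  unlabeled background `F_n` by the organ's carbon pool `C_i =
  carbon_fraction × dry_biomass`.  With `C_i` in grams the factor 1000
  lands the result in milligrams, the scale on which whole-plant totals
  of a few mg are naturally expressed.
* **Negative excess** (atom percent below background, typical late in
  the season when label has been exported or respired away) is
  preserved and flagged, never clamped: clamping would silently
  fabricate mass conservation in the monthly balance.  The monthly
  allocation is only defined when the month's total excess is positive;
  otherwise the partition is reported as missing.
* **Transport rate** `V_i` divides each organ's excess mass by its dry
  biomass and by the hours since the end of labeling, i.e. the
  per-gram import rate in µg·g⁻¹·h⁻¹.  The per-gram convention is a
  design choice: the rate's conventional unit is per gram, and dividing
  by biomass makes rates comparable across organs of very different
  size.  (Reported per organ instead, rates would simply be these
  values times biomass.)
* When an organ × month pair carries several timepoints, the monthly
  balance uses the latest one (end of chase).  If a row supplies both a
  raw ratio and a δ¹³C, the δ value wins; the validator warns.

## Assay calibrations

The colorimetric kit formulas — soluble sugar `2.34·(A + 0.07)/W`,
starch `0.578·(A + 0.0295)/W`, both mg per g fresh weight from a 620 nm
absorbance — are applied exactly as fixed affine calibrations; the
constants are treated as already incorporating the kit's dilution
scheme, so no additional dilution factor is applied unless the caller
supplies one through the extraction bookkeeping.

HPLC sugar components are quantified against an external standard
series (six points, 0.625–20 mg·ml⁻¹) fitted by unweighted ordinary
least squares; weighting is deliberately not applied because the
calibration protocol specifies none.  The sample conversion is
`content = (area − intercept)/slope × extract_volume / sample_mass`,
default 10 ml per 1 g of tissue.  Negative computed contents (area
below the fitted intercept) are flagged, not truncated.

**Quantification range.**  Relative accuracy degrades below the lowest
standard: the fitted intercept's uncertainty is a fixed absolute error,
so for extracts under 0.625 mg·ml⁻¹ (6.25 mg·g⁻¹ at default
bookkeeping) the relative error can exceed the detector noise several
fold.  The recovery tests therefore assert the ~3× noise bound within
the calibration range.

The soluble-to-starch summary flags soluble dominance only when soluble
sugars *strictly* exceed half the non-structural carbohydrate total; an
exact 50 % split does not count.

## Statistical screens

* **Correlations** use the sample Pearson r with the two-sided p from
  the t transform on n−2 degrees of freedom; stars follow the
  convention `**` p < 0.01, `*` 0.01 ≤ p < 0.05.  Cells default to
  replicate-level pairing (stages × replicates): with only four stage
  means, even r ≈ 0.96 cannot reach p < 0.01, so replicate-level n is
  what gives the starred significance levels a leg to stand on; a
  `stage_means` switch collapses replicates first for sensitivity
  analysis.  No multiple-testing correction is applied across cells
  (none is conventional for these descriptive tables); callers can
  correct downstream.
* **Gene–trait ranking** computes r between each gene's FPKM
  trajectory and the sucrose trajectory, sorts descending with
  lexicographic tie-break, and excludes zero-variance genes with a log
  entry.  Pearson's affine invariance makes the ranking insensitive to
  gene-wise FPKM rescaling.
* **DEG filtering** keeps records with FDR ≤ 0.05 *and* |log₂FC| ≥ 1,
  both boundaries inclusive as the thresholds are stated; the filter is
  monotone in both thresholds.  Venn region counts enumerate exclusive
  membership over any number of comparisons.
* **ANOVA + LSD letters.**  Groups are compared by unprotected
  Fisher LSD: every pair gets a t test with the one-way-ANOVA pooled
  mean squared error on N−k degrees of freedom (the behavior of the
  usual statistical packages).  The compact letter display is built by
  insert-and-absorb: start with one column holding all groups, split
  every column containing a significantly different pair, absorb
  subset columns, then assign letters in descending-mean order.  The
  construction guarantees both directions — groups share a letter iff
  the LSD test does not separate them — which the tests verify against
  an exhaustive pairwise oracle.  Degenerate inputs: zero pooled
  variance with unequal means yields all-distinct letters; groups with
  fewer than two replicates are rejected.  A Shapiro–Wilk normality
  pre-check warns (never blocks), since the downstream ANOVA is the
  procedure actually reported.

## The synthetic study

The generator emulates the labeling experiment so every stage has
inputs with known truth.

**Pulse-chase dynamics** are first-order and linear — the field
protocol provides no kinetic model, so the simplest mechanistic choice
is made explicit: the source (leaf) excess pool drains to each sink at
a constant per-hour transfer rate and to a respired pool at a
respiration rate; sinks may respire too (default 0).  Forward Euler
with `dt = 0.01 h` is used instead of the closed form so the respired
pool is an explicit state and conservation (organs + respired = pulse)
holds to machine precision at every step; a step-size guard rejects
`rate × dt > 0.1`.  The two-hour feeding is treated as an instantaneous
pulse at t = 0, which is a good approximation on a 72 h chase.

Defaults (one labeled branch unit): leaf 40 g dry mass at 45 % carbon,
branches 30 g/47 %, peels 25 g/44 %, seed kernels 15 g/50 % — realistic
for a pruned fruiting branch; background δ¹³C −27‰; pulse enrichment
0.2 atom-% points above background, which puts the leaf near +150‰ at
t = 0, matching what a 99 atom-% ¹³CO₂ feeding produces; chase sampled
at 0/6/24/48/72 h; measurement noise 1‰ (Gaussian, additive in per-mil
space, the scale of isotope-ratio instrument repeatability).

Each month's kinetics are stated in the config as the allocation vector
the noiseless model should reach at 72 h; a closed-form solver converts
the target to rates given the fraction of exported carbon lost to
respiration (default 20 %).  The four committed monthly targets are the
canonical seasonal partition: leaves dominant in July, seeds taking
over by October.

**Assay signals** invert the calibration formulas around planted true
contents (multiplicative noise, CV 2 % — typical microplate
repeatability); the committed sugar truth follows the seasonal pattern
of an oil fruit (fructose dominant early, seed sucrose peaking at
25.93 mg·g⁻¹ in September, soluble sugars above starch throughout).
Enzyme panels are noisy replicates around stage profiles with the
September SuSy-II peak and the organ-specific invertase shapes; the
neutral-invertase assay is absent for peels, exercising the
missing-column path.

**Expression tables** plant genes whose latent trajectory mixes the
standardized sucrose series with independent noise at weight equal to
the target correlation; FPKM is made non-negative by `exp(µ + σz)` with
σ = 0.25, which keeps the transform near-linear — the observable
FPKM-level correlation is attenuated only ~2 % below the latent target.
Background genes are independent noise.  With the triplicate design (4
stages × 3 replicates = 12 observations) the null distribution of r
across ~1000 background genes has a long tail (max |r| near 0.8), so
whether *every* planted gene at r ≈ 0.9 outranks all background genes
is seed-dependent; the seeded default configuration satisfies it, and
the recovery scripts report the realized precision.

**What passing tests do and do not show.**  The generator's noise is
well-behaved (Gaussian, independent); real data add fractionation
drift, within-organ heterogeneity, extraction losses and batch effects
that the model does not emulate.  Passing recovery tests demonstrates
the *analysis* is correct and well-calibrated under the stated noise
model, not that field data of this design would achieve the same
precision.

## Reproducibility

All randomness descends from one integer seed through per-stage child
streams, so identical configs give byte-identical CSVs.  The pipeline
manifest records config and input checksums, per-stage row counts, QC
flag counts and the seed; re-running over the same inputs reproduces
identical output checksums.

## Problem sizes

The committed configuration simulates four months × four organs with a
0.01 h step over 72 h, quadruplicate assays, and 1000-gene expression
tables; the recovery and oracle suites use 1000 randomized inputs and
200 Monte-Carlo letter draws.  These sizes make every distributional
check well-resolved while the full test suite and the reproduction
script each run in seconds.

## Known limitations

* No isotope fractionation corrections, Keeling-plot partitioning, or
  raw mass-spectrometer file parsing; readings enter as ratios or δ¹³C.
* HPLC peak detection/integration is out of scope — peak areas are
  inputs; no recovery factor is applied for filtration or repeated
  extraction (none is specified by the protocols emulated).
* Differential-expression model fitting is consumed, not performed: DEG
  tables arrive with log₂FC and FDR already computed.
* The compartment model is linear with constant rates; saturating
  transport or diel variation would need a different kinetic core.
* Whether a monthly total should be scaled per plant or per labeled
  branch is left to the user's biomass convention; the package is
  agnostic (scale the pool biomasses accordingly).
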