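# pulsechase

Source–sink carbon allocation analysis for ¹³C pulse-chase labeling
studies on fruit trees, with calibrated sugar/starch quantification and
the correlation screens that link sugar accumulation to enzyme
activities and gene expression.

## Who this is for

Plant physiologists running stable-isotope labeling campaigns: a branch
is fed ¹³CO₂ for a short pulse, then organs (leaves, branches, fruit
peels, seed kernels) are sampled over a chase and assayed.  The package
turns those raw measurements into the quantities such a study reports —
per-organ tracer allocation, transport rates, sugar profiles,
correlation tables with significance stars, and compact-letter
displays — and ships a synthetic-data generator with known ground truth
so the whole pipeline can be exercised and validated without a field
season.

## The model

Isotope chain (per organ *i*, month, chase time *H*):

```
δ¹³C  = (R_s − R_c) / R_c × 1000            R_c = 0.0112372 (VPDB)
Atom% = (δ + 1000)·R_c / ((δ + 1000)·R_c + 1000) × 100
C_i   = C% × W_i                            [g carbon; W_i dry biomass]
¹³C_i = C_i × (Atom% − F_n)/100 × 1000      [mg excess tracer; F_n = background]
P_i   = ¹³C_i / Σ_j ¹³C_j × 100             [allocation %, sums to 100]
V_i   = (¹³C_i/W_i) / H                     [µg·g⁻¹·h⁻¹ transport rate]
```

Assays: soluble sugar `2.34·(A + 0.07)/W` and starch
`0.578·(A + 0.0295)/W` (mg·g⁻¹ FW from 620 nm absorbance), HPLC sugar
components against an unweighted OLS standard curve over the
0.625–20 mg·ml⁻¹ gradient.  Screens: Pearson r with two-sided t-based
p-values (`*` p < 0.05, `**` p < 0.01), DEG filtering at FDR ≤ 0.05 and
|log₂FC| ≥ 1 (boundaries inclusive), Venn region counts, and one-way
ANOVA followed by Fisher's LSD rendered as a compact letter display.

The simulator drives a first-order compartment model: the leaf's
excess-¹³C pool drains to each sink at a per-hour transfer rate and to
an explicit respired pool, integrated by forward Euler with exact mass
accounting; assay signals are generated by inverting the calibration
formulas around planted true contents.

## Worked example

`examples/01_isotope_allocation.py` builds an August-style sampling by
hand and prints:

```
       organ  delta13c  atom_percent  excess13c_mg  allocation_percent  transport_rate_ug_g_h
    branches    -13.25        1.0967        2.1314              8.8211                 0.9868
      leaves     70.98        1.1892       19.3709             80.1686                 6.7260
       peels    -20.00        1.0893        0.8466              3.5037                 0.4703
seed_kernels     -5.00        1.1057        1.8138              7.5066                 1.6794

total excess 13C this month: 24.163 mg
```

Reading it: each organ's δ¹³C is converted to atom percent; the excess
over the unlabeled background (here δ¹³C ≈ −27‰) times the organ's
carbon pool gives milligrams of tracer; the allocation column
partitions the month's 24.2 mg of labeled carbon across organs (sums to
100 %), and the last column is the import rate per gram of dry biomass
per hour of chase.

`examples/04_full_pipeline.py` simulates a four-month study from the
committed config and recovers the planted August allocation
(7.70 / 54.55 / 16.54 / 21.21 % for branches/leaves/peels/seeds) within
a fraction of a percentage point despite 1‰ measurement noise:

```
branches         8.10
leaves          54.97
peels           16.19
seed_kernels    20.75
```

The other examples cover the assay calibrations (`02`) and the
correlation/DEG/letter screens (`03`).  The same functionality is
available from the shell via the `pulsechase` command
(`simulate`, `isotope-allocate`, `assay-quant`, `correlate`,
`deg-filter`, `letters`, `run-all`, `validate`).

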