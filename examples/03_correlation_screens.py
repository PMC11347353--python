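"""Statistical screens: correlations, DEG filtering, letters.

Generates a small synthetic panel (enzyme activities + sugar profiles +
expression table with genes planted to track sucrose), then runs each
screen and prints what it finds.
"""

import pandas as pd

from pulsechase import (
    anova_lsd_letters,
    deg_filter,
    default_config,
    enzyme_sugar_matrix,
    gene_sucrose_screen,
    simulate_assays,
    simulate_enzyme_panels,
    simulate_expression,
    venn_overlap,
)
from pulsechase.pipeline import build_sugar_profiles
from pulsechase.simulate import DEFAULT_SUGAR_TRUTH

cfg = default_config()

# sugar x enzyme correlation matrix for the seed kernels
panels = simulate_enzyme_panels(cfg)
profiles = build_sugar_profiles(*simulate_assays(None, cfg))
profiles["replicate"] = profiles["sample_id"].str.extract(r"r(\d+)$")[0].astype(int)
matrix = enzyme_sugar_matrix(panels, profiles)["seed_kernels"]
cell = matrix.query("sugar == 'sucrose' and enzyme == 'SuSy_II'").iloc[0]
print("seed kernels, sucrose vs SuSy-II: "
      f"r = {cell.r:.3f}{cell.star} (p = {cell.p:.2g}, n = {cell.n})")
print("  -> the sucrose-synthesis enzyme tracks seed sucrose; ** marks p < 0.01\n")

# gene screen: 10 planted genes among 200 background
sucrose = DEFAULT_SUGAR_TRUTH.query("organ == 'seed_kernels'").set_index("month")["sucrose"].to_dict()
expr, planted = simulate_expression(cfg, sucrose, n_genes=200, n_planted=10, target_r=0.9)
top = gene_sucrose_screen(expr, sucrose, top_k=10)
hits = len(set(top.gene_id) & set(planted))
print(f"gene screen: top-10 contains {hits}/10 planted sucrose-tracking genes")
print(top.head(3).round(3).to_string(index=False), "\n")

# DEG filter boundaries and overlap of comparisons
deg = pd.DataFrame(dict(
    gene_id=["g0", "g1", "g2", "g3", "g4"],
    log2fc=[1.5, 0.5, -2.0, 3.0, -1.0],
    fdr=[0.01, 0.01, 0.04, 0.2, 0.05],
))
kept, counts = deg_filter(deg)
print(f"DEG filter (FDR<=0.05, |log2FC|>=1): kept {len(kept)}/5 "
      f"({counts['up']} up, {counts['down']} down; boundary rows survive)")
common = venn_overlap({"J_A": {"g0", "g2", "g4"}, "J_S": {"g2", "g4"}, "J_O": {"g4", "g9"}})
print(f"genes common to all three comparisons: {common[('J_A', 'J_S', 'J_O')]}\n")

# ANOVA + LSD letters across months for seed SuSy-II
sub = panels.query("organ == 'seed_kernels'")
groups = {m: g["SuSy_II"].to_numpy() for m, g in sub.groupby("month")}
letters = anova_lsd_letters(groups)
print("seed SuSy-II letters by month (shared letter = not significantly different):")
for month in ("Jul", "Aug", "Sep", "Oct"):
    print(f"  {month}: mean {groups[month].mean():8.1f} U/g  -> {letters[month]}")
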