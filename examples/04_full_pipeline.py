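"""One-command reproduction: simulate a study and run every stage.

Writes the synthetic inputs and all derived outputs (allocation table,
sugar profiles, correlation matrices, gene screen, DEG summary,
significance letters, manifest and plain-text report) into ./scratch.
"""

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from pulsechase.pipeline import run_all

outdir = Path("scratch/example_run")
cfg = Path("scratch/example_config.yaml")
cfg.parent.mkdir(parents=True, exist_ok=True)
cfg.write_text(resources.files("pulsechase.data").joinpath("default.yaml").read_text())

run_all(cfg, outdir)

alloc = pd.read_csv(outdir / "allocation.csv")
aug = alloc.query("month == 'Aug'").set_index("organ")["allocation_percent"]
print("August allocation of excess 13C recovered from noisy readings (%):")
print(aug.round(2).to_string())
manifest = json.loads((outdir / "manifest.json").read_text())
print(f"\nstages run: {manifest['stage_row_counts']}")
print(f"outputs in {outdir} (see report.txt for the allocation block "
      "and starred correlation matrices)")
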