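#!/usr/bin/env python
"""Depth-segmented elasticity per cell line.

Fits every pixel's retract curve in the two indentation windows
((0, 50] nm membrane, (50, 200] nm cortex) and summarises each map with the
10%-trimmed mean. Verifies the qualitative picture: the malignant line has
the stiffest membrane but the softest cortex. Writes results/elasticity.csv.
"""
import os

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from fdmech import RunConfig, fold_change, percent_change, process_map, read_dataset

base = os.path.join(os.path.dirname(__file__), "..", "results")
rows = []
for line in ("mcf10a", "mcf10at", "mcf10ca1a"):
    fv = read_dataset(os.path.join(base, "..", "scratch", "containers", f"{line}.h5"))
    fv = process_map(fv, RunConfig(events=False))
    e = fv.channels["e_pm"]
    c = fv.channels["e_cortex"]
    e, c = e[np.isfinite(e)], c[np.isfinite(c)]
    rows.append({
        "line": line,
        "e_pm_kpa": trim_mean(e, 0.10), "e_pm_sd": e.std(ddof=1),
        "e_cortex_kpa": trim_mean(c, 0.10), "e_cortex_sd": c.std(ddof=1),
        "e_pm_true": float(fv.scene.e_pm_true.mean()),
        "e_cortex_true": float(fv.scene.e_cortex_true.mean()),
        "n_pixels": int(e.size),
    })
df = pd.DataFrame(rows).set_index("line")
df.to_csv(os.path.join(base, "elasticity.csv"))
print(df.round(2))
print(f"\nmembrane fold change, malignant vs healthy: "
      f"{fold_change(df.loc['mcf10ca1a','e_pm_kpa'], df.loc['mcf10a','e_pm_kpa']):.2f}")
print(f"cortex decrease, healthy -> malignant: "
      f"{percent_change(df.loc['mcf10a','e_cortex_kpa'], df.loc['mcf10ca1a','e_cortex_kpa']):.1f}%")
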