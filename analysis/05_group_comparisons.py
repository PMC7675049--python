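#!/usr/bin/env python
"""Between-line statistics on per-map modulus summaries.

Treats each seeded map as one cell (its trimmed-mean modulus as the
per-cell value, the unit of analysis for group comparisons) and runs
one-way ANOVA with Tukey's HSD across the three lines for membrane and
cortex moduli. Writes results/comparisons.csv.
"""
import os

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from fdmech import RunConfig, anova_tukey, build_scene, process_map, simulate_map

SEED = 31
N_CELLS = 8
LINES = {"mcf10a": (5.3, 37.5), "mcf10at": (3.7, 20.5),
         "mcf10ca1a": (10.7, 15.9)}

pm_groups, cx_groups = {}, {}
for i, (line, (e_pm, e_cortex)) in enumerate(LINES.items()):
    pm, cx = [], []
    for cell in range(N_CELLS):
        seed = SEED + 100 * i + cell
        scene = build_scene(8, 8, coverage=0.0, e_pm_out=e_pm,
                            e_cortex=e_cortex, seed=seed)
        fv = process_map(simulate_map(scene, seed=seed), RunConfig(events=False))
        e = fv.channels["e_pm"]
        c = fv.channels["e_cortex"]
        pm.append(trim_mean(e[np.isfinite(e)], 0.10))
        cx.append(trim_mean(c[np.isfinite(c)], 0.10))
    pm_groups[line], cx_groups[line] = pm, cx
    print(f"{line}: E_pm {np.mean(pm):.2f} +/- {np.std(pm, ddof=1):.2f} kPa, "
          f"E_cortex {np.mean(cx):.2f} +/- {np.std(cx, ddof=1):.2f} kPa "
          f"(n={N_CELLS} cells)")

rows = []
for channel, groups in (("e_pm", pm_groups), ("e_cortex", cx_groups)):
    res = anova_tukey(groups)
    print(f"\n{channel}: ANOVA F={res['f']:.1f}, p={res['p']:.2e}")
    for pair in res["pairwise"]:
        print(f"  {pair.group_a} vs {pair.group_b}: "
              f"p={pair.p_value:.4f} ({pair.label})")
        rows.append({"channel": channel, "group_a": pair.group_a,
                     "group_b": pair.group_b, "p_value": pair.p_value,
                     "label": pair.label})
base = os.path.join(os.path.dirname(__file__), "..", "results")
pd.DataFrame(rows).to_csv(os.path.join(base, "comparisons.csv"), index=False)
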