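#!/usr/bin/env python
"""Simulate one force-volume map per cell line.

The three mammary epithelial lines are emulated with their measured
membrane/cortex moduli and cholesterol-domain coverages as ground truth:
MCF10A (healthy, soft membrane / stiff cortex, sparse domains), MCF10AT
(premalignant) and MCF10CA1a (malignant, stiff membrane / soft cortex,
dense domains). Containers land in scratch/containers/.
"""
import os

from fdmech import build_scene, simulate_map, write_dataset

SEED = 2026
LINES = {
    "mcf10a": dict(e_pm=5.3, e_cortex=37.5, coverage=0.054),
    "mcf10at": dict(e_pm=3.7, e_cortex=20.5, coverage=0.116),
    "mcf10ca1a": dict(e_pm=10.7, e_cortex=15.9, coverage=0.275),
}
GRID = 24

out_dir = os.path.join(os.path.dirname(__file__), "..", "scratch", "containers")
os.makedirs(out_dir, exist_ok=True)

for i, (line, p) in enumerate(LINES.items()):
    scene = build_scene(GRID, GRID, coverage=p["coverage"],
                        e_pm_in=p["e_pm"], e_pm_out=p["e_pm"],
                        e_cortex=p["e_cortex"], p_bind=1.0, seed=SEED + i)
    fv = simulate_map(scene, seed=SEED + i)
    path = os.path.join(out_dir, f"{line}.h5")
    write_dataset(fv, path)
    print(f"{line}: {GRID}x{GRID} map, realized domain coverage "
          f"{scene.coverage:.3f} (target {p['coverage']}), "
          f"{len(scene.events)} injected tether events -> {path}")
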