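# fdmech

Depth-segmented elasticity and single-molecule adhesion mapping for
force-volume AFM recordings on living cells.

Multiparametric force-distance (FD) AFM records one approach/retract force
curve per pixel. On a cell, the indentation response mixes two structures: a
soft plasma-membrane-dominated layer and the stiffer actin cortex beneath
it. With a ligand (here a cholesterol-binding toxin fragment) coupled to the
tip through a PEG linker, the retraction additionally carries
single-molecule unbinding events that map receptor-enriched membrane
domains. `fdmech` turns grids of raw curves into co-registered maps of
height, membrane and cortex Young's moduli, adhesion force and binding
specificity, plus the group statistics used to compare conditions — and
ships a synthetic force-volume generator with full ground truth so every
stage is testable without instrument data.

## Models

**Elasticity.** For a spherical tip of radius R indenting to depth δ the
Hertz model gives

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2},

so F^{2/3} is linear in δ. Young's modulus is extracted in two depth
windows: δ ∈ (0, 50] nm (membrane contribution, E_pm) and δ ∈ (50, 200] nm
(cortex, E_cortex); the deeper window is fit incrementally against the force
at the window entry. For thin layers on a stiff support the apparent
stiffening is corrected with the polynomial bottom-effect model

    F = (16E/9)·√R·δ^{3/2}·[1 + 0.884α + 0.781α² + 0.386α³ + 0.0048α⁴],
    α = √(Rδ)/h,

which reduces to the Hertz sphere with ν = 1/2 as α → 0.

**Adhesion.** Rupture candidates are sustained force dips below −3σ on the
baseline-corrected retract. Each candidate's extension profile is fit with
the Marko–Siggia worm-like chain F(x) = (kBT/Lp)[¼(1−x/Lc)⁻² − ¼ + x/Lc];
an event is *specific* when its rupture force exceeds 80 pN, its tip–sample
distance exceeds 5 nm and the tether fit is accepted. Map-level outputs:
binding probability (% of analyzed pixels with specific events),
connected-component domain sizes, and membrane elasticity stratified by
cholesterol (>100 pN events) vs non-adhesive (<30 pN) pixels.

## Worked example

```
$ fdmech simulate --rows 24 --cols 24 --coverage 0.275 --e-pm-in 13.1 \
      --e-pm-out 9.0 --e-cortex 15.9 --seed 777 --out map.h5
wrote map.h5: 24x24, realized coverage 0.274
$ fdmech mapstats map.h5 --out stats.json
```

or through the library (this is `analysis/04_stratified_elasticity.py`):

```
              e_pm_kpa    sd    n  true_kpa
stratum
cholesterol      13.64  2.91  135      13.1
non_adhesive      9.37  3.24  396       9.0

Mann-Whitney U two-tailed p = 1.54e-32 (****)
```

The pipeline recovered the membrane modulus of cholesterol-enriched pixels
(13.6 kPa vs 13.1 kPa injected) and of non-adhesive pixels (9.4 vs 9.0 kPa)
from 576 simulated curves at 15 pN noise, and the two strata separate
decisively. The numbered scripts under `analysis/` walk through the full
study: scene simulation per cell line, depth-segmented elasticity (membrane
fold change ≈ 2.1 between malignant and healthy lines, cortex decrease
≈ 57%), adhesion mapping (binding probabilities ≈ 5.4 / 11.3 / 25.5% at the
three coverages) and the between-line ANOVA/Tukey comparisons. Tables land
in `results/`.

## Layout

```
src/fdmech/       library: model, io, preprocess, contact, adhesion,
                  mapstats, stats, synthetic, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite incl. end-to-end acceptance checks
docs/format.md    HDF5 container schema
docs/methods.md   models, estimators, design choices, limitations
```
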