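# Methods

## Data model and units

A force-volume map is a grid of force-distance records, one per pixel, each
with an approach and a retract segment of (piezo displacement z, force F)
samples stored in time order. All computation uses nm, pN, kPa and N/m
(1 N/m = 1000 pN/nm; 1 kPa = 10⁻³ pN/nm²), fixed at the container boundary
to keep the contact-mechanics arithmetic free of SI-prefix errors. Grids are
0-based (row, col), row-major. The container schema is in `format.md`.

## Per-curve processing

**Baseline.** Raw curves carry a slowly varying drift; a 2nd-degree
polynomial is fit on the off-contact region and subtracted. The off-contact
region is initially the 30% of samples farthest from the surface
(`off_contact_fraction`). Because a quadratic fitted on ~30% of the ramp
extrapolates poorly over the remaining off-contact stretch, the baseline is
refit once (`baseline_iterations`) on the full region implied by the current
contact estimate, minus a 15 nm guard. Tether pulls are kept out of the
refit two ways: runs of at least two samples below −3 robust sigma within
80 nm of contact truncate the region below the pull, and any remaining
negative outliers are rejected before the final fit.

**Noise.** σ is the standard deviation of residuals about a straight-line
fit of the off-contact retract — a linear fit so that residual tilt does not
inflate the estimate. On the generator's white noise the estimator is
unbiased to <2%.

**Contact point.** The spec of the problem leaves the algorithm open; we use
a deterministic ratio-of-variances scan. For each candidate split w₀ the
curve is modelled as zero force before contact and a two-layer segmented
Hertz response after it (shallow stiffness C₁ to the 50 nm boundary,
deep stiffness C₂ beyond, force-continuous); both stiffnesses solve in
closed form, and the candidate minimising the total residual sum of squares
wins, followed by a 0.25 nm fine pass. Design points that matter:

* The scan runs on tip position w = z − F/k, so cantilever deflection does
  not skew deep candidates, and (by default) pools the approach and retract
  samples — both segments share the contact point, and the approach carries
  no adhesion features. Pooling cuts the error sd by ~√2.
* A single-layer (flat + Hertz) split model is biased by tens of nm on
  two-layer curves; the two-layer family brings the estimator into the
  Cramér–Rao regime (±1–4 nm at σ = 15 pN depending on layer contrast).
* Samples inside adhesion dips (below −3σ, dilated) are masked out of the
  scan; they are outside the model family and otherwise drag the split
  several nm toward the surface.
* Pixels whose maximum force stays below 5σ (`contact_min_snr`) are flagged
  no-contact and excluded from all derived channels (absent, never zero).

**Indentation.** δ = (z − z₀) − F/k, clipped at zero, retraction by default
(`fit_segment`).

## Elasticity estimators

`hertz_slope_fit` implements the textbook route: ordinary least squares of
F^{2/3} on δ through the origin, E = (3/4)(1−ν²)s^{3/2}/√R. This is exact on
clean data but Jensen-biased when per-sample noise is comparable to the
force scale (the 2/3 power of a noisy force is biased low, and shallow
membrane forces reach only ~27 pN against σ = 15 pN), so the
depth-segmented default (`fit_method="force"`) does least squares in force
space instead: F on δ^{3/2} through the origin for the membrane window, and
incrementally F − F(50 nm) on δ^{3/2} − 50^{3/2} for the cortex window, with
the entry force anchored on the measured mean within ±6 nm of the boundary.
Both routes coincide noise-free; the force-space route is unbiased under
additive noise. Windows default to the (0, 50] and (50, 200] nm depth
ranges; a curve that never reaches the deeper window yields a membrane value
only. With `bottom_effect=True` the shallow window instead fits the
polynomial thin-layer model (linear in E, closed form); the layer thickness
defaults to 50 nm — identifying "the layer" with the membrane window depth —
and is configurable, since the total-cell-height reading is equally
defensible.

**Map summary.** Per-pixel membrane estimates have a heavy right tail
(a contact point that errs deep lets cortex samples leak into the shallow
window), so map-level location is reported as the 10% trimmed mean; with it,
group values spanning 3.7–37.5 kPa are recovered within ~7% at σ = 15 pN,
while the plain mean fails by >30% for the softest membranes.

## Adhesion events

Detection operates on the baseline-corrected retract, outside contact:
runs of ≥2 consecutive samples below −3σ (merged across ≤2-sample gaps)
that return above −3σ within 5 samples. Two auxiliary rules handle edge
cases without raising the flat-noise false-alarm rate above ~2% per curve:
a single sample below −4.2σ qualifies, and a single sample below −3σ
qualifies when the two preceding samples already pull below −σ and the
force stays at baseline afterwards (steep tethers can place only one sample
below threshold). Candidates closer than 8 nm merge (a shallow pull split
by noise is one event), ordered by tip–sample distance
s = (z₀ − z) + F/k. The rupture force is the magnitude of the minimum with
a half-sample linear extrapolation along the pull (the true rupture lies
within one sample past the minimum; the raw minimum alone is biased ~19 pN
low); when the tether fit is accepted, the estimate is averaged with the
fitted model's force half a sample beyond the minimum, which halves the
classification flip rate at the 80 pN gate.

WLC validation fits the Marko–Siggia interpolation over (Lp, Lc) by
profiling: the amplitude kBT/Lp is closed-form for each Lc on a 96-point
grid with parabolic refinement — deterministic and fast enough for
hundred-map runs. kBT is taken at the acquisition temperature (4.28 pN·nm at
310 K). Acceptance requires ≥10 raw samples between the contact-side
crossing and the rupture, ≥5 usable samples after the extension filter, fit
RMS below 2σ, and Lc ∈ [5, 60] nm (linker + protein scale); Lp is bounded to
[0.1, 1.5] nm — without the bound a Hookean detachment is WLC-fittable at
small extension ratio. Rejections carry a reason code. Note the 2σ RMS rule
discriminates shape only when the misfit exceeds the noise floor: at
σ = 15 pN a 130 pN Hookean ramp is rejected in only ~25% of draws, at
σ = 5 pN deterministically.

Specificity: force > 80 pN AND distance > 5 nm AND WLC accepted. Strata:
*cholesterol* if a specific event exceeds 100 pN, *non-adhesive* if no
candidate reaches 30 pN, otherwise *indeterminate* (excluded from the
stratified comparison). When several specific events occur in one curve the
last rupture (largest distance) defines the pixel's adhesion-force channel.

## Map statistics and group tests

Binding probability = 100 × specific pixels / analyzed pixels (pixels with a
located contact; whole-grid denominator, cell masking is out of scope).
Domains are connected components of the specific mask, 8-connectivity by
default (irregular domains should not split at diagonal contacts). Group
comparisons follow the experimental conventions: one-way ANOVA + Tukey HSD
(scipy/statsmodels) for per-cell means, two-tailed Mann–Whitney U otherwise
— exact by enumeration for pooled n ≤ 12 (scipy's exact distribution when
untied), normal approximation with tie and continuity correction beyond;
the test choice is explicit, no automatic normality check. Significance
labels use strict thresholds: p < 0.05 (*), < 0.01 (**), < 0.005 (***),
< 0.001 (****), else "ns"; a boundary p takes the weaker label.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:

* **Acquisition defaults**: k = 0.1 N/m, R = 65 nm, ν = 0.5, setpoint
  750 pN, 100 nm pixels, 512 samples per segment, 310 K — all within the
  instrument ranges of the source experiments.
* **Scene**: clustered binding domains grown as random 8-connected blobs
  with sizes from a truncated power law (exponent 1.8, small domains most
  abundant) until a target coverage is met; the membrane modulus field takes
  one value inside domains and one outside, the cortex field is uniform.
* **Curve**: piecewise two-layer contact response, force-continuous at the
  50 nm boundary (incremental stiffness switches, force accumulates); the
  approach ramps until the setpoint is reached, so the curve maximum is the
  setpoint to within one sample; contact height 220 ± 10 nm per pixel.
  Second-degree drift (2 pN, 0.01 pN/nm, 2×10⁻⁵ pN/nm²) and white Gaussian
  noise, σ = 15 pN (under the instrument's typical 20 pN).
* **Events**: on domain pixels with probability `p_bind`, a WLC pull
  (Lp = 0.38 nm, Lc uniform in [10, 40] nm) solved against the cantilever
  (z(s) = z₀ − s − F_wlc(s)/k is monotone, so the tether profile interpolates
  without iteration), rupturing at a force drawn from N(130, 35) pN
  truncated positive. Ground truth (rupture force, separation, Lc, Lp, the
  domain mask, the true contact height) rides along in the container.
* **Determinism**: the scene uses `SeedSequence([seed])`; each pixel uses
  `SeedSequence([seed, row, col])`, so pixel streams are independent of
  traversal order and containers re-write byte-identically.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: PeakForce tapping dynamics and hydrodynamic drag,
viscoelastic approach/retract hysteresis, multiple bonds per pixel,
nonspecific adhesion, membrane tethers pulled from the cell itself, tilt or
piezo nonlinearity, and cell-boundary topography (contact height is a flat
field with jitter).

## Problem sizes and numerical choices

Monte-Carlo checks use 8×8 maps × 50 seeds per modulus pair for parameter
recovery, 500 single-event curves for detection statistics, and 100 seeded
64×64 maps (the three coverage targets cycled) for binding-probability
recovery; the acceptance script uses 8–24-pixel grids with a handful of
seeds per quantity. Binding-probability recovery is judged against each
map's ground-truth count of injected events that satisfy the printed
specificity rules — rupture forces are drawn from N(130, 35) truncated
positive, so ~8% of injected events are legitimately non-specific and the
raw domain coverage is not the right reference. Fit failures (nonpositive
slopes, non-converged windows) yield absent values, never zeros. Degenerate
inputs raise typed errors (`SchemaError`, `InsufficientDataError`,
`DomainError`, `ConfigError`) naming the offending field or key.

## Known limitations

* The membrane-window estimate is weakly identified per curve at σ = 15 pN
  (shallow forces ≲ 27 pN); per-pixel values scatter by ~25–100% and only
  map-level summaries are quantitative.
* Rupture forces carry an irreducible discretization noise (the rupture
  falls between samples; for steep tethers the force changes by up to
  ~70 pN per sample), so events near the 80 pN gate misclassify at a few
  percent and binding probabilities on dense maps read ~1 percentage point
  low relative to ground truth.
* The contact-point scan assumes the two-layer family with a fixed 50 nm
  boundary; strongly graded or viscoelastic responses would bias it.
* The bottom-effect layer thickness is a user choice; nothing in a single
  curve identifies it.
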