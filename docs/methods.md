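# Methods

This note records the model definitions, defaults and design choices the
package commits to, and what the synthetic study conditions do and do not
demonstrate.

## Statistical shape model

Each subject contributes m landmark coordinates stacked into a 3m-vector.
PCA (full SVD) yields the mean shape, an orthonormal 3m×k basis and n×k
scores with zero column means; defaults m = 69, n = 124, k = 40, with
k ≤ min(n−1, 3m) enforced. The score matrix is regressed on the four body
characteristics — gender (0 female / 1 male), age (years), height (m),
BMI (kg/m²) — by per-component least squares. The printed regression form
has no intercept; because PC scores are centered by construction, the
characteristics are centered on their training mean (and by default scaled
to unit SD) to make the intercept-free form well-posed. `raw_coef_`
applies the chain rule so coefficients can be read per raw unit.

Alignment: rigid Procrustes (iterative alignment to the re-estimated mean;
rotation and translation removed, **scale retained** — body size is signal
that height and BMI must explain) is the default mode, with `none`
available. Whether the source landmark frames need alignment depends on
how they were exported; the noiseless-recovery checks run with `none`
because the generator already places all subjects in one frame and the
true effect modes contain rotation-like components that Procrustes would
deliberately remove.

Identifiability: characteristics span 4 dimensions, so only the composite
landmark-space map `basis · A` (3m×4) is identifiable, not A in isolation
(the PCA basis is sign/rotation arbitrary in degenerate-eigenvalue
subspaces). Recovery tests therefore compare the composite map against the
generator's ground-truth tensor; on a noiseless population it is exact to
machine precision.

Design grid: the homogenized characteristic grid defaults to 2 genders ×
5 ages × 5 heights × 4 BMIs = 200 points, evenly spaced over age 10–90 yr,
height 1.45–1.95 m, BMI 15–35 kg/m²; a single-level axis sits at its range
midpoint. Only the total of 200 is externally fixed; the 2×5×5×4 split and
the ranges are this package's convention.

## TPS morphing

Kernel φ(r) = r (the 3-D biharmonic/TPS choice), affine part fitted
jointly, side conditions Σwᵢ = 0 and Σwᵢsᵢᵀ = 0. λ = 0 by default: the
intent of landmark morphing is exact interpolation; λ > 0 adds smoothing
with landmark residual non-decreasing in λ. The dense symmetric solve is
appropriate at m ≈ 69; the condition number is logged and warned above
1e12. Coplanar or duplicate landmarks raise with the offending rows named.
One global field displaces skull and brain nodes alike — no sliding or
contact handling — so interior element inversion is possible for extreme
targets and must be caught by the quality gates, not by the morph itself.

## Mesh quality and geometric error

"Jacobian" is implemented as the corner scaled Jacobian (solids: corner
edge-triad determinant normalized by edge lengths, minimum over corners,
tets evaluated at all 4 corners; shells: normalized corner cross product
signed by the mean element normal) and "Skew" as equiangular skew
(θₑ = 90° quad faces, 60° triangle faces; solids take the face maximum).
Both are rigid- and scale-invariant, which the change-rate oracles
exploit. Degenerate elements (zero-length edges) report −1 / 1 rather than
raising.

Change rate per element and metric: |q_morph − q_base| / max(|q_base|,
floor) with floor = 1e-3. On baselines containing *ideal* elements
(skew exactly 0, as in the synthetic brain lattice) the skew rate is
effectively an absolute change divided by the floor and becomes very large
for visually mild distortion; with realistic baselines whose elements are
imperfect the rate behaves as a relative measure. The gate defaults (mean
error < 4 mm, max < 5 mm, mean change < 5%, max < 10%, min scaled
Jacobian > 0.2) are all configurable.

Point-to-surface distance is the exact minimum over all triangles,
computed by a vectorized exhaustive scan (plane projection with
barycentric inside test, else nearest edge segment). At the fixture scales
used (≲10³ triangles) this is fast and is bit-equal to the scalar
closest-point oracle used in tests; a spatial index would change speed,
not values.

## CORA-style rating

The corridor sub-rating uses constant-width corridors derived from the
reference peak (inner a0 = 0.05, outer b0 = 0.5 of max|ref|), per-sample
linear scoring, averaged. The cross-correlation sub-ratings search integer
sample shifts within ±d_max·T (d_max = 0.12) maximizing Pearson ρ, with
ties preferring the smaller |shift|: shape = max(0, ρ*), size = ratio of
squared-signal integrals over the aligned window (min/max), phase =
1 − |shift|/(d_max·T). Weights: 0.5 corridor + 0.5 cross, and 0.5/0.25/0.25
shape/size/phase inside the cross group. Signals are linearly resampled
onto 1000 uniform points over the overlap window; the shift search stays
on the sample grid (no sub-sample refinement). These settings constitute
one fully specified variant of the corridor-plus-correlation family;
published scores obtained with other releases/settings are not comparable
and are not reproduced here.

## Injury classification and dataset

Peak brain von Mises stress bands: J1 [0,6), J2 [6,11), J3 [11,15),
J4 [15,27), J5 [27,∞) kPa. The half-open left-closed convention at the
printed boundaries is this package's documented choice (source notation
"0–6 … 6–11" is ambiguous at exact boundaries); a boundary value belongs
to the upper class.

The synthetic dataset emulates a full-factor simulation campaign:
1812 records over 9 speeds (20–60 km/h, 5 km/h steps) × 2 states
(0 pedestrian / 1 cyclist) = 18 cells of 100 records (+1 for the first
12 cells, since 1812 is not divisible by 18). Characteristics within cells
follow a deterministic van der Corput stratification (bases 2/3/5 for age,
BMI and the height quantile; alternating gender) plus small seed-dependent
jitter: this emulates factorial coverage of the characteristic space and
keeps subgroup prevalence statistics stable across seeds, which i.i.d.
sampling at n = 1812 cannot (binomial noise in a ~230-record age band is
~3 points per band).

Latent response: r = 0.8·(speed−20) + 0.050·age − 0.195·(bmi−25) +
tent(height) − 1.0·state + N(0, 0.5), with tent(h) = max(0, 1−|h−1.7|/0.15)
giving the deliberately non-monotone height effect; the realized values
are affinely rescaled so the dataset spans exactly 4.4–46.9 kPa
(calibration by construction). The age and BMI coefficients were set by
sweeping the generator until the severe-class (J5) prevalence gaps land at
~10 percentage points (age > 80 vs 10–20) and ~8 points (BMI 15–20 vs
30–35); measured over ten seeds they are 10.1 ± 0.6 and 8.1 ± 0.5 points.
The state term is subtracted so that pedestrians (state 0) have the higher
mean response. None of this is mechanistic: the generator encodes the
*trends* (direction, ordering, span, subgroup gaps), so passing tests
demonstrate that the analysis code measures what the generator encodes —
not that real collisions behave this way.

## Baseline mesh fixture

The baseline head is synthetic: an ellipsoidal quad-shell "skull"
(half-axes 75/95/85 mm, cube-surface grid projected to the sphere,
resolution 6 → 216 quads) around a perfect hexahedral lattice "brain"
(box inscribed in the ellipsoid, 4³ = 64 hexas), with 69 landmark nodes
spread over the shell by a golden-spiral direction set and a companion
triangulated skull surface sharing the shell nodes exactly. All elements
clear the 0.2 scaled-Jacobian gate by construction. It is a topology- and
metric-faithful stand-in for an anatomical head mesh, not an anatomical
model; absolute quality numbers (and the skew change-rate caveat above)
reflect its idealized elements.

## Prediction harness

Standardization statistics are always fitted on the training fold only and
applied to the held-out fold — the protocol source says only that data
"were standardized"; fitting per fold is chosen to preclude leakage.
Folds come from a shuffled k-fold partition (sizes differ by ≤1,
seed-reproducible). Grid search is exhaustive, scored by mean CV accuracy
(classification) or MSE (regression), ties broken by first-in-grid order.
Multi-class recall/F/AUC are macro-averaged (the averaging scheme is not
externally fixed; macro is the documented choice), with AUC computed from
the Mann–Whitney rank statistic per class one-vs-rest; classes absent from
the truth are excluded from macro averages with a warning. R² on
zero-variance truth is reported as 1.0 for a perfect fit (documented
convention) and NaN otherwise. Two reference estimators (k-NN classifier,
closed-form ridge) make the harness self-contained; any sklearn-style
estimator plugs in through fit/predict(_proba).

## Problem sizes and tolerances

Default problem sizes throughout (124×69 population, 216+64-element mesh,
1812-record dataset, 1000-sample signals) run the full suite in a few
seconds. Numerical tolerances in tests reflect the conditioning of each
operation: machine-precision-level (1e-8…1e-12) for direct linear algebra
(PCA, TPS, metrics), 1e-6 mm for morph/landmark fidelity, ±2 percentage
points for the stochastic prevalence gaps, grid-resolution accuracy
(±0.01) for the CORA phase shift.

## Known limitations

- The shape model is linear; no nonlinear shape effects, no automatic
  landmark detection.
- TPS morphing cannot repair inverted elements; validation only detects
  them.
- The keyword mesh dialect covers nodes, shell/solid elements, node sets
  and part names only — no materials, contacts or controls.
- The CORA variant is not an ISO/TS 18571 implementation.
- All empirical numbers produced here are properties of the synthetic
  generators, by design.
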