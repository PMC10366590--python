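# Methods

## Model overview

`broadvol` implements a deep-broad ensemble classifier for 3D volumetric
images.  The "deep" half is a 3D residual convolutional network whose
weights are drawn once from a seeded distribution and frozen — it is a
random feature extractor, never trained.  The "broad" half is a Broad
Learning System (BLS): random feature-mapping nodes and random enhancement
nodes concatenated into a state matrix `G = [D | E]`, with a single output
weight matrix solved in closed form,

    W = argmin ||Y − GW||² + λ||W||²  =  (λI + GᵀG)⁻¹ GᵀY.

The central claim this design embodies is that, with a sufficiently rich
random convolutional representation, the closed-form broad learner does the
decisive fitting work, so gradient-based pre-training of the deep module is
unnecessary.  Training cost is one matrix factorisation.

### Extractor architecture

| stage | blocks | channels | kernel / stride |
|---|---|---|---|
| stem conv | – | 64 | 7×7×7, stride (1,2,2) |
| stem avg-pool | – | 64 | 3×3×3, stride (2,2,2) |
| residual module 1 | 3 | 256 | bottleneck, stride 1 |
| global avg-pool | – | 256 | → shallow vector `x_d` |
| residual module 2 | 4 | 512 | bottleneck, stride (2,2,2) |
| global avg-pool | – | 512 | → deep vector `x_e` |

Module 2 consumes module 1's **pre-pool** tensor: the deep path is the
composition of both residual modules, `x_e = GAP(λ_e(λ_d(X_base)))`.
In ensemble mode the feature nodes read `x_d` and the enhancement nodes
read `x_e` directly (not `D`, as the classic BLS wiring would); classic
wiring remains available via `BLSConfig(mode="classic")` and is used for
plain tabular inputs.

**Stride scheme.** The reference stage sizes imply an unusual stem: for a
224×224×128 input the stem convolution halves only the last two axes
(224,112,64) and the pool then halves all three (112,56,32); module 1
preserves shape and module 2 halves all three (56,28,16).  The default
`stride_scheme="stem_aniso"` reproduces exactly these shapes — stem conv
(1,2,2), pool (2,2,2), module 1 stride 1, module 2 (2,2,2).  A
`"uniform"` alternative (stem conv (2,2,2)) is selectable in config.

**No normalisation layers.** The network is never trained, so there is
nothing for batch/instance norm to stabilise; omitting them keeps the
network exactly linear-homogeneous in the stem (useful invariants:
zero input → zero features, stem(αv) = α·stem(v)) and the variance of the
random features is controlled by He initialisation instead
(`he_normal`: std = √(2/fan_in); `he_uniform` available).  Biases are
zero.  Activations inside bottleneck blocks are ReLU; the bottleneck inner
width is `channels/4` (the standard 4× expansion), overridable — reducing
inner widths and stem channels shrinks compute without changing the
256/512 output dimensionality.

**Convolution numerics.** Convolutions use "same" zero padding (spatial
size depends only on stride, output = ⌈n/s⌉) and odd kernels.  Two compute
paths exist — offset-wise shift-and-matmul (small kernels) and per-channel
FFT (the 7×7×7 stem) — both verified against a brute-force nested-loop
reference to 1e-5 in the tests.  Default accumulation is float64; float32
is selectable.

### Broad learner

* `D = φ(X W_e + β_e)` with φ defaulting to identity (the mapping layer may
  be linear); `E = δ(S W_h + β_h)` with δ = tanh (the enhancement layer is
  non-linear by design).  Both are config keys
  (`identity/tanh/sigmoid/relu`).
* Random weights are uniform on [−1, 1], drawn group-wise (equal-width node
  groups, `total = groups × width`).  Enhancement weights are additionally
  scaled by `1/√(source_dim)`: with a 512-dimensional standardized source,
  unscaled uniform weights would push every tanh pre-activation deep into
  saturation and reduce E to signs.  The scale is exposed as
  `enh_weight_scale`.
* Inputs are standardized (train-set mean/sd, stored in the model) by
  default; raw pass-through via `standardize=False`.
* λ defaults to 1e-8: the closed form is the λ→0 limit of the ridge
  pseudo-inverse, and a tiny positive ridge keeps the solve well posed.
  The solve is a symmetric positive-definite factorisation of
  `λI + GᵀG`; no explicit inverse is formed.  scipy may warn that the
  system is ill-conditioned at this λ — that is expected and harmless at
  the sample sizes involved.
* **Sparse auto-coding** (optional, off by default): mapping weights can be
  refined by solving `min_W ||ZW − X||² + s·||W||₁` (Z = the random
  feature projection of the input) with ISTA soft-thresholding, max 50
  iterations, tolerance 1e-6 on the iterate change; with `s = 0` it reduces
  to plain least squares.  Non-convergence returns the best iterate with a
  warning.  The sparsity coefficient `s` is swept over [0.4, 0.7] in sweep
  mode.
* Hyperparameter sweep ranges (validated in `sweep_mode` and by
  `SweepGrid`): feature nodes 500–4000, enhancement nodes 100–1000,
  sparsity 0.4–0.7.  Outside sweep mode arbitrary values are allowed.
* Prediction: scores `GW`, labels by argmax with first-index tie-break.
  The softmax of the scores is exposed as a probability view — a monotone,
  calibration-free transform; ROC/AUC always use raw score margins.

## Preprocessing

Resample to isotropic voxels (default 1.5 mm, trilinear; nearest-neighbour
selectable for label maps), min–max scale intensities to (0, 1) globally
(optional percentile clipping, off by default), centre-crop to
224×224×128 with offsets ⌊(in−out)/2⌋.  Inputs smaller than the crop
target are symmetrically zero-padded so the pipeline is total on phantoms
of any size.  Volumes are used in native voxel order (a flag enables RAS
canonicalisation); a constant-valued volume maps to all-zeros with a
warning rather than NaN.

## Evaluation protocol

Per task (AD_vs_NC, AD_vs_MCI, MCI_vs_NC, three_class) the manifest is
split 0.7:0.3, stratified by class.  The default split granularity is the
**subject**: repeat scans of one subject never straddle the train/test
boundary, which avoids identity leakage when a dataset carries multiple
scans per patient.  `split_level="image"` reproduces the plain image-level
protocol; subject disjointness is asserted at run time either way.

Metrics from the confusion matrix (positive class first; AD positive in
AD-vs-NC and AD-vs-MCI, MCI positive in MCI-vs-NC): ACC, SEN, SPEC, PREC,
F1, with zero denominators reported as 0 and logged.  ROC is swept over the
positive-minus-negative score margin with trapezoidal AUC (scikit-learn).
Repeated runs report mean ± sd over seeds.  Wall-clock timings are logged
to stderr and kept out of the canonical JSON report so identical runs
produce byte-identical artifacts; fit time and total time are logged
separately since feature extraction dominates wall clock while the
closed-form fit is near-instant.

Extracted features are cached keyed by (voxel-data hash, extractor-config
hash); the extractor is frozen, so the cache is lossless and sweeps re-run
only the broad learner.

## Synthetic phantoms

The generator emulates the one property of staged disease the model should
exploit: a spatially structured, class-ordered morphological difference.
Each phantom is an ellipsoidal bright region (semi-axes 0.42 of the grid)
with a central dark cavity whose radius is
`(0.15 + 0.15·severity·effect_size)` of the smallest semi-axis, severity
NC=0, MCI=1, AD=2 — a ventricle-like enlargement.  Per-subject anatomy is
jittered (0.5% sd on semi-axes, 5% sd on cavity radius, ±1.5 voxel cavity
offset) so classes overlap realistically; i.i.d. Gaussian noise (default
sd 0.05) is added and intensities clipped at 0.  Defaults: 32³ voxels at
2.0 mm spacing — deliberately not 1.5 mm, so the resampling stage is
genuinely exercised end to end.

At `effect_size = 1` the classes are separable even by a logistic threshold
on mean intensity (the tests verify ≥ 0.95), which establishes that
downstream accuracy targets are attainable rather than vacuous; at
`effect_size = 0` the label has no effect on the noiseless image (equal
seeds give voxel-identical AD and NC phantoms), giving an exact null.
What passing phantom tests does **not** show: robustness to scanner
effects, Rician noise, registration error, anatomy beyond a single cavity,
or realistic class overlap — phantom accuracies are far above what any
clinical dataset would yield and are properties of the pipeline, not
clinical performance claims.

## Problem sizes used in tests and the acceptance script

Tests and the acceptance script run the complete method at desk scale,
chosen once as the smallest sizes that still exercise every stage: 40
phantoms per class at 32³ voxels, five 0.7:0.3 splits, and a
reduced-internal-width extractor (16 stem channels, 16-wide bottlenecks,
full 256/512 outputs).  The full-size shape contract (224×224×128 input
through the reference stage shapes) runs once at 4-wide internals, where the
spatial contract — which depends only on the stride scheme — is unchanged.

## Design choices where the design was open

* **Permutation null measurement.**  A closed-form ridge fit always retains
  some *training*-set memorisation of permuted labels through the hat
  matrix diagonal (≈ Φ(√(p_eff/n)) agreement), so the no-signal null is
  measured out-of-fit: fit on permuted labels on half the data, evaluate
  on the held-out half, where expected accuracy is exactly chance.  The
  low-capacity regime (effective dof ≪ n), where even training accuracy on
  permuted labels stays near chance, is covered separately in the unit
  tests.
* **BLS capacity for the Gaussian sanity check** is the default config;
  with 1000 feature + 500 enhancement nodes and λ = 1e-8 the learner
  interpolates n = 200 samples, so training accuracy on separable classes
  is 1.0 by construction.
* **Softmax as probability**: scores are not calibrated; the softmax view
  exists because users expect a probability-shaped output.
* **Enhancement source in ensemble mode** is `x_e` only; a hybrid mode
  (`[D | x_e]`) exists behind `hybrid_enhancement=True` but is not the
  default.
* **Tie-breaks** are deterministic (first class index); degenerate
  all-equal scores therefore predict class 0.

## Known limitations

* The extractor forward pass is pure numpy/scipy; at the full 64/256/512
  width and 224×224×128 input it is minutes-per-volume on one CPU.  The
  reduced-width configuration exists for exactly this reason, and feature
  caching amortises extraction across splits and sweeps.
* Incremental/added-node BLS updates (dynamic expansion) are not
  implemented — the ensemble model here is trained in one shot.
* Skull stripping, bias-field correction and template registration are out
  of scope of the preprocessing chain.
* Three-class evaluation reports accuracy and the 3×3 confusion matrix
  only; per-class ROC beyond score export is out of scope.
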