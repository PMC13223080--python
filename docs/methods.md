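# Methods

`aslnet` re-implements a perfusion-only deep-learning pipeline for two
clinical classification tasks in diffuse glioma: WHO grade (II / III / IV)
and 12-month overall survival (short `<12` vs long `>=12` months), using a
single arterial-spin-labeling (ASL) perfusion volume per patient plus a
small clinical table (age, sex, extent of resection).  Because the package
must be testable without any external imaging collection, every stage is
exercised on synthetic perfusion phantoms generated by the package itself.

## Preprocessing

ASL volumes carry no standardised intensity units, so every step is
designed to be scale-robust.

**ROI extraction.** The tumour is approximated by the centroid of the
brightest `0.01%` of voxels (`top_fraction = 1e-4`).  All voxels tied with
the k-th brightest are included; if that tie set degenerates to the whole
volume (the k-th value equals the background floor), only voxels strictly
above the floor are kept.  A cube of 70 mm per side (70 voxels at the 1 mm
isotropic default) is extracted around the rounded centroid, clamped — not
padded — at grid borders so every voxel is real data.  A constant volume
has no brightest set and is rejected.  Optional isotropic resampling and a
Gaussian pre-smooth (sigma 1 mm) can be applied before extraction.

**Background threshold `vf`.** Cubic subregions covering ~0.5% of the ROI
volume (side `round(S * 0.005^(1/3))`, at least 2 voxels) are scanned
exhaustively via an integral image; each window is scored `mean + sd`, and
`vf` is the maximum intensity inside the lowest-scoring window.  Voxels
`<= vf` are excluded from the robust statistics.  Limitation: when a cube
contains no genuinely low-intensity region, any max-of-a-window statistic
necessarily sits near the intensity bulk, so a large fraction of voxels is
flagged; the pipeline assumes an air margin or low-signal pocket exists,
which holds both for the phantoms and for whole-head acquisitions.

**Feature channels**, in fixed order:

0. raw cube;
1. global robust standardisation `(x - median) / (MAD + eps)`, median and
   raw MAD (no consistency constant) over foreground voxels only;
2. local standardisation in non-overlapping 15 mm tiles (edge tiles
   truncated), each tile by its own mean and sd;
3. `log1p(max(x - vf, 0))` — zero on background, monotone above it.

`eps` guards are `1e-6` times the relevant foreground intensity scale, so
constant regions map to zero rather than dividing by zero.  A fully
constant cube yields zero derived channels by construction.

**Augmentation** applies, in order: per-axis random flips, one rotation
drawn uniformly in ±10° about a random spatial plane (linear
interpolation), an elastic deformation from a coarse control grid (spacing
15 voxels, displacement sd 2 voxels, cubic upsampling of the displacement
field), and Rician noise `sqrt((x + n1)^2 + n2^2)`.  All channels receive
identical geometric transforms.  Rician — not Gaussian — noise matches the
magnitude-image noise distribution of MRI; its closed forms (Rayleigh mean
`sigma * sqrt(pi/2)` at zero signal, second moment `x^2 + 2 sigma^2`) are
used as test oracles.

## Networks

Both classifiers share a 3-D residual trunk implemented in numpy with
hand-written backpropagation (im2col convolutions, group normalisation,
max-pooling, decoupled-weight-decay Adam): the package targets small,
CPU-scale experiments and carries no deep-learning-framework dependency.

* **Stem:** 7x7x7 convolution, stride 2 → GroupNorm → ReLU → 3x3x3
  max-pool, stride 2.
* **Stages 1–4:** configurable numbers of residual blocks (3x3x3
  convolutions, GroupNorm, ReLU, projection shortcuts where shape
  changes); the first blocks of stages 2–4 downsample with stride 2; the
  filter width doubles per stage.  An optional bottleneck block variant is
  available.
* **Head:** global average pooling → dropout → softmax.

Padding is "same" with ceil division at strided layers, which gives the
spatial trace 70 → 35 → 18 → 18 → 9 → 5 → 3 for a 70-voxel input.  Weights
use He/Glorot initialisation with zero biases.

The survival network adds intermediate fusion by feature-wise linear
modulation (FiLM): age (z-scored), sex, and one-hot extent of resection
pass through a small MLP (one hidden layer of 16, dropout 0.2) that emits
one `(gamma, beta)` pair per conditioned stage, applied channel-wise after
the final block of each of the last three stages.  `gamma` is parameterised
as `1 + delta` with the MLP output layer zero-initialised, so training
starts exactly at the identity modulation — a property the tests assert
bit-for-bit.  Clinical covariates reach the graph only through these
pairs.  FiLM is applied once per conditioned stage (after its last block),
the simpler of the two readings of "applied to the outputs of the last
three residual stages".

Two presets are provided: the full-resolution preset (70³ input, 16
initial filters, 2 blocks per stage) and a desk preset (32³ input, 8
initial filters, 1 block per stage) that keeps cross-validated training on
one CPU in minutes.  Both keep the 7³ stem.

## Training

Patient-level stratified k-fold cross-validation (default k = 5; each
patient is one group, so the stratified split is the grouped split and no
subject can appear on both sides).  Per fold: AdamW (lr 1e-3, weight decay
1e-4), label-smoothed cross-entropy (eps = 0.1), batch size 8.  The held
fold is monitored each epoch with macro one-vs-rest AUC (falling back to
the defined classes, then to negative log-likelihood, if a class is absent
from the fold); the learning rate halves after a patience of 2 epochs
without improvement, training stops early after 5, and the best-epoch
weights are restored.  Every patient receives exactly one out-of-fold
probability.  Train-time augmentation (an `AugmentPolicy` on the training
configuration) draws a fresh transform per sample per epoch; it is off in
the desk-scale experiments, whose phantoms already carry Rician noise.

Decision rules are calibrated post hoc on the out-of-fold predictions:

* **survival:** the probability threshold maximising F1 of the short-OS
  class, searched over midpoints of consecutive distinct probabilities
  (ties toward the lower threshold);
* **grade:** per-class scaling of `argmax(s ⊙ p)` maximising macro-F1 with
  `s_1 = 1`, over a 33-point log grid in [0.25, 4].  With three classes the
  full grid is enumerated (exactly the grid optimum); coordinate descent
  is used beyond that.

## Metrics

Macro one-vs-rest AUC (midrank tie handling), accuracy, and
support-weighted precision/recall/F1 delegate to scikit-learn; their
definitions are pinned by independent oracles in the tests (exhaustive
pair counting, hand confusion-matrix arithmetic, the weighted-recall ≡
accuracy identity).  Confidence bands use the percentile bootstrap over
patient-level resamples (default 2000; degenerate one-class resamples are
skipped and counted).  Cohort descriptive tables report per-category
counts and percentages (one decimal, half-up rounding) including an
explicit "empty" category; partition balance uses Pearson chi-squared
without continuity correction for categorical variables (with a
permutation fallback when an expected cell drops below 1) and the
Mann-Whitney test for continuous ones.

## Explainability

**Integrated gradients** accumulate the model gradient along the straight
path from a baseline to the input using the midpoint Riemann rule
(default 128 steps); the target is the predicted class's probability, and
the completeness gap `|sum(IG) - (f(x) - f(baseline))|` is reported with
every map.

The default baseline is the Gaussian-blurred input (sigma = side/4), not
a zero volume, for a structural reason: group normalisation at inference
standardises each sample's activations, which makes the trunk *exactly*
invariant to a positive global rescaling of its input (the conv biases
are erased by the normalisation).  Along the ray from an all-zero — or
any spatially constant — baseline, the model output is therefore constant
except in a boundary layer near the origin (empirically alpha < 0.002),
which no fixed-step quadrature can resolve: measured completeness gaps
with a zero baseline exceeded 30% of the prediction difference and did
not shrink with more steps.  Blurring instead destroys the focal
perfusion structure while preserving the intensity scale, so the path is
well-posed end to end; attributions then quantify the contribution of
fine-scale perfusion structure over its smoothed surrogate, and measured
completeness gaps fall to a fraction of a percent at 128 steps.  A zero
(or any custom) baseline remains available as an argument.  Relative
completeness is only meaningful on samples whose prediction actually
moves away from the baseline's, so end-to-end checks evaluate it on the
samples with the largest `|f(x) − f(baseline)|`.

**Exact Shapley values** treat input blocks as players — the four image
channels, plus the clinical vector as a fifth player for the survival
model.  A coalition's value is the target-class probability with absent
blocks replaced by baseline; all `2^p` coalitions are evaluated (guarded
at p ≤ 8), so efficiency, symmetry, and dummy axioms hold to numerical
precision.  Shares are reported as `|phi|` normalised per sample, then
averaged over samples.  Saliency overlays default to an inverted colormap
(cooler colours = higher attribution), with a flag for the conventional
direction.

## Decision-curve analysis

Net benefit at threshold probability `pt` is
`TP/N - (FP/N) * pt/(1 - pt)` for the decision "act when the predicted
probability ≥ pt", compared with treat-all
(`pi - (1 - pi) * pt/(1 - pt)`) and treat-none (0) over a default grid of
0.01…0.99.  For the three-class grade task, the analysis collapses to a
chosen class pair (e.g. grade II vs IV) with renormalised probabilities;
which class is "positive" is a clinical framing the caller must choose —
both directions are supported and none is silently assumed.

## Synthetic phantoms

Each phantom is a smooth brain-level field (mean 1.0, sd 0.1 after
Gaussian smoothing) inside a soft elliptical brain mask with a near-zero
air margin, plus an axis-aligned ellipsoidal tumour whose rim intensity is
`multiplier x brain mean` — multipliers 1.6 / 2.4 / 3.6 for classes
II / III / IV, chosen well-separated relative to the rim-vs-background
contrast so class labels are recoverable from ROI intensity — an optional
low-signal necrotic core (probability 0.3), and Rician noise (sigma 0.05).
Tumour radii are drawn uniformly (default 8–12 mm; 6–9 mm in the
desk-scale experiments on 48³ grids).  Survival labels follow a logistic
link on grade (intercept −0.4; coefficients −2.2 / −0.3 / +1.2), and short
survivors receive +8 years on a Normal(56, 12) age draw, so the survival
task has both an imaging and a clinical signal.  Everything is
deterministic given (spec, seed).

What the phantoms do **not** emulate: pCASL physics (labeling delay, T1
relaxation), anatomy-faithful brain templates, scanner- or site-dependent
intensity distributions, and partial-volume or motion artefacts.  Passing
the phantom experiments demonstrates that the pipeline's machinery —
ROI extraction, channel engineering, cross-validated training, FiLM
fusion, attribution, decision analysis — works end to end and can recover
a known perfusion-encoded signal; it says nothing about discrimination on
real cohorts.

## Desk-scale experiment sizes

The reference signal-recovery experiment uses 120 phantoms on 48³ grids
with 32³ ROIs, three folds, and at most 10 epochs with early stopping
(patience 3); the grade task is averaged over three seeded cohorts.  These
sizes are the package's own desk-scale choice: they keep a full
cross-validated run of both networks in single-digit minutes on one CPU
core while leaving the recovered out-of-fold AUC comfortably above chance.
k = 3 (rather than the library default k = 5) keeps per-fold training sets
at 80 volumes.

## Numerical choices and degenerate inputs

* float32 throughout the network engine; parameter gradients verified
  against finite differences, and piecewise-linear layers (conv, pool)
  against exact directional derivatives.
* `eps` guards: `1e-5` inside GroupNorm; `1e-6 x` intensity scale in the
  channel ops; probability floor `1e-12` in every log.
* Ties: midrank credit in AUC; first-in-scan-order window in the `vf`
  scan; strict-improvement-only updates in both decision-rule searches
  (so an already-optimal identity rule is retained); lower threshold
  preferred in F1 threshold tuning.
* Degenerate inputs are either labeled errors (constant volume in ROI
  extraction, one-class inputs to ROC/threshold tuning, FiLM length
  mismatches) or well-defined fixed points (constant cubes → zero derived
  channels; treat-none ≡ all-negative predictions).

## Known limitations

* The numpy engine is single-threaded BLAS-bound; the full 70³ preset is
  supported but intended for inference-scale checks, not long training.
* `vf` estimation presumes some low-intensity region exists (see above).
* Exact Shapley is exponential in players and deliberately capped at 8.
* Bootstrap percentile intervals undercover slightly at small n, as usual;
  the coverage test pins the seeded behaviour rather than asymptotics.
* Phantom realism limits are listed above; reported AUCs on phantoms are
  not comparable to AUCs on clinical cohorts.
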