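# aslnet

Perfusion-only deep learning for diffuse glioma: 3-D residual networks
that classify WHO grade (II / III / IV) and 12-month overall survival from
a single arterial-spin-labeling (ASL) perfusion MRI volume, with
game-theoretic explainability and decision-curve analysis.  The package is
aimed at researchers who want a fully automated, segmentation-free
perfusion pipeline that is testable end to end without any external
imaging collection: a built-in phantom generator produces ASL-like
cohorts whose tumour rim perfusion encodes the class labels.

## What it implements

* **Preprocessing** — automatic ROI extraction (centroid of the brightest
  0.01% of voxels, 70 mm cube), a per-scan background threshold `vf` from
  small low-intensity uniform subregions, and four aligned feature
  channels: raw, global median/MAD standardisation, local 15 mm-tile
  standardisation, and `log1p(max(x − vf, 0))`; augmentation by flips,
  ±10° rotations, elastic deformation, and Rician noise.
* **Networks** — a 3-D residual trunk (7³ stem conv stride 2, GroupNorm,
  ReLU, 3³ max-pool stride 2; four stages of 3³-conv residual blocks with
  doubling widths; GAP → dropout → softmax), and a survival variant whose
  last three stages are conditioned on age / sex / extent-of-resection
  through feature-wise linear modulation (FiLM): per-channel
  `γ ⊙ x + β` pairs emitted by a small MLP, initialised at the identity.
  Implemented in numpy with hand-written backpropagation.
* **Training** — patient-level stratified k-fold cross-validation, AdamW,
  label-smoothed cross-entropy, macro one-vs-rest AUC monitoring with
  ReduceLROnPlateau and early stopping, best-epoch restoration, and
  post-hoc decision calibration on out-of-fold predictions (F1-optimal
  threshold for survival; macro-F1-optimal per-class scaling for grade).
* **Metrics** — macro OvR AUC `= (1/K) Σ_c AUC(c vs rest)`, weighted
  precision/recall/F1, percentile-bootstrap confidence bands, descriptive
  cohort tables, and partition balance tests (χ², Mann-Whitney).
* **Explainability** — integrated gradients (midpoint rule, completeness
  gap reported) and exact Shapley attribution over input blocks (4 image
  channels, + clinical vector for the survival model; all 2^p coalitions).
* **Decision-curve analysis** — net benefit
  `TP/N − (FP/N)·p_t/(1 − p_t)` against treat-all and treat-none.

See `docs/methods.md` for the model details, parameter defaults, and what
the phantom experiments do and do not demonstrate.

## Worked example

Generate a phantom cohort, fit the grade classifier with 3-fold
patient-level cross-validation, and summarise the out-of-fold results:

```python
from aslnet.phantom import PhantomSpec, CovariateModel, generate_cohort
from aslnet.model import AslNetModel
from aslnet.train import TrainConfig

spec = PhantomSpec(grid_shape=(48, 48, 48), tumor_radius_mm=(6.0, 9.0))
cohort = generate_cohort(spec, 60, (1/3, 1/3, 1/3), CovariateModel(), seed=7)
model = AslNetModel.from_cohort(
    cohort, "grade",
    train_config=TrainConfig(max_epochs=8, early_stop_patience=3, seed=7),
    k=3)
results = model.fit()
print(results.summary())
```

```
ASLNet grade model — 60 patients, 3-fold patient-level CV
classes: ('II', 'III', 'IV')
net: input 32^3 x 4, filters (8, 16, 32, 64), blocks (1, 1, 1, 1)
------------------------------------------------------------
out-of-fold macro OvR AUC : 0.887
accuracy                 : 0.733
weighted precision       : 0.737
weighted recall          : 0.733
weighted F1              : 0.735
class scaling factors    : [1.000, 0.648, 1.834]
per-fold best val AUC    : 0.964, 0.962, 0.858
```

The macro OvR AUC of 0.887 says the network recovered the rim-perfusion
ordering that encodes grade in the phantoms; the class scaling factors are
the post-hoc calibration that rebalances the argmax decision (here,
boosting the under-scored grade-IV-like class); accuracy and the weighted
metrics are computed from the calibrated out-of-fold decisions.
`results.predict_proba(...)` applies the restored per-fold networks to new
volumes, and `aslnet.explain.exact_shapley` / `integrated_gradients`
attribute any prediction to channels and voxels.

A command-line interface mirrors the library
(`aslnet simulate | preprocess | train | evaluate | explain | dca |
run-all`), writing NIfTI volumes, CSV tables, and a JSON run manifest.

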