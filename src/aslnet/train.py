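"""Patient-level cross-validated training and post-hoc decision calibration.

Folds are stratified at the patient level (each patient is a group, so no
subject appears on both sides of any split).  Each fold trains with AdamW
on label-smoothed cross-entropy, monitors macro one-vs-rest AUC on the held
fold, halves the learning rate on plateau, stops early, and restores the
best-epoch weights; every patient receives exactly one out-of-fold
probability.  Decision rules are then calibrated on those out-of-fold
predictions: a probability threshold maximising F1 for the binary survival
task, or per-class scaling factors maximising macro-F1 for the grade task.
The held-out test set is simply never passed to any function in this
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from ._nn import AdamW, softmax
from .preprocess import AugmentPolicy

__all__ = ["SplitPlan", "TrainConfig", "DecisionRule", "TrainResult",
           "make_folds", "smoothed_cross_entropy", "train_model",
           "tune_threshold", "fit_class_scaling"]


@dataclass
class SplitPlan:
    fold_of_patient: dict
    k: int
    strat_label: dict

    def __post_init__(self):
        folds = set(self.fold_of_patient.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold indices must lie in [0, k)")

    def patients_in_fold(self, f: int) -> list:
        return [p for p, ff in self.fold_of_patient.items() if ff == f]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    label_smoothing: float = 0.1
    max_epochs: int = 50
    early_stop_patience: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    min_lr: float = 1e-5
    batch_size: int = 8
    seed: int = 0
    augment: "AugmentPolicy | None" = None  # per-sample train-time augmentation

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label smoothing must be in [0, 0.5)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class DecisionRule:
    """Calibrated post-hoc decision rule for one task."""

    task: str  # "os" | "grade"
    threshold: float | None = None
    class_scales: np.ndarray | None = None

    def __post_init__(self):
        if (self.threshold is None) == (self.class_scales is None):
            raise ValueError("exactly one of threshold / class_scales must be set")
        if self.threshold is not None and not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.class_scales is not None:
            self.class_scales = np.asarray(self.class_scales, dtype=float)
            if np.any(self.class_scales <= 0):
                raise ValueError("class scales must be positive")

    def apply(self, probs: np.ndarray) -> np.ndarray:
        probs = np.asarray(probs, dtype=float)
        if self.threshold is not None:
            p = probs[:, 1] if probs.ndim == 2 else probs
            return (p >= self.threshold).astype(int)
        return np.argmax(probs * self.class_scales, axis=1)


@dataclass
class TrainResult:
    fold_predictors: list
    oof_probs: pd.DataFrame  # one row per patient: patient_id, fold, p0..pK-1
    history: pd.DataFrame    # fold, epoch, train_loss, val_auc, lr
    plan: SplitPlan


def make_folds(patients: pd.DataFrame, strat_label: str, k: int,
               seed: int = 0) -> SplitPlan:
    """Stratified group k-fold at the patient level (no subject leakage)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    ids = patients["patient_id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    y = patients[strat_label].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        warnings.warn(
            f"classes with fewer than k={k} members: "
            f"{counts[counts < k].index.tolist()}; folds for them are "
            "as balanced as the counts allow")
    # one row per patient: stratified k-fold on patients IS the grouped split
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = {}
    for f, (_, test_idx) in enumerate(splitter.split(ids, y)):
        for i in test_idx:
            fold_of[ids[i]] = f
    return SplitPlan(fold_of_patient=fold_of, k=k,
                     strat_label=dict(zip(ids, y)))


def smoothed_cross_entropy(probs: np.ndarray, label: int, eps: float) -> float:
    """Cross-entropy against the smoothed target (1-eps)*onehot + eps/K."""
    p = np.asarray(probs, dtype=float)
    k = p.shape[-1]
    q = np.full(k, eps / k)
    q[label] += 1.0 - eps
    return float(-(q * np.log(np.maximum(p, 1e-12))).sum())


def _val_monitor(probs: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Macro OvR AUC; falls back to the classes whose AUC is defined, then
    to negative cross-entropy when no class has both outcomes in the fold."""
    aucs = []
    for c in range(k):
        y = (labels == c)
        if 0 < y.sum() < len(y):
            from sklearn.metrics import roc_auc_score
            aucs.append(roc_auc_score(y.astype(int), probs[:, c]))
    if aucs:
        return float(np.mean(aucs))
    p_true = np.maximum(probs[np.arange(len(labels)), labels], 1e-12)
    return float(np.mean(np.log(p_true)))


def _smoothed_targets(labels: np.ndarray, k: int, eps: float) -> np.ndarray:
    q = np.full((len(labels), k), eps / k, dtype=np.float32)
    q[np.arange(len(labels)), labels] += 1.0 - eps
    return q


def train_model(features: np.ndarray, labels: np.ndarray, patient_ids,
                plan: SplitPlan, net_builder, tc: TrainConfig,
                clinical: np.ndarray | None = None,
                verbose: bool = False) -> TrainResult:
    """Cross-validated training; returns per-fold models and OOF probabilities.

    ``net_builder(seed) -> Predictor`` constructs a fresh network per fold.
    ``features`` is (N, S, S, S, 4); ``clinical`` is the optional (N, 5)
    covariate matrix for the survival network.  Only the training pool may
    be passed here — there is deliberately no argument for test data.
    """
    ids = np.asarray(patient_ids)
    if set(ids) != set(plan.fold_of_patient):
        raise ValueError("split plan does not cover exactly the given patients")
    labels = np.asarray(labels, dtype=int)
    folds = np.array([plan.fold_of_patient[p] for p in ids])

    oof = None
    predictors, hist_rows = [], []
    for f in range(plan.k):
        tr = np.where(folds != f)[0]
        va = np.where(folds == f)[0]
        rng = np.random.default_rng(tc.seed * 10007 + f)
        pred = net_builder(int(rng.integers(2 ** 31)))
        k_classes = pred.net.config.n_classes
        if oof is None:
            oof = np.full((len(ids), k_classes), np.nan)
        opt = AdamW(pred.net.params(), lr=tc.lr, weight_decay=tc.weight_decay)
        best_auc, best_state, since_best, since_plateau = -np.inf, None, 0, 0

        for epoch in range(tc.max_epochs):
            order = rng.permutation(tr)
            losses = []
            for i in range(0, len(order), tc.batch_size):
                idx = order[i:i + tc.batch_size]
                xb = features[idx]
                if tc.augment is not None:
                    from dataclasses import replace as _dc_replace
                    from .preprocess import FeatureStack, augment_sample
                    xb = np.stack([
                        augment_sample(
                            FeatureStack(channels=xb[j]),
                            _dc_replace(tc.augment,
                                        seed=int(rng.integers(2 ** 31)))
                        ).channels
                        for j in range(len(xb))])
                clin = None if clinical is None else clinical[idx]
                logits = pred.net.forward_logits(xb, clin, train=True)
                p = softmax(logits)
                q = _smoothed_targets(labels[idx], k_classes, tc.label_smoothing)
                loss = float(-(q * np.log(np.maximum(p, 1e-12))).sum() / len(idx))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss in fold {f} epoch {epoch} "
                        f"(seed {tc.seed}): aborting fold")
                losses.append(loss)
                opt.zero_grad()
                pred.net.backward(((p - q) / len(idx)).astype(np.float32))
                opt.step()

            va_clin = None if clinical is None else clinical[va]
            va_probs = pred.predict_proba(features[va], va_clin,
                                          batch_size=tc.batch_size)
            val_auc = _val_monitor(va_probs, labels[va], k_classes)
            hist_rows.append({"fold": f, "epoch": epoch,
                              "train_loss": float(np.mean(losses)),
                              "val_auc": val_auc, "lr": opt.lr})
            if verbose:
                print(f"fold {f} epoch {epoch}: loss {np.mean(losses):.4f} "
                      f"val AUC {val_auc:.3f} lr {opt.lr:.2e}")

            improved = np.isfinite(val_auc) and val_auc > best_auc + 1e-6
            if not np.isfinite(val_auc):
                raise RuntimeError(
                    f"non-finite validation monitor in fold {f} epoch {epoch} "
                    f"(seed {tc.seed})")
            if improved:
                best_auc, best_state = val_auc, pred.get_state()
                since_best = since_plateau = 0
            else:
                since_best += 1
                since_plateau += 1
                if since_plateau > tc.plateau_patience:
                    opt.lr = max(opt.lr * tc.plateau_factor, tc.min_lr)
                    since_plateau = 0
                if since_best > tc.early_stop_patience:
                    break

        if best_state is not None:
            pred.set_state(best_state)
        va_clin = None if clinical is None else clinical[va]
        oof[va] = pred.predict_proba(features[va], va_clin,
                                     batch_size=tc.batch_size)
        predictors.append(pred)

    oof_df = pd.DataFrame({"patient_id": ids, "fold": folds})
    for c in range(k_classes):
        oof_df[f"p{c}"] = oof[:, c]
    return TrainResult(fold_predictors=predictors, oof_probs=oof_df,
                       history=pd.DataFrame(hist_rows), plan=plan)


def tune_threshold(oof_probs, labels) -> DecisionRule:
    """Threshold on the positive-class probability maximising its F1.

    Candidates are the midpoints between consecutive distinct sorted
    probabilities plus one value below the minimum; ties are broken toward
    the lower threshold.
    """
    p = np.asarray(oof_probs, dtype=float)
    if p.ndim == 2:
        p = p[:, 1]
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold tuning requires both classes present")
    uniq = np.unique(p)
    candidates = [max(uniq[0] / 2.0, 1e-9)]
    candidates += [float((a + b) / 2.0) for a, b in zip(uniq, uniq[1:])]
    best_t, best_f1 = None, -1.0
    for t in candidates:
        f1 = f1_score(y, (p >= t).astype(int), zero_division=0)
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = t, f1
    best_t = min(max(best_t, 1e-9), 1.0 - 1e-9)
    return DecisionRule(task="os", threshold=float(best_t))


def fit_class_scaling(oof_probs, labels, grid_lo: float = 0.25,
                      grid_hi: float = 4.0, grid_points: int = 33,
                      passes: int = 2) -> DecisionRule:
    """Per-class scaling of argmax decisions maximising macro-F1.

    The first class's scale is fixed to 1; the others range over a
    log-spaced grid.  With up to three classes the full grid is enumerated
    (the search is then exactly the grid optimum); beyond that, coordinate
    descent over the same grid.  Deterministic: a candidate replaces the
    incumbent only on strict improvement, so already-optimal all-ones
    scales are retained.
    """
    p = np.asarray(oof_probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size == 0:
        raise ValueError("empty probability input")
    if len(np.unique(y)) < 2:
        raise ValueError("class scaling requires at least two classes present")
    k = p.shape[1]
    grid = np.exp(np.linspace(np.log(grid_lo), np.log(grid_hi), grid_points))
    scales = np.ones(k)

    def score(s):
        return f1_score(y, np.argmax(p * s, axis=1), average="macro",
                        zero_division=0)

    best = score(scales)
    if k <= 3:
        import itertools
        for combo in itertools.product(grid, repeat=k - 1):
            trial = np.concatenate([[1.0], combo])
            f1 = score(trial)
            if f1 > best + 1e-12:
                best, scales = f1, trial
    else:
        for _ in range(passes):
            for c in range(1, k):
                for g in grid:
                    trial = scales.copy()
                    trial[c] = g
                    f1 = score(trial)
                    if f1 > best + 1e-12:
                        best, scales = f1, trial
    return DecisionRule(task="grade", class_scales=scales)
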