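"""High-level modelling interface.

``AslNetModel`` bundles a preprocessed cohort with an architecture and a
training configuration; ``fit()`` runs patient-level cross-validated
training and returns an ``AslNetResults`` carrying the per-fold networks,
out-of-fold probabilities, the calibrated decision rule, and summary
metrics — analogous to the model/results split of statistical modelling
packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .net import (DESK_PRESET, MlpConfig, NetConfig, build_grade_net,
                  build_os_net, encode_clinical)
from .phantom import GRADE_CLASSES, SyntheticCohort
from .preprocess import build_feature_stack, extract_roi
from .train import (DecisionRule, TrainConfig, TrainResult, fit_class_scaling,
                    make_folds, train_model, tune_threshold)

__all__ = ["AslNetModel", "AslNetResults", "OS_CLASSES"]

# index 1 is the "short" (<12 months) class: the positive decision class
OS_CLASSES = ("long", "short")


def _replace(cfg: NetConfig, **kw) -> NetConfig:
    from dataclasses import replace
    return replace(cfg, **kw)


@dataclass
class AslNetModel:
    """A perfusion classifier specification bound to its training pool."""

    features: np.ndarray          # (N, S, S, S, 4)
    labels: np.ndarray            # integer class indices
    patient_ids: np.ndarray
    task: str                     # "grade" | "os"
    class_order: tuple[str, ...]
    net_config: NetConfig
    train_config: TrainConfig = field(default_factory=TrainConfig)
    clinical: np.ndarray | None = None
    k: int = 5

    def __post_init__(self):
        if self.task not in ("grade", "os"):
            raise ValueError("task must be 'grade' or 'os'")
        if self.features.shape[1] != self.net_config.input_side:
            raise ValueError(
                f"feature side {self.features.shape[1]} != "
                f"net input_side {self.net_config.input_side}")
        if self.task == "os" and self.clinical is None:
            raise ValueError("survival task requires a clinical matrix")

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, task: str,
                    net_config: NetConfig | None = None,
                    train_config: TrainConfig | None = None,
                    k: int = 5, top_fraction: float = 1e-4) -> "AslNetModel":
        """Preprocess every volume of a cohort into model-ready features."""
        if net_config is None:
            net_config = _replace(DESK_PRESET,
                                  n_classes=3 if task == "grade" else 2)
        voxel_mm = cohort.volumes[0].voxel_mm
        cube_mm = net_config.input_side * voxel_mm
        stacks, keep = [], []
        for i, vol in enumerate(cohort.volumes):
            roi = extract_roi(vol, top_fraction=top_fraction, cube_mm=cube_mm)
            stacks.append(build_feature_stack(roi).channels)
            keep.append(i)
        clin_df = cohort.clinical.iloc[keep].reset_index(drop=True)
        features = np.stack(stacks)

        if task == "grade":
            order = tuple(c for c in GRADE_CLASSES
                          if c in set(clin_df["grade"]))
            labels = np.array([order.index(g) for g in clin_df["grade"]])
            clinical = None
        else:
            order = OS_CLASSES
            labels = np.array([order.index(s) for s in clin_df["os_label"]])
            age = clin_df["age"].to_numpy(dtype=float)
            clinical = encode_clinical(clin_df, age.mean(), age.std())
        return cls(features=features, labels=labels,
                   patient_ids=clin_df["patient_id"].to_numpy(),
                   task=task, class_order=order, net_config=net_config,
                   train_config=train_config or TrainConfig(),
                   clinical=clinical, k=k)

    def _builder(self):
        if self.task == "grade":
            return lambda s: build_grade_net(self.net_config, s)
        return lambda s: build_os_net(self.net_config, MlpConfig(), s)

    def fit(self, verbose: bool = False) -> "AslNetResults":
        patients = pd.DataFrame({
            "patient_id": self.patient_ids,
            "label": [self.class_order[i] for i in self.labels]})
        plan = make_folds(patients, "label", self.k,
                          seed=self.train_config.seed)
        result = train_model(self.features, self.labels, self.patient_ids,
                             plan, self._builder(), self.train_config,
                             clinical=self.clinical, verbose=verbose)
        k = len(self.class_order)
        oof = result.oof_probs[[f"p{c}" for c in range(k)]].to_numpy()
        if self.task == "grade":
            rule = fit_class_scaling(oof, self.labels)
        else:
            rule = tune_threshold(oof[:, 1], self.labels)
        return AslNetResults(model=self, train_result=result,
                             decision_rule=rule, oof_probs=oof)


@dataclass
class AslNetResults:
    """Fitted cross-validation results for one task."""

    model: AslNetModel
    train_result: TrainResult
    decision_rule: DecisionRule
    oof_probs: np.ndarray

    @property
    def oof_auc(self) -> float:
        """Out-of-fold macro one-vs-rest AUC (binary AUC for the OS task)."""
        return _metrics.macro_ovr_auc(self.oof_probs, self.model.labels)

    def oof_report(self) -> _metrics.MetricReport:
        pred = self.decision_rule.apply(self.oof_probs)
        rep = _metrics.classification_report(pred, self.model.labels,
                                             task=self.model.task)
        rep.auc = self.oof_auc
        return rep

    def predict_proba(self, features: np.ndarray,
                      clinical: np.ndarray | None = None) -> np.ndarray:
        """Ensemble mean probability over the restored best fold models."""
        probs = [p.predict_proba(features, clinical)
                 for p in self.train_result.fold_predictors]
        return np.mean(probs, axis=0)

    def predict(self, features: np.ndarray,
                clinical: np.ndarray | None = None) -> np.ndarray:
        return self.decision_rule.apply(self.predict_proba(features, clinical))

    def summary(self) -> str:
        rep = self.oof_report()
        m = self.model
        lines = [
            f"ASLNet {m.task} model — {len(m.patient_ids)} patients, "
            f"{m.k}-fold patient-level CV",
            f"classes: {m.class_order}",
            f"net: input {m.net_config.input_side}^3 x {m.net_config.n_channels}, "
            f"filters {m.net_config.stage_widths}, "
            f"blocks {m.net_config.blocks_per_stage}",
            "-" * 60,
            f"out-of-fold macro OvR AUC : {self.oof_auc:0.3f}",
            f"accuracy                 : {rep.accuracy:0.3f}",
            f"weighted precision       : {rep.weighted_precision:0.3f}",
            f"weighted recall          : {rep.weighted_recall:0.3f}",
            f"weighted F1              : {rep.weighted_f1:0.3f}",
        ]
        if self.decision_rule.threshold is not None:
            lines.append(
                f"decision threshold (short OS) : {self.decision_rule.threshold:0.3f}")
        else:
            scales = ", ".join(f"{s:0.3f}" for s in self.decision_rule.class_scales)
            lines.append(f"class scaling factors    : [{scales}]")
        per_fold = (self.train_result.history.groupby("fold")["val_auc"]
                    .max().to_numpy())
        lines.append("per-fold best val AUC    : "
                     + ", ".join(f"{a:0.3f}" for a in per_fold))
        return "\n".join(lines)
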