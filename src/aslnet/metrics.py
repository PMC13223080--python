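"""Task metrics, bootstrap confidence bands, and cohort descriptive tables.

Discrimination is summarised by the macro one-vs-rest AUC (the mean over
classes of each class-vs-rest ROC AUC, ties getting half credit) together
with accuracy and support-weighted precision/recall/F1.  Cohort composition
mirrors the usual descriptive table: counts and half-up-rounded percentages
per category, including an explicit "empty" row for missing values, plus
between-partition balance tests (Pearson chi-squared for categorical
variables, Mann-Whitney for continuous ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (accuracy_score, auc as _auc_trapz,
                             precision_recall_fscore_support, roc_auc_score,
                             roc_curve)

__all__ = [
    "MetricReport", "CohortSummary", "RocCurve", "BootstrapInterval",
    "macro_ovr_auc", "binary_roc", "classification_report", "bootstrap_ci",
    "cohort_table", "split_balance",
]


@dataclass
class MetricReport:
    task: str
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    support: int
    auc: float | None = None
    ci: tuple[float, float, float] | None = None  # (level, lo, hi)

    def __post_init__(self):
        for v in (self.accuracy, self.weighted_precision,
                  self.weighted_recall, self.weighted_f1):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("metrics must lie in [0, 1]")
        if self.support <= 0:
            raise ValueError("support must be positive")

    def to_markdown(self) -> str:
        rows = [("Accuracy", self.accuracy),
                ("Weighted Precision", self.weighted_precision),
                ("Weighted Recall (Sensitivity)", self.weighted_recall),
                ("Weighted F1-score", self.weighted_f1)]
        if self.auc is not None:
            rows.insert(0, ("Macro OvR AUC", self.auc))
        lines = ["| Metric | Value |", "| --- | --- |"]
        lines += [f"| {name} | {value:0.2f} |" for name, value in rows]
        lines.append(f"| Support (# samples) | {self.support} |")
        if self.ci is not None:
            level, lo, hi = self.ci
            lines.append(f"| AUC {int(level * 100)}% CI | "
                         f"[{lo:0.2f}, {hi:0.2f}] |")
        return "\n".join(lines)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class BootstrapInterval:
    level: float
    lo: float
    hi: float
    point: float
    n_effective: int
    n_skipped: int


@dataclass
class CohortSummary:
    """Per-variable category counts and half-up-rounded percentages."""

    variables: dict  # name -> list of (category, count, percentage)
    total: int
    balance: dict | None = None  # name -> (statistic, p)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, cats in self.variables.items():
            for cat, count, pct in cats:
                rows.append({"variable": var, "category": cat,
                             "count": count, "percentage": pct})
        return pd.DataFrame(rows)


def _check_labels(labels: np.ndarray, n_classes: int) -> None:
    present = np.bincount(labels, minlength=n_classes)
    bad = [c for c in range(n_classes)
           if present[c] == 0 or present[c] == len(labels)]
    if bad:
        raise ValueError(
            f"one-vs-rest AUC undefined for classes {bad}: "
            "each class needs at least one positive and one negative")


def macro_ovr_auc(probs: np.ndarray, labels, n_classes: int | None = None) -> float:
    """Mean over classes of the one-vs-rest ROC AUC (rank statistic, midranks)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim != 2:
        raise ValueError("probs must be (n_samples, n_classes)")
    k = n_classes or probs.shape[1]
    _check_labels(labels, k)
    aucs = [roc_auc_score((labels == c).astype(int), probs[:, c])
            for c in range(k)]
    return float(np.mean(aucs))


def binary_roc(probs: np.ndarray, labels) -> RocCurve:
    """Stepwise ROC curve over all thresholds; AUC equals the rank statistic."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, probs)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_auc_trapz(fpr, tpr)))


def classification_report(pred_labels, true_labels, task: str = "") -> MetricReport:
    """Accuracy plus support-weighted precision / recall / F1."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if true.size == 0:
        raise ValueError("empty label input")
    p, r, f1, _ = precision_recall_fscore_support(
        true, pred, average="weighted", zero_division=0)
    return MetricReport(task=task, accuracy=float(accuracy_score(true, pred)),
                        weighted_precision=float(p), weighted_recall=float(r),
                        weighted_f1=float(f1), support=int(true.size))


def bootstrap_ci(metric_fn, probs, labels, n_boot: int = 2000,
                 level: float = 0.95, seed: int = 0) -> BootstrapInterval:
    """Percentile bootstrap interval over patient-level resamples.

    Resamples on which the metric is undefined (e.g. one class only) are
    skipped and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            vals.append(float(metric_fn(probs[idx], labels[idx])))
        except ValueError:
            skipped += 1
    if not vals:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return BootstrapInterval(level=level, lo=float(lo), hi=float(hi),
                             point=float(metric_fn(probs, labels)),
                             n_effective=len(vals), n_skipped=skipped)


def _half_up_pct(count: int, total: int) -> float:
    pct = Decimal(count) / Decimal(total) * Decimal(100)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_EMPTY = "empty"


def _is_missing(v) -> bool:
    return pd.isna(v) or (isinstance(v, str) and v.strip() == "")


def cohort_table(clinical: pd.DataFrame, variables: list[str]) -> CohortSummary:
    """Descriptive counts and percentages (one decimal, half-up rounding).

    Every variable gets an explicit "empty" category counting missing
    entries; percentages are taken over the full cohort size.
    """
    missing_cols = [v for v in variables if v not in clinical.columns]
    if missing_cols:
        raise ValueError(f"variables not in table: {missing_cols}")
    total = len(clinical)
    out = {}
    for var in variables:
        col = clinical[var]
        missing = col.map(_is_missing)
        counts: dict = {}
        for v in col[~missing]:
            counts[v] = counts.get(v, 0) + 1
        cats = [(str(cat), c, _half_up_pct(c, total)) for cat, c in counts.items()]
        cats.append((_EMPTY, int(missing.sum()), _half_up_pct(int(missing.sum()), total)))
        out[var] = cats
    return CohortSummary(variables=out, total=total)


def _chi2_no_correction(table: np.ndarray) -> tuple[float, float, np.ndarray]:
    stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), expected


def _permutation_chi2(table: np.ndarray, n_perm: int = 2000,
                      seed: int = 0) -> float:
    """Monte-Carlo p-value for the chi2 statistic when expected cells are tiny."""
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    obs_stat, _, _ = _chi2_no_correction(table)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        s, _, _ = _chi2_no_correction(np.maximum(t, 0))
        if s >= obs_stat - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def split_balance(train: pd.DataFrame, test: pd.DataFrame,
                  variables: list[str], seed: int = 0) -> dict:
    """Partition balance tests: chi2 (categorical) / Mann-Whitney (continuous)."""
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both partitions must be non-empty")
    results = {}
    for var in variables:
        a, b = train[var], test[var]
        if pd.api.types.is_numeric_dtype(a) and a.nunique() > 5:
            stat, p = stats.mannwhitneyu(a.dropna(), b.dropna(),
                                         alternative="two-sided")
            results[var] = (float(stat), float(p))
            continue
        cats = sorted(set(a.dropna()) | set(b.dropna()), key=str)
        table = np.array([[int((a == c).sum()) for c in cats],
                          [int((b == c).sum()) for c in cats]])
        table = table[:, table.sum(axis=0) > 0]
        if table.size == 0 or table.shape[1] < 2:
            results[var] = (0.0, 1.0)
            continue
        stat, p, expected = _chi2_no_correction(table)
        if (expected < 1).any():
            warnings.warn(
                f"expected cell < 1 for {var!r}; using permutation p-value")
            p = _permutation_chi2(table, seed=seed)
        results[var] = (stat, p)
    return results
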