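"""Decision-curve analysis.

For a binary decision taken whenever the predicted probability reaches a
threshold probability ``pt``, the net benefit is

    NB(pt) = TP/N - (FP/N) * pt / (1 - pt),

weighing false positives by the odds a patient would accept at that
threshold.  The model curve is compared against treating every patient
("treat-all", NB = pi - (1 - pi) * pt/(1 - pt) at prevalence pi) and
treating none (NB = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DcaCurve", "net_benefit_curve", "reference_curves",
           "collapse_to_binary", "default_threshold_grid", "plot_dca"]


def default_threshold_grid() -> np.ndarray:
    """99 thresholds 0.01 ... 0.99."""
    return np.round(np.arange(1, 100) / 100.0, 2)


@dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n: int
    prevalence: float
    strategy: str  # "model" | "treat_all" | "treat_none"

    def __post_init__(self):
        if np.any(self.tp + self.fp > self.n):
            raise ValueError("TP + FP cannot exceed N")


def _check_thresholds(thresholds: np.ndarray) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    return t


def net_benefit_curve(probs, labels, thresholds=None) -> DcaCurve:
    """Net benefit of acting on ``prob >= pt`` at each threshold."""
    t = _check_thresholds(default_threshold_grid() if thresholds is None
                          else thresholds)
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("decision curve requires both classes present")
    n = len(y)
    tp = np.empty(len(t), dtype=int)
    fp = np.empty(len(t), dtype=int)
    for i, pt in enumerate(t):
        pos = probs >= pt
        tp[i] = int(np.sum(pos & (y == 1)))
        fp[i] = int(np.sum(pos & (y == 0)))
    nb = tp / n - (fp / n) * t / (1.0 - t)
    return DcaCurve(thresholds=t, net_benefit=nb, tp=tp, fp=fp, n=n,
                    prevalence=float(np.mean(y)), strategy="model")


def reference_curves(labels, thresholds=None) -> tuple[DcaCurve, DcaCurve]:
    """Treat-all and treat-none reference curves for the same label vector."""
    t = _check_thresholds(default_threshold_grid() if thresholds is None
                          else thresholds)
    y = np.asarray(labels).astype(int)
    n = len(y)
    n_pos = int(y.sum())
    pi = n_pos / n
    treat_all = DcaCurve(
        thresholds=t,
        net_benefit=pi - (1.0 - pi) * t / (1.0 - t),
        tp=np.full(len(t), n_pos), fp=np.full(len(t), n - n_pos),
        n=n, prevalence=pi, strategy="treat_all")
    treat_none = DcaCurve(
        thresholds=t, net_benefit=np.zeros(len(t)),
        tp=np.zeros(len(t), dtype=int), fp=np.zeros(len(t), dtype=int),
        n=n, prevalence=pi, strategy="treat_none")
    return treat_all, treat_none


def collapse_to_binary(probs: np.ndarray, labels, positive_class,
                       negative_class,
                       class_order=None) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a multi-class problem to two classes for a binary DCA.

    Keeps only samples labelled with either class and renormalises the
    positive-class probability over the retained pair.  ``class_order``
    names the probability columns; it defaults to the sorted unique labels.
    Which grade counts as "positive" is the caller's clinical framing; both
    directions are supported.
    """
    labels = np.asarray(labels)
    classes = (sorted(set(labels.tolist()), key=str) if class_order is None
               else list(class_order))
    keep = (labels == positive_class) | (labels == negative_class)
    if not keep.any():
        raise ValueError("no samples from the requested class pair")
    probs = np.asarray(probs, dtype=float)[keep]
    idx = {c: i for i, c in enumerate(classes)}
    if probs.ndim == 2:
        p_pos = probs[:, idx[positive_class]]
        p_neg = probs[:, idx[negative_class]]
        denom = np.maximum(p_pos + p_neg, 1e-12)
        p = p_pos / denom
    else:
        p = probs
    y = (labels[keep] == positive_class).astype(int)
    return p, y


def plot_dca(model_curve: DcaCurve, treat_all: DcaCurve, treat_none: DcaCurve,
             out_path, title: str = "Decision curve analysis") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(model_curve.thresholds, model_curve.net_benefit, label="model")
    ax.plot(treat_all.thresholds, treat_all.net_benefit, "--", label="treat all")
    ax.plot(treat_none.thresholds, treat_none.net_benefit, ":", label="treat none")
    lo = min(-0.05, float(model_curve.net_benefit.min()))
    ax.set_ylim(lo, max(0.05, float(model_curve.net_benefit.max()) * 1.2))
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
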