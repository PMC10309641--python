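"""Evaluation metrics for compositional predictions.

Regression-scale metrics (cross-entropy, per-class R², class-averaged RMSE)
compare the predicted probability vectors to the true ones directly;
classification-scale metrics (accuracy, macro F1) first collapse each
composition to its argmax class.  Per-class scores are always macro-averaged
(unweighted mean over all K classes) so that minority classes carry the same
weight as the majority.

Conventions:

* cross-entropy uses the natural log and adds ``eps = 1e-20`` inside the log
  to tolerate hard-zero predictions;
* RMSE is computed per class first (square root inside the class average);
* a class with zero variance in the truth has an undefined R² — it is
  reported as NaN and excluded from the macro mean, with a warning;
* a class absent from both truth and prediction argmaxes gets F1 = 0 and
  still counts in the macro mean, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "MetricsReport",
    "cross_entropy",
    "r2_scores",
    "rmse",
    "argmax_labels",
    "accuracy",
    "f1_scores",
    "compute_report",
]

CROSS_ENTROPY_EPS: float = 1e-20


def _pair(Y: ArrayLike, Yhat: ArrayLike) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    A = np.asarray(Y, dtype=float)
    B = np.asarray(Yhat, dtype=float)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("Y and Yhat must be n×K matrices")
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return A, B


def cross_entropy(Y: ArrayLike, Yhat: ArrayLike, eps: float = CROSS_ENTROPY_EPS) -> float:
    """Mean cross-entropy ``−(1/n) Σ_i Σ_j y_ij log(ŷ_ij + eps)`` in nats."""
    A, B = _pair(Y, Yhat)
    if np.any(B < 0):
        raise ValueError("predictions must be non-negative")
    return float(-(A * np.log(B + eps)).sum() / A.shape[0])


def r2_scores(Y: ArrayLike, Yhat: ArrayLike) -> tuple[NDArray[np.float64], float]:
    """Per-class coefficients of determination and their unweighted mean.

    ``R²_j = 1 − SSres_j / SStot_j`` with SStot taken about the class mean.
    Zero-variance classes yield NaN, are excluded from the macro mean and
    trigger a warning.
    """
    A, B = _pair(Y, Yhat)
    if A.shape[0] < 2:
        raise ValueError("R² needs at least 2 samples")
    ss_res = ((A - B) ** 2).sum(axis=0)
    ss_tot = ((A - A.mean(axis=0)) ** 2).sum(axis=0)
    per_class = np.full(A.shape[1], np.nan)
    defined = ss_tot > 0
    per_class[defined] = 1.0 - ss_res[defined] / ss_tot[defined]
    if not defined.all():
        bad = np.flatnonzero(~defined).tolist()
        warnings.warn(f"R² undefined for zero-variance class(es) {bad}; excluded from macro mean")
    macro = float(np.nanmean(per_class)) if defined.any() else float("nan")
    return per_class, macro


def rmse(Y: ArrayLike, Yhat: ArrayLike) -> float:
    """Class-averaged RMSE: per-class root mean squared error, then mean over classes."""
    A, B = _pair(Y, Yhat)
    per_class = np.sqrt(((A - B) ** 2).mean(axis=0))
    return float(per_class.mean())


def argmax_labels(Y: ArrayLike) -> NDArray[np.int64]:
    """Collapse each composition to its dominant class (lowest index wins ties)."""
    A = np.asarray(Y, dtype=float)
    if A.ndim != 2:
        raise ValueError("Y must be an n×K matrix")
    return np.argmax(A, axis=1)


def accuracy(Y: ArrayLike, Yhat: ArrayLike) -> float:
    """Fraction of samples whose predicted argmax class matches the true one."""
    A, B = _pair(Y, Yhat)
    return float((argmax_labels(A) == argmax_labels(B)).mean())


def f1_scores(Y: ArrayLike, Yhat: ArrayLike) -> tuple[NDArray[np.float64], float]:
    """One-vs-rest F1 per class on the argmax labels, plus the macro mean.

    ``F1_j = TP / (TP + (FN + FP)/2)``.  A class absent from both the true
    and predicted argmaxes contributes F1 = 0 (with a warning) and is kept in
    the macro mean over all K classes.
    """
    A, B = _pair(Y, Yhat)
    K = A.shape[1]
    t = argmax_labels(A)
    p = argmax_labels(B)
    per_class = np.zeros(K)
    silent: list[int] = []
    for j in range(K):
        tp = int(np.sum((t == j) & (p == j)))
        fn = int(np.sum((t == j) & (p != j)))
        fp = int(np.sum((t != j) & (p == j)))
        if tp + fn + fp == 0:
            silent.append(j)
            per_class[j] = 0.0
        else:
            per_class[j] = tp / (tp + 0.5 * (fn + fp))
    if silent:
        warnings.warn(f"class(es) {silent} absent from both truth and prediction; F1 set to 0")
    return per_class, float(per_class.mean())


@dataclass(frozen=True)
class MetricsReport:
    """The five headline metrics plus per-class breakdowns."""

    accuracy: float
    cross_entropy: float
    f1_macro: float
    f1_per_class: NDArray[np.float64]
    rmse: float
    r2_macro: float
    r2_per_class: NDArray[np.float64]

    def to_dict(self) -> dict[str, float | list[float]]:
        return {
            "accuracy": self.accuracy,
            "cross_entropy": self.cross_entropy,
            "f1_macro": self.f1_macro,
            "f1_per_class": list(self.f1_per_class),
            "rmse": self.rmse,
            "r2_macro": self.r2_macro,
            "r2_per_class": list(self.r2_per_class),
        }


def compute_report(Y: ArrayLike, Yhat: ArrayLike) -> MetricsReport:
    """Evaluate all five metrics of a prediction against the truth."""
    f1_pc, f1_m = f1_scores(Y, Yhat)
    r2_pc, r2_m = r2_scores(Y, Yhat)
    return MetricsReport(
        accuracy=accuracy(Y, Yhat),
        cross_entropy=cross_entropy(Y, Yhat),
        f1_macro=f1_m,
        f1_per_class=f1_pc,
        rmse=rmse(Y, Yhat),
        r2_macro=r2_m,
        r2_per_class=r2_pc,
    )
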