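"""Synthetic regression datasets with compositional labels.

Features are drawn i.i.d. uniform on an interval; for each point the
expected label is a multinomial-logit (softmax) function of the features,
``α = softmax(x'·B_{·,1}, …, x'·B_{·,K})`` with ``x' = (1, x_1, …, x_p)``
and ``B`` a ``(p+1)×K`` coefficient matrix whose first row holds the
intercepts.  The realised label is a single draw from ``Dirichlet(α)``.

Because α itself sums to 1 the Dirichlet concentration is below 1 and draws
are sparse: most label rows sit near a vertex of the simplex, with the
vertex probabilities given by α.  This mimics segment-level ground truth in
which most units belong overwhelmingly to one class.  The expected per-class
mass share of a generated dataset is the average of α over the feature
distribution, which the imbalancing helpers manipulate.

Two small example coefficient matrices are bundled for the 2-feature,
2-class setting: ``B_CLOSE`` with nearly identical class columns (labels
hover near the centre of the simplex) and ``B_SEPARATED`` with well
separated columns (labels concentrate at the vertices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .oversampler import LabeledDataset
from .simplex_core import clr_inverse

__all__ = [
    "GeneratorConfig",
    "B_CLOSE",
    "B_SEPARATED",
    "mean_composition",
    "generate_dataset",
    "imbalance_by_deletion",
    "imbalance_sweep_coefficients",
]

# Example coefficient matrices for p=2 features, K=2 classes (row 0 = intercepts).
# B_CLOSE has near-identical columns; B_SEPARATED has well-separated ones.
B_CLOSE: NDArray[np.float64] = np.array(
    [[0.4, 0.4], [0.2, 0.4], [0.5, 0.3]], dtype=float
)
B_SEPARATED: NDArray[np.float64] = np.array(
    [[0.1, 0.9], [0.0, 0.5], [0.8, 0.1]], dtype=float
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling plan for :func:`generate_dataset`.

    Parameters
    ----------
    n, p, k
        Sample, feature and class counts.
    feature_interval
        ``(low, high)`` bounds of the uniform feature distribution
        (default ``(-10, 10)``).
    seed
        Seeds both the feature draws and the Dirichlet label draws.
    """

    n: int
    p: int
    k: int
    feature_interval: tuple[float, float] = (-10.0, 10.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1 or self.k < 2:
            raise ValueError("need n >= 1, p >= 1, k >= 2")
        low, high = self.feature_interval
        if not low < high:
            raise ValueError("feature_interval must satisfy low < high")


def _check_b(B: ArrayLike, p: int | None = None, k: int | None = None) -> NDArray[np.float64]:
    arr = np.asarray(B, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("B must be a (p+1)×K matrix with p >= 1, K >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("B must have finite entries")
    if p is not None and arr.shape[0] != p + 1:
        raise ValueError(f"B has {arr.shape[0]} rows, expected p+1={p + 1}")
    if k is not None and arr.shape[1] != k:
        raise ValueError(f"B has {arr.shape[1]} columns, expected K={k}")
    return arr


def mean_composition(x: ArrayLike, B: ArrayLike) -> NDArray[np.float64]:
    """Expected label ``α = softmax(x'·B)`` for features ``x`` (or a stack of rows)."""
    xa = np.atleast_2d(np.asarray(x, dtype=float))
    Ba = _check_b(B, p=xa.shape[-1])
    scores = Ba[0] + xa @ Ba[1:]
    out = clr_inverse(scores)
    return out[0] if np.asarray(x).ndim == 1 else out


def generate_dataset(
    config: GeneratorConfig, B: ArrayLike, concentration: float = 1.0
) -> LabeledDataset:
    """Draw a dataset: uniform features, Dirichlet labels around the softmax mean.

    ``concentration`` multiplies the Dirichlet parameter vector; the default
    of 1 uses α exactly as produced by the softmax (total concentration 1,
    hence sparse, near-vertex labels).  Raising it concentrates labels
    around their mean without changing it.
    """
    Ba = _check_b(B, p=config.p, k=config.k)
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(config.seed)
    low, high = config.feature_interval
    X = rng.uniform(low, high, size=(config.n, config.p))
    alpha = mean_composition(X, Ba) * concentration
    if not np.all(np.isfinite(alpha)):
        raise RuntimeError("non-finite Dirichlet parameters produced by the softmax")
    # Dirichlet via the gamma construction, vectorised over rows.  Parts with
    # very small alpha_j can underflow to exactly 0; they stay 0 (downstream
    # ops apply their own zero replacement) but a row sum of 0 cannot occur
    # because max(alpha_i) >= concentration/K.
    G = rng.standard_gamma(alpha)
    Y = G / G.sum(axis=1, keepdims=True)
    return LabeledDataset(X, Y)


def imbalance_by_deletion(
    data: LabeledDataset, class_index: int, fraction: float, seed: int | None = None
) -> LabeledDataset:
    """Delete ``round(fraction·|D_c|)`` uniformly chosen points with label argmax ``class_index``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not 0 <= class_index < data.k:
        raise ValueError(f"class_index out of range for K={data.k}")
    rng = np.random.default_rng(seed)
    owners = np.argmax(data.labels, axis=1)
    D = np.flatnonzero(owners == class_index)
    if D.size == 0:
        warnings.warn(f"no points have class {class_index} as label argmax; nothing deleted")
        return data
    n_del = int(round(fraction * D.size))
    if n_del == 0:
        return data
    drop = rng.choice(D, size=n_del, replace=False)
    keep = np.setdiff1d(np.arange(data.n), drop)
    return data.subset(keep)


def imbalance_sweep_coefficients(
    B_balanced: ArrayLike, increments: ArrayLike
) -> list[NDArray[np.float64]]:
    """Copies of ``B_balanced`` with class 0's intercept raised by each increment.

    Raising the intercept of the first class's column monotonically raises
    the expected mass share of class 0, which is the x-axis of an imbalance
    sweep; only this induced share matters, not the particular coefficient.
    """
    Ba = _check_b(B_balanced)
    incs = np.asarray(increments, dtype=float)
    if not np.all(np.isfinite(incs)):
        raise ValueError("increments must be finite")
    out = []
    for inc in incs:
        Bi = Ba.copy()
        Bi[0, 0] += inc
        out.append(Bi)
    return out
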