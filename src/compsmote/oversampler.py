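"""SMOTE-style oversampling for datasets whose labels are compositions.

The class-imbalance notion here is *soft*: each label row is a probability
vector over K classes, and the per-class mass of the dataset is the sum
vector ``S_j = Σ_i y_ij``.  The majority class is ``argmax(S)`` and the
minority class ``argmin(S)``.  Oversampling repeatedly picks two original
points whose label argmax is the current minority class, interpolates their
features linearly and their labels on the Aitchison simplex, and appends the
synthetic point until the minority mass has caught up with the (growing)
mass of the initial majority class.

Because both parents of a synthetic point have their label argmax equal to
the target class m, and the simplex combination is a log-linear weighted
average, the synthetic label satisfies ``y_new[m] > y_new[M]`` strictly for
any interior weight — each iteration therefore adds more mass to the
minority class than to the majority one, which guarantees termination.

Two label-combination variants are provided and are mathematically
equivalent (they differ only in round-off): ``"compositional"`` uses the
perturbation/power operators directly, ``"logratio"`` averages the clr
transforms and maps back through the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .simplex_core import as_composition, clr, clr_inverse, perturb, power, replace_zeros

__all__ = [
    "LabeledDataset",
    "OversampleResult",
    "sum_vector",
    "majority_class",
    "minority_class",
    "combine_labels",
    "interpolate_features",
    "convergence_margin",
    "oversample",
    "undersample",
]

LABEL_METHODS = ("compositional", "logratio")


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix ``X (n×p)`` paired with a compositional label matrix ``Y (n×K)``.

    Label rows are validated against the simplex invariant (non-negative,
    unit sum within 1e-9) and renormalised to exact unit sum on construction.
    """

    features: NDArray[np.float64]
    labels: NDArray[np.float64]

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        Y = as_composition(np.asarray(self.labels, dtype=float))
        if Y.ndim != 2:
            raise ValueError("labels must be a 2-D matrix")
        if X.shape[0] != Y.shape[0]:
            raise ValueError(f"features have {X.shape[0]} rows but labels have {Y.shape[0]}")
        if X.shape[0] < 1:
            raise ValueError("dataset must contain at least one point")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", Y)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def k(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx: ArrayLike) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(self.features[idx], self.labels[idx])

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        if other.n == 0:
            return self
        return LabeledDataset(
            np.vstack([self.features, other.features]),
            np.vstack([self.labels, other.labels]),
        )


@dataclass(frozen=True)
class OversampleResult:
    """Synthetic points created by :func:`oversample` plus their provenance.

    ``provenance`` has one row per synthetic point with columns ``r1``,
    ``r2`` (original-dataset indices of the parents), ``w`` (the weight of
    parent r1) and ``target_class`` (the minority class the point was created
    for).  ``class_sums`` is the final per-class mass over original plus
    synthetic points.
    """

    synthetic: LabeledDataset | None
    provenance: pd.DataFrame
    class_sums: NDArray[np.float64]
    majority_class: int

    @property
    def n_synthetic(self) -> int:
        return 0 if self.synthetic is None else self.synthetic.n


def sum_vector(labels: ArrayLike) -> NDArray[np.float64]:
    """Per-class label mass ``S_j = Σ_i y_ij``; the total equals n."""
    Y = np.asarray(labels, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("labels must be a non-empty n×K matrix")
    return Y.sum(axis=0)


def majority_class(S: ArrayLike) -> int:
    """Index of the largest class mass; ties broken by lowest index."""
    return int(np.argmax(np.asarray(S, dtype=float)))


def minority_class(S: ArrayLike) -> int:
    """Index of the smallest class mass; ties broken by lowest index."""
    return int(np.argmin(np.asarray(S, dtype=float)))


def interpolate_features(x1: ArrayLike, x2: ArrayLike, w: float) -> NDArray[np.float64]:
    """Convex combination ``w·x1 + (1−w)·x2`` of two feature vectors."""
    a1 = np.asarray(x1, dtype=float)
    a2 = np.asarray(x2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError(f"feature dimension mismatch: {a1.shape} vs {a2.shape}")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return w * a1 + (1.0 - w) * a2


def combine_labels(
    y1: ArrayLike, y2: ArrayLike, w: float, method: str = "compositional"
) -> NDArray[np.float64]:
    """Weighted average of two compositions on the simplex.

    ``compositional`` computes ``(w ⊗ y1) ⊕ ((1−w) ⊗ y2)`` with the Aitchison
    operators; ``logratio`` computes ``clr⁻¹(w·clr(y1) + (1−w)·clr(y2))``.
    The two are algebraically identical.  Zero parts are replaced by 1e-20
    before any log or power operation.
    """
    if method not in LABEL_METHODS:
        raise ValueError(f"method must be one of {LABEL_METHODS}, got {method!r}")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    a1 = replace_zeros(np.asarray(y1, dtype=float))
    a2 = replace_zeros(np.asarray(y2, dtype=float))
    if a1.shape != a2.shape:
        raise ValueError(f"label dimension mismatch: {a1.shape} vs {a2.shape}")
    if method == "compositional":
        return perturb(power(w, a1), power(1.0 - w, a2))
    return clr_inverse(w * clr(a1) + (1.0 - w) * clr(a2))


def convergence_margin(y_new: ArrayLike, m: int, M: int) -> float:
    """``y_new[m] − y_new[M]``: the per-iteration gain of the minority class.

    Strict positivity of this margin for every synthetic point (with an
    interior weight) is what makes the oversampling loop terminate.
    """
    if m == M:
        raise ValueError("minority and majority class indices must differ")
    y = np.asarray(y_new, dtype=float)
    return float(y[m] - y[M])


def _argmax_rows(Y: NDArray[np.float64]) -> NDArray[np.int64]:
    # np.argmax breaks ties at the lowest index, the convention used throughout
    return np.argmax(Y, axis=1)


def _knn_indices(
    X: NDArray[np.float64], candidates: NDArray[np.int64], r1: int, k: int
) -> NDArray[np.int64]:
    """Indices (into the dataset) of the k nearest candidates to r1, self excluded.

    Exact Euclidean distance on the raw features; distance ties broken by
    lowest index via stable sort on (distance, index).
    """
    others = candidates[candidates != r1]
    d = np.linalg.norm(X[others] - X[r1], axis=1)
    order = np.lexsort((others, d))
    return others[order[:k]]


def oversample(
    data: LabeledDataset,
    k: int = 10,
    method: str = "compositional",
    seed: int | None = None,
) -> OversampleResult:
    """Generate synthetic points until the minority class mass reaches the majority's.

    The loop recomputes the minority class ``m = argmin(S)`` each iteration
    (S includes the synthetic mass added so far), while the majority class M
    is fixed at entry; termination compares ``min(S)`` against the *current*
    sum of class M, which grows slightly as synthetic labels leak mass into
    it.  Parents are always drawn from the ORIGINAL points whose label argmax
    is m; synthetic points never become parents.

    Parameters
    ----------
    data
        The imbalanced dataset.
    k
        Number of nearest neighbours considered for the second parent,
        clamped to ``|D|−1`` when the candidate class D is small.
    method
        Label-combination variant, ``"compositional"`` or ``"logratio"``.
    seed
        Seeds all randomness (parent choices and interpolation weights).

    Raises
    ------
    ValueError
        If the candidate set for the current minority class has fewer than
        two points — such a class is too small to oversample and the caller
        must decide how to proceed.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if method not in LABEL_METHODS:
        raise ValueError(f"method must be one of {LABEL_METHODS}, got {method!r}")
    rng = np.random.default_rng(seed)

    X, Y = data.features, data.labels
    S = sum_vector(Y)
    M = majority_class(S)
    owners = _argmax_rows(Y)

    new_X: list[NDArray[np.float64]] = []
    new_Y: list[NDArray[np.float64]] = []
    prov: list[tuple[int, int, float, int]] = []

    while S.min() < S[M]:
        m = minority_class(S)
        D = np.flatnonzero(owners == m)
        if D.size < 2:
            raise ValueError(
                f"class {m} has only {D.size} point(s) with it as label argmax; "
                "at least 2 are needed to oversample it"
            )
        r1 = int(rng.choice(D))
        k_eff = min(k, D.size - 1)
        neighbours = _knn_indices(X, D, r1, k_eff)
        r2 = int(rng.choice(neighbours))
        w = float(rng.uniform(0.0, 1.0))
        x_new = interpolate_features(X[r1], X[r2], w)
        y_new = combine_labels(Y[r1], Y[r2], w, method=method)
        new_X.append(x_new)
        new_Y.append(y_new)
        prov.append((r1, r2, w, m))
        S = S + y_new

    provenance = pd.DataFrame(prov, columns=["r1", "r2", "w", "target_class"]).astype(
        {"r1": int, "r2": int, "w": float, "target_class": int}
    )
    synthetic = (
        LabeledDataset(np.vstack(new_X), np.vstack(new_Y)) if new_X else None
    )
    return OversampleResult(
        synthetic=synthetic, provenance=provenance, class_sums=S, majority_class=M
    )


def undersample(
    data: LabeledDataset, n_largest: int = 1, seed: int | None = None
) -> LabeledDataset:
    """Randomly delete majority points until the top class mass no longer leads.

    The largest class L is fixed at entry (it is also the current largest at
    every step before the crossing).  One point is removed per step, chosen
    uniformly among points whose label argmax is one of the ``n_largest``
    classes with the highest current mass; removal stops at the first step
    where the mass of L no longer exceeds the largest of the other classes.
    """
    if n_largest not in (1, 2, 3):
        raise ValueError("n_largest must be 1, 2 or 3")
    if data.k < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)

    keep = np.ones(data.n, dtype=bool)
    Y = data.labels
    owners = _argmax_rows(Y)
    L = majority_class(Y.sum(axis=0))

    while True:
        S = Y[keep].sum(axis=0)
        second = max(S[j] for j in range(data.k) if j != L)
        if S[L] <= second:
            break
        top = np.argsort(-S, kind="stable")
        pool = np.flatnonzero(keep & np.isin(owners, top[:n_largest]))
        if pool.size == 0:
            raise ValueError(
                "no removable points left in the top classes before balance was reached"
            )
        drop = int(rng.choice(pool))
        keep[drop] = False
        if not keep.any():
            raise ValueError("undersampling would remove every point")

    if keep.all():
        return data
    return data.subset(np.flatnonzero(keep))
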