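"""Aitchison-simplex algebra: the compositional-data operators everything else builds on.

A *composition* is a vector of ``K >= 2`` non-negative parts that sum to 1;
the set of all such vectors is the simplex ``S^K``.  Compositions carry only
relative information, so ordinary Euclidean arithmetic on them is not
meaningful.  The operators below — closure, perturbation, power and the
centred log-ratio (clr) transform — form the standard Aitchison geometry in
which addition becomes ``perturb`` and scalar multiplication becomes
``power``; clr maps the simplex isometrically onto the zero-sum hyperplane
of ``R^K`` where plain vector arithmetic applies, and its inverse is the
softmax.

Zeros are not silently patched: operators that need strictly positive parts
raise ``ValueError`` and the caller decides, typically via
:func:`replace_zeros` with the default tiny value of ``1e-20``.

All functions accept 1-D vectors or 2-D row-stacks and operate along the
last axis.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

#: Default substitute for exact zeros in compositions prior to log/power ops.
TINY: float = 1e-20

#: Tolerance for accepting an input vector as a composition (sum-to-1 check).
COMPOSITION_ATOL: float = 1e-9

__all__ = [
    "TINY",
    "COMPOSITION_ATOL",
    "closure",
    "replace_zeros",
    "as_composition",
    "clr",
    "clr_inverse",
    "perturb",
    "power",
]


def _asarray(v: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(v, dtype=float)
    if arr.ndim not in (1, 2):
        raise ValueError(f"{name} must be a vector or a matrix of row vectors, got ndim={arr.ndim}")
    if arr.shape[-1] < 2:
        raise ValueError(f"{name} must have at least 2 parts, got K={arr.shape[-1]}")
    return arr


def closure(v: ArrayLike) -> NDArray[np.float64]:
    """Normalise a non-negative vector to unit sum (the closure operator C).

    Parameters
    ----------
    v
        Vector of ``K >= 2`` non-negative reals (or a 2-D stack of them) with
        a strictly positive sum per row.

    Returns
    -------
    The composition proportional to ``v``: ``v / sum(v)``.

    Raises
    ------
    ValueError
        If any entry is negative, non-finite, or a row sums to zero.
    """
    arr = _asarray(v, "v")
    if not np.all(np.isfinite(arr)):
        raise ValueError("closure requires finite entries")
    if np.any(arr < 0):
        raise ValueError("closure requires non-negative entries")
    total = arr.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("closure undefined for an all-zero vector")
    return arr / total


def replace_zeros(x: ArrayLike, tiny: float = TINY) -> NDArray[np.float64]:
    """Substitute exact zeros by ``tiny`` (default 1e-20), leaving other entries untouched.

    No renormalisation is performed here; compose with :func:`closure` if a
    strict composition is needed afterwards.
    """
    arr = _asarray(x, "x")
    if tiny <= 0:
        raise ValueError("tiny must be positive")
    if np.any(arr < 0):
        raise ValueError("replace_zeros requires non-negative entries")
    return np.where(arr == 0.0, tiny, arr)


def as_composition(v: ArrayLike, atol: float = COMPOSITION_ATOL) -> NDArray[np.float64]:
    """Validate ``v`` as a composition and renormalise it to exact unit sum.

    Entries must be non-negative and each row must sum to 1 within ``atol``
    (the slack absorbs decimal round-trips through CSV).
    """
    arr = _asarray(v, "v")
    if not np.all(np.isfinite(arr)):
        raise ValueError("composition entries must be finite")
    if np.any(arr < 0):
        raise ValueError("composition entries must be non-negative")
    total = arr.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > atol):
        bad = np.abs(np.atleast_1d(total) - 1.0).max()
        raise ValueError(f"composition rows must sum to 1 within {atol} (max deviation {bad:.3g})")
    return arr / arr.sum(axis=-1, keepdims=True)


def _require_positive(arr: NDArray[np.float64], op: str) -> None:
    if np.any(arr <= 0):
        raise ValueError(
            f"{op} requires strictly positive parts; apply replace_zeros() first to handle zeros"
        )


def clr(x: ArrayLike) -> NDArray[np.float64]:
    """Centred log-ratio transform: ``clr(x)_i = log(x_i / g(x))``.

    ``g(x)`` is the geometric mean of the parts.  Computed as
    ``log(x_i) - mean(log x)`` so parts as small as 1e-20 stay well inside
    floating-point range.  The image always sums to zero.
    """
    arr = _asarray(x, "x")
    _require_positive(arr, "clr")
    logs = np.log(arr)
    return logs - logs.mean(axis=-1, keepdims=True)


def clr_inverse(z: ArrayLike) -> NDArray[np.float64]:
    """Inverse clr transform, i.e. the softmax, computed with max-subtraction.

    Maps any real vector to a composition; constant shifts of ``z`` leave the
    result unchanged, so clr_inverse is a true inverse only on zero-sum
    vectors (the clr image).
    """
    arr = _asarray(z, "z")
    if not np.all(np.isfinite(arr)):
        raise ValueError("clr_inverse requires finite entries")
    shifted = arr - arr.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def perturb(x: ArrayLike, y: ArrayLike) -> NDArray[np.float64]:
    """Perturbation ``x ⊕ y = C(x_1 y_1, …, x_K y_K)`` — simplex addition.

    Computed in log space (``clr_inverse(log x + log y)``) so that parts near
    1e-20 do not underflow when multiplied.
    """
    ax = _asarray(x, "x")
    ay = _asarray(y, "y")
    if ax.shape[-1] != ay.shape[-1]:
        raise ValueError(f"dimension mismatch: {ax.shape[-1]} vs {ay.shape[-1]} parts")
    _require_positive(ax, "perturb")
    _require_positive(ay, "perturb")
    return clr_inverse(np.log(ax) + np.log(ay))


def power(alpha: float, x: ArrayLike) -> NDArray[np.float64]:
    """Power transformation ``α ⊗ x = C(x_1^α, …, x_K^α)`` — simplex scaling.

    Computed in log space (``clr_inverse(α log x)``) for the same underflow
    reason as :func:`perturb`.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    ax = _asarray(x, "x")
    _require_positive(ax, "power")
    return clr_inverse(float(alpha) * np.log(ax))
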