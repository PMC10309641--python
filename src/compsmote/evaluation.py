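"""Replicated raw-vs-oversampled benchmarking harness.

Each replicate draws a fresh train/test pair from the synthetic generator,
optionally rebalances the training set (random undersampling of the top
classes, then simplex oversampling with either label-combination variant),
fits a regressor, predicts the test labels and scores all five metrics.
Regressors are pluggable: anything with ``fit(X, Y)`` / ``predict(X)``
returning row-stochastic predictions works, and a light least-squares
baseline on clr-transformed labels is built in so the harness runs with no
heavyweight model dependency.

Results come back as a long-form table (one row per replicate × method) plus
a mean/s.d. summary per method × metric, which is the shape in which such
comparisons are normally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .metrics import compute_report
from .oversampler import LabeledDataset, oversample, undersample
from .simplex_core import clr, clr_inverse, closure, replace_zeros
from .synthetic_data import GeneratorConfig, generate_dataset

__all__ = [
    "Regressor",
    "ClrLinearRegressor",
    "OracleRegressor",
    "ConstantMeanRegressor",
    "ExperimentConfig",
    "run_replicated_comparison",
    "run_imbalance_sweep",
    "summarise",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["accuracy", "cross_entropy", "f1_macro", "rmse", "r2_macro"]


class Regressor(Protocol):
    """Anything that learns a map from features to compositional labels."""

    def fit(self, X: ArrayLike, Y: ArrayLike) -> "Regressor": ...

    def predict(self, X: ArrayLike) -> NDArray[np.float64]: ...


def _renormalise(pred: NDArray[np.float64]) -> NDArray[np.float64]:
    """Clip negatives and renormalise rows so backends may emit raw scores."""
    pred = np.clip(np.asarray(pred, dtype=float), 0.0, None)
    pred = replace_zeros(pred) if np.any(pred.sum(axis=1) == 0) else pred
    return closure(pred)


class ClrLinearRegressor:
    """Ordinary least squares on clr-transformed labels, inverted by softmax.

    The generator's labels follow a softmax-linear mean, so a linear map into
    clr space is a natural, dependency-free baseline.  Zero label parts are
    replaced by 1e-20 before the log-ratio transform.
    """

    def __init__(self) -> None:
        self.coef_: NDArray[np.float64] | None = None

    def fit(self, X: ArrayLike, Y: ArrayLike) -> "ClrLinearRegressor":
        Xa = np.asarray(X, dtype=float)
        Z = clr(replace_zeros(np.asarray(Y, dtype=float)))
        A = np.hstack([np.ones((Xa.shape[0], 1)), Xa])
        self.coef_, *_ = np.linalg.lstsq(A, Z, rcond=None)
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        if self.coef_ is None:
            raise RuntimeError("fit before predict")
        Xa = np.asarray(X, dtype=float)
        A = np.hstack([np.ones((Xa.shape[0], 1)), Xa])
        return clr_inverse(A @ self.coef_)


class OracleRegressor:
    """Returns pre-supplied true labels; for harness self-tests only."""

    def __init__(self, truth: NDArray[np.float64]) -> None:
        self.truth = np.asarray(truth, dtype=float)

    def fit(self, X: ArrayLike, Y: ArrayLike) -> "OracleRegressor":
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        return self.truth.copy()


class ConstantMeanRegressor:
    """Always predicts the mean training composition."""

    def __init__(self) -> None:
        self.mean_: NDArray[np.float64] | None = None

    def fit(self, X: ArrayLike, Y: ArrayLike) -> "ConstantMeanRegressor":
        self.mean_ = closure(np.asarray(Y, dtype=float).mean(axis=0))
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        if self.mean_ is None:
            raise RuntimeError("fit before predict")
        Xa = np.asarray(X, dtype=float)
        return np.tile(self.mean_, (Xa.shape[0], 1))


@dataclass(frozen=True)
class ExperimentConfig:
    """Plan for a replicated comparison.

    ``methods`` selects the arms: ``"raw"`` (no resampling) and/or the two
    oversampling variants.  When ``undersample_first`` is set the training
    set is first randomly undersampled over the ``n_largest`` top classes,
    then oversampled (for the non-raw arms).
    """

    n_train: int = 550
    n_test: int = 2000
    n_replicates: int = 20
    k_neighbors: int = 10
    methods: tuple[str, ...] = ("raw", "logratio", "compositional")
    undersample_first: bool = False
    n_largest: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        bad = set(self.methods) - {"raw", "logratio", "compositional"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


def _prepare_training(
    train: LabeledDataset,
    method: str,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[LabeledDataset, int]:
    """Apply the arm's resampling to the training set; returns (dataset, q)."""
    if method == "raw":
        return train, 0
    work = train
    if config.undersample_first:
        work = undersample(work, n_largest=config.n_largest, seed=int(rng.integers(2**31)))
    result = oversample(
        work, k=config.k_neighbors, method=method, seed=int(rng.integers(2**31))
    )
    if result.synthetic is not None:
        work = work.concat(result.synthetic)
    return work, result.n_synthetic


def run_replicated_comparison(
    config: ExperimentConfig,
    B: ArrayLike,
    regressor_factory: Callable[[], Regressor],
    generator: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Run the raw-vs-oversampled comparison over seeded replicates.

    Returns a long-form table with one row per replicate × method carrying
    the five headline metrics, per-class F1/R² breakdowns, the synthetic
    point count ``q`` and a ``failed`` flag (a regressor crash marks the row
    failed and the run continues).
    """
    Ba = np.asarray(B, dtype=float)
    p, k = Ba.shape[0] - 1, Ba.shape[1]
    base = generator or GeneratorConfig(n=config.n_train, p=p, k=k)
    master = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for rep in range(config.n_replicates):
        rep_rng = np.random.default_rng(master.integers(2**31))
        train = generate_dataset(
            GeneratorConfig(
                n=config.n_train, p=p, k=k,
                feature_interval=base.feature_interval,
                seed=int(rep_rng.integers(2**31)),
            ),
            Ba,
        )
        test = generate_dataset(
            GeneratorConfig(
                n=config.n_test, p=p, k=k,
                feature_interval=base.feature_interval,
                seed=int(rep_rng.integers(2**31)),
            ),
            Ba,
        )
        share0 = float(train.labels.sum(axis=0)[0] / train.n)
        for method in config.methods:
            row: dict = {"replicate": rep, "method": method, "train_share_class0": share0}
            try:
                prepared, q = _prepare_training(train, method, config, rep_rng)
                model = regressor_factory()
                model.fit(prepared.features, prepared.labels)
                pred = _renormalise(model.predict(test.features))
                report = compute_report(test.labels, pred)
                row.update(
                    accuracy=report.accuracy,
                    cross_entropy=report.cross_entropy,
                    f1_macro=report.f1_macro,
                    rmse=report.rmse,
                    r2_macro=report.r2_macro,
                    q=q,
                    failed=False,
                )
                for j in range(k):
                    row[f"f1_class{j}"] = report.f1_per_class[j]
                    row[f"r2_class{j}"] = report.r2_per_class[j]
            except Exception:  # noqa: BLE001 - a failing arm must not kill the run
                logger.exception("replicate %d method %s failed", rep, method)
                row.update(q=0, failed=True)
            rows.append(row)
    return pd.DataFrame(rows)


def summarise(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and s.d. per method × metric over non-failed replicates."""
    ok = results[~results["failed"].astype(bool)]
    metric_cols = [c for c in ok.columns if c in METRIC_COLUMNS or c.startswith(("f1_class", "r2_class"))]
    return ok.groupby("method")[metric_cols].agg(["mean", "std"])


def run_imbalance_sweep(
    config: ExperimentConfig,
    B_list: Sequence[ArrayLike],
    regressor_factory: Callable[[], Regressor],
) -> pd.DataFrame:
    """Replicated comparison at each coefficient matrix of an imbalance sweep.

    The returned table adds a ``step`` index and the realised class-0 mass
    share of the training data (mean over replicates), which serves as the
    sweep's x-axis.
    """
    frames = []
    master = np.random.default_rng(config.seed)
    for step, B in enumerate(B_list):
        step_cfg = ExperimentConfig(
            n_train=config.n_train,
            n_test=config.n_test,
            n_replicates=config.n_replicates,
            k_neighbors=config.k_neighbors,
            methods=config.methods,
            undersample_first=config.undersample_first,
            n_largest=config.n_largest,
            seed=int(master.integers(2**31)),
        )
        res = run_replicated_comparison(step_cfg, B, regressor_factory)
        res.insert(0, "step", step)
        res["realised_share_class0"] = res["train_share_class0"].mean()
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
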