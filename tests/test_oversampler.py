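"""Tests for the simplex oversampler: primitives, the main loop, undersampling."""

import numpy as np
import pytest
from numpy.testing import assert_allclose, assert_array_equal

from compsmote.oversampler import (
    LabeledDataset,
    combine_labels,
    convergence_margin,
    interpolate_features,
    majority_class,
    minority_class,
    oversample,
    sum_vector,
    undersample,
)
from compsmote.simplex_core import clr, clr_inverse, replace_zeros
from conftest import random_compositions


def one_hot_dataset(counts, rng, p=2):
    """n one-hot-labelled points with `counts[j]` points in class j."""
    k = len(counts)
    labels = np.repeat(np.eye(k), counts, axis=0)
    features = rng.normal(size=(labels.shape[0], p))
    return LabeledDataset(features, labels)


class TestSumVectorAndClassPicks:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([[1, 0], [0, 1]], [1, 1]),
            ([[0.5, 0.5], [0.5, 0.5]], [1, 1]),
            ([[0.2, 0.8], [0.3, 0.7], [0.9, 0.1]], [1.4, 1.6]),
        ],
    )
    def test_examples(self, labels, expected):
        assert_allclose(sum_vector(np.array(labels, dtype=float)), expected, atol=1e-12)

    def test_total_equals_n(self, rng):
        Y = random_compositions(rng, 37, 5)
        assert sum_vector(Y).sum() == pytest.approx(37.0, abs=1e-9)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            sum_vector(np.empty((0, 3)))

    def test_majority_minority_and_ties(self):
        assert majority_class([1.4, 1.6]) == 1
        assert minority_class([1.4, 1.6]) == 0
        assert majority_class([1.0, 1.0]) == 0
        assert minority_class([1.0, 1.0]) == 0
        # the seabed-cover share pattern: class 2 dominant, class 1 rare
        S = np.array([0.117, 0.040, 0.482, 0.361]) * 550
        assert majority_class(S) == 2
        assert minority_class(S) == 1


class TestCombineLabels:
    @pytest.mark.parametrize("method", ["compositional", "logratio"])
    def test_endpoints(self, method):
        y1 = np.array([0.2, 0.8])
        y2 = np.array([0.7, 0.3])
        assert_allclose(combine_labels(y1, y2, 1.0, method), y1, atol=1e-12)
        assert_allclose(combine_labels(y1, y2, 0.0, method), y2, atol=1e-12)

    @pytest.mark.parametrize("method", ["compositional", "logratio"])
    def test_symmetric_midpoint(self, method):
        got = combine_labels(np.array([0.2, 0.8]), np.array([0.8, 0.2]), 0.5, method)
        assert_allclose(got, [0.5, 0.5], atol=1e-12)

    def test_variants_agree_with_independent_clr_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            y1, y2 = random_compositions(rng, 2, k)
            w = float(rng.uniform())
            # independent oracle: weighted average in clr space via softmax
            z = w * clr(y1) + (1 - w) * clr(y2)
            expected = np.exp(z) / np.exp(z).sum()
            assert_allclose(combine_labels(y1, y2, w, "compositional"), expected, atol=1e-8)
            assert_allclose(combine_labels(y1, y2, w, "logratio"), expected, atol=1e-8)

    def test_zero_parts_are_replaced_not_fatal(self):
        out = combine_labels(np.array([0.0, 1.0]), np.array([0.5, 0.5]), 0.5)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out >= 0)

    def test_rejects_bad_weight_and_method(self):
        y = np.array([0.5, 0.5])
        with pytest.raises(ValueError):
            combine_labels(y, y, 1.5)
        with pytest.raises(ValueError):
            combine_labels(y, y, 0.5, method="euclidean")


class TestInterpolateFeatures:
    def test_examples(self):
        assert_allclose(interpolate_features([0, 0], [2, 4], 0.5), [1, 2])
        assert_allclose(interpolate_features([1, 2], [3, 4], 1.0), [1, 2])
        assert_allclose(interpolate_features([1.0], [5.0], 0.25), [4.0])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            interpolate_features([1, 2], [1, 2, 3], 0.5)


class TestConvergenceMargin:
    def test_plain_subtraction(self):
        assert convergence_margin([0.7, 0.3], 0, 1) == pytest.approx(0.4)

    def test_rejects_equal_indices(self):
        with pytest.raises(ValueError):
            convergence_margin([0.5, 0.5], 1, 1)

    def test_positive_when_parents_share_argmax(self, rng):
        """Log-linear combination preserves the strict ordering of components."""
        for _ in range(200):
            y1 = np.sort(rng.dirichlet(np.ones(3)))[::-1]  # argmax at 0
            y2 = np.sort(rng.dirichlet(np.ones(3)))[::-1]
            w = float(rng.uniform(0.01, 0.99))
            y_new = combine_labels(y1, y2, w)
            assert convergence_margin(y_new, 0, 2) > 0

    def test_boundary_weight_with_indifferent_parent(self):
        y1 = np.array([0.6, 0.4])
        y2 = np.array([0.5, 0.5])
        y_new = combine_labels(y1, y2, 0.0)
        assert convergence_margin(y_new, 0, 1) == pytest.approx(0.0, abs=1e-12)


def imbalanced_dataset(rng, n=60, k=3):
    """Small dataset with soft labels biased so class sums are unequal."""
    alphas = np.array([[6, 2, 2], [2, 6, 2], [2, 2, 6]], dtype=float)
    weights = [0.6, 0.3, 0.1]
    rows = rng.choice(3, size=n, p=weights)
    labels = np.vstack([rng.dirichlet(alphas[r]) for r in rows])
    features = rng.normal(size=(n, 4))
    return LabeledDataset(features, labels)


class TestOversample:
    def test_balanced_input_yields_no_synthetic_points(self, rng):
        data = one_hot_dataset([5, 5], rng)
        result = oversample(data, k=3, seed=0)
        assert result.n_synthetic == 0
        assert len(result.provenance) == 0

    def test_termination_bound_and_target_class(self, rng):
        data = imbalanced_dataset(rng)
        result = oversample(data, k=5, seed=7)
        S = result.class_sums
        M = result.majority_class
        assert S.min() >= S[M] - 1e-9
        assert S.min() < S[M] + 1.0
        syn = result.synthetic
        assert syn is not None
        assert_array_equal(
            np.argmax(syn.labels, axis=1), result.provenance["target_class"].to_numpy()
        )

    def test_features_inside_parent_bounding_box(self, rng):
        data = imbalanced_dataset(rng)
        result = oversample(data, k=5, seed=3)
        X = data.features
        for row, rec in zip(result.synthetic.features, result.provenance.itertuples()):
            lo = np.minimum(X[rec.r1], X[rec.r2])
            hi = np.maximum(X[rec.r1], X[rec.r2])
            assert np.all(row >= lo - 1e-12) and np.all(row <= hi + 1e-12)

    def test_provenance_replay_reproduces_synthetic_points(self, rng):
        data = imbalanced_dataset(rng)
        for method in ("compositional", "logratio"):
            result = oversample(data, k=5, method=method, seed=11)
            for i, rec in enumerate(result.provenance.itertuples()):
                x = interpolate_features(
                    data.features[rec.r1], data.features[rec.r2], rec.w
                )
                y = combine_labels(
                    data.labels[rec.r1], data.labels[rec.r2], rec.w, method=method
                )
                assert_array_equal(result.synthetic.features[i], x)
                # stored labels pass through the dataset's canonical unit-sum
                # renormalisation; replaying it gives bit-identical values
                assert_array_equal(result.synthetic.labels[i], y / y.sum())

    def test_seeded_runs_are_bit_identical(self, rng):
        data = imbalanced_dataset(rng)
        a = oversample(data, k=5, seed=42)
        b = oversample(data, k=5, seed=42)
        assert_array_equal(a.synthetic.features, b.synthetic.features)
        assert_array_equal(a.synthetic.labels, b.synthetic.labels)
        assert a.provenance.equals(b.provenance)

    def test_variants_agree_given_identical_seed(self, rng):
        data = imbalanced_dataset(rng)
        a = oversample(data, k=5, method="compositional", seed=5)
        b = oversample(data, k=5, method="logratio", seed=5)
        assert_array_equal(a.synthetic.features, b.synthetic.features)
        assert_allclose(a.synthetic.labels, b.synthetic.labels, atol=1e-8)

    def test_parents_are_original_points_only(self, rng):
        data = imbalanced_dataset(rng)
        result = oversample(data, k=5, seed=9)
        assert result.provenance[["r1", "r2"]].to_numpy().max() < data.n

    def test_tiny_candidate_class_is_a_named_error(self, rng):
        # class 1 has a single point: too small to oversample
        data = one_hot_dataset([10, 1], rng)
        with pytest.raises(ValueError, match="class 1"):
            oversample(data, k=3, seed=0)

    def test_rejects_nonpositive_k(self, rng):
        data = one_hot_dataset([3, 2], rng)
        with pytest.raises(ValueError):
            oversample(data, k=0, seed=0)


class TestUndersample:
    def test_balanced_input_unchanged(self, rng):
        data = one_hot_dataset([4, 4], rng)
        out = undersample(data, seed=0)
        assert out.n == data.n

    def test_one_hot_counts_stop_at_first_crossing(self, rng):
        data = one_hot_dataset([10, 2], rng)
        out = undersample(data, n_largest=1, seed=1)
        counts = np.bincount(np.argmax(out.labels, axis=1), minlength=2)
        assert counts.tolist() == [2, 2]
        assert out.n == 4

    def test_last_removal_was_necessary(self, rng):
        """Replacing any removed point would restore S[top] > S[second]."""
        alphas = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]], dtype=float)
        rows = rng.choice(3, size=90, p=[0.7, 0.2, 0.1])
        data = LabeledDataset(
            rng.normal(size=(90, 2)),
            np.vstack([rng.dirichlet(alphas[r]) for r in rows]),
        )
        out = undersample(data, n_largest=1, seed=4)
        L = majority_class(data.labels.sum(axis=0))
        S = out.labels.sum(axis=0)
        others = [j for j in range(3) if j != L]
        assert S[L] <= max(S[j] for j in others) + 1e-12
        # first crossing: the state before the final removal violated the
        # bound, so adding back at least one removed point must break it
        kept_rows = {tuple(r) for r in out.features}
        removed = [i for i in range(data.n) if tuple(data.features[i]) not in kept_rows]
        assert removed

        def violates(i):
            S_back = S + data.labels[i]
            return S_back[L] > max(S_back[j] for j in others)

        assert any(violates(i) for i in removed)

    def test_rejects_bad_n_largest(self, rng):
        with pytest.raises(ValueError):
            undersample(one_hot_dataset([3, 1], rng), n_largest=5, seed=0)


class TestLabeledDataset:
    def test_rejects_row_mismatch_and_bad_labels(self, rng):
        with pytest.raises(ValueError):
            LabeledDataset(np.zeros((3, 2)), np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            LabeledDataset(np.zeros((1, 2)), np.array([[0.5, 0.6]]))

    def test_concat_and_subset(self, rng):
        a = one_hot_dataset([2, 2], rng)
        b = one_hot_dataset([1, 1], rng)
        both = a.concat(b)
        assert both.n == 6
        assert both.subset([0, 5]).n == 2
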