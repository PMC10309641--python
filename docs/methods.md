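# Methods

## Setting and notation

A dataset pairs a feature matrix `X ∈ R^(n×p)` with a label matrix
`Y ∈ R^(n×K)` whose rows are compositions: `y_ij ≥ 0`, `Σ_j y_ij = 1`.
Class imbalance is defined through the per-class label mass
`S_j = Σ_i y_ij` (the sum vector); a balanced dataset has `S_j ≈ n/K` for
every class. The majority class is `M = argmax(S)` and the minority class
`m = argmin(S)`, with argmax/argmin ties broken by the lowest index
everywhere in the package (labels, sums, metric argmaxes) for determinism.

## Simplex algebra

Compositions live in Aitchison geometry, not Euclidean space. The package
implements the standard operators: closure `C(v) = v / Σv`, perturbation
`x ⊕ y = C(x_1 y_1, …, x_K y_K)`, power `α ⊗ x = C(x_1^α, …, x_K^α)`, the
centred log-ratio transform `clr(x)_j = log(x_j / g(x))` with `g` the
geometric mean, and its inverse, the softmax. Perturbation and power are
evaluated in log space (`clr⁻¹(log x + log y)` and `clr⁻¹(α log x)`) so
that parts as small as `1e-20` cannot underflow in products; the softmax
subtracts the row maximum before exponentiating. `clr` uses
`log x_j − mean(log x)` for the same reason.

Zero parts make log-ratio operations undefined. The package's single zero
policy is explicit substitution of exact zeros by `tiny = 1e-20` via
`replace_zeros`; operators that need positive parts raise an error rather
than substituting silently, so data problems surface at the call site. The
oversampler applies the substitution itself before combining parent labels,
since Dirichlet-sampled labels can contain underflowed zeros legitimately.

Compositions are accepted when their sum is within `1e-9` of 1 (CSV
round-trips truncate digits) and are renormalised to exact unit sum on
entry into a dataset.

## The oversampler

The loop keeps the invariant that `S` reflects all points created so far:

1. `M` is fixed at entry; `m = argmin(S)` is re-elected every iteration.
2. The candidate set `D` contains **original** points only — synthetic
   points never become parents, so the generated distribution is anchored
   to the observed data and a run is reproducible from the provenance table
   alone.
3. Neighbour search is exact Euclidean distance on the raw (unscaled)
   features, self excluded, distance ties broken by lowest index;
   `k_eff = min(k, |D|−1)` so small classes clamp rather than crash. A
   class with fewer than two candidate points raises an error naming the
   class: a 3–4% class genuinely cannot be oversampled well and the caller
   must decide (merge classes, collect data, or skip).
4. `w` is drawn from the closed interval `[0, 1]`; endpoint draws duplicate
   a parent and are kept.
5. Termination compares `min(S)` against the *current* sum of class `M`,
   which grows as synthetic labels leak mass into it. Both parents have
   argmax `m`, and log-linear combination preserves strict componentwise
   ordering, so `y_new[m] > y_new[M]` (the convergence margin) for every
   interior `w`; each iteration therefore shrinks the gap and the loop
   stops with `S[M] ≤ min(S) < S[M] + 1`.

The two label-combination variants — operator form
`(w ⊗ y_r1) ⊕ ((1−w) ⊗ y_r2)` and clr form
`clr⁻¹(w·clr(y_r1) + (1−w)·clr(y_r2))` — are algebraically identical; both
are kept because they correspond to the two ways users think about the
geometry, and their agreement (≤ ~1e-15 observed, 1e-8 asserted) is a
standing cross-check on the algebra.

### Undersampling

The optional pre-step removes uniformly chosen points whose label argmax is
among the `n_largest ∈ {1,2,3}` top classes by current mass, one at a time,
until the mass of the class that was largest at entry no longer exceeds
every other class's mass. The largest class must be fixed at entry: if it
were re-elected after every removal, the first crossing would swap the top
two classes and the loop would alternate between them, never satisfying a
"largest ≤ second largest" test at discrete granularity until the dataset
emptied. Before the crossing the entry-largest class *is* the current
largest, so the removal pool is unaffected by this choice.

## Synthetic data generator

The generator emulates segment-level mixture data: features
`x_ij ~ U(low, high)` i.i.d. (default `[-10, 10]`), expected label
`α = softmax(x'·B)` with `x' = (1, x_1, …, x_p)` and `B ∈ R^((p+1)×K)`
(row 0 = intercepts), realised label `y ~ Dirichlet(α)`. Since `Σα = 1`,
the total concentration is 1 and draws are sparse — most labels sit near a
vertex, with vertex probabilities `α`. This matches ground truth in which
most units belong overwhelmingly to one class. `E[y|x] = α`, so the mass
share of class `j` in a large dataset is the average of `α_j` over the
feature distribution; raising class 0's intercept raises its share
monotonically, which is how imbalance sweeps are driven. An optional
concentration multiplier (> 1 tightens labels around `α` without moving the
mean) exists for sensitivity checks but defaults to 1 and is unused in all
shipped experiments. Draws use the gamma representation
(`y = G/ΣG`, `G_j ~ Gamma(α_j)`), vectorised over rows; a part whose
`α_j` is very small can underflow to an exact 0 and is left to the zero
policy downstream.

`B` entries are accepted as any finite reals; the `[0,1]` range of the
bundled examples is a convention, not a constraint (intercept sweeps need
values outside it).

Two calibrated 17×4 matrices are bundled, sharing one feature-coefficient
block (slopes ~U(0, 0.08), small enough that the softmax is not saturated
for `x ∈ [-10,10]^16`): `FOUR_CLASS_B`, whose intercepts were tuned once by
Monte-Carlo iteration to give mass shares ≈ (0.117, 0.040, 0.482, 0.361) —
one dominant class near 50% and one rare class near 4%, the profile of a
typical cover-mapping dataset — and `FOUR_CLASS_BALANCED_B` with equal
(25%) shares, the origin of intercept sweeps. The two-feature matrices
`B_CLOSE`/`B_SEPARATED` illustrate near-identical versus well-separated
class columns (the latter produces many more near-vertex labels).

### What the generator does not emulate

Real feature vectors (image moments, spectra) are correlated, non-uniform
and often heavy-tailed; here features are independent uniforms. Real
label noise need not be Dirichlet, and real datasets contain structural
zeros rather than underflow zeros. Passing benchmarks on this generator
shows the oversampler does what it claims under a softmax-linear Dirichlet
world; it does not certify gains on any particular real dataset, where the
effect is known to depend on the model and the imbalance profile.

## Metrics

For truth `Y` and prediction `Ŷ` (rows renormalised to the simplex):

- cross-entropy `−(1/n) Σ_i Σ_j y_ij log(ŷ_ij + ε)`, natural log,
  `ε = 1e-20` so hard-zero predictions cost `−log ε ≈ 46` per unit mass
  rather than infinity;
- per-class `R²_j = 1 − SSres_j/SStot_j` about the class mean, macro mean
  over classes; a zero-variance class has no defined `R²` and is reported
  as NaN and excluded from the macro mean (with a warning) rather than
  being given an arbitrary 0;
- RMSE per class first, then averaged over classes (`(1/K) Σ_j RMSE_j`):
  the square root is applied before the class average, so every class
  contributes on the same scale regardless of its variance;
- accuracy and one-vs-rest F1 (`TP/(TP + (FN+FP)/2)`) on the argmax
  classes, F1 macro-averaged over **all** K classes; a class absent from
  both truth and prediction contributes 0 (with a warning) instead of being
  dropped, so metric values are comparable across runs.

All five are cross-checked in the test suite against a naive-loop
reimplementation (to 1e-12) and against scikit-learn where an equivalent
exists.

## Benchmarking harness

Each replicate draws fresh train/test sets, applies each arm's resampling
(raw; oversampled with either variant; optionally undersample-first) to the
training set only, fits a fresh regressor, and scores the test set.
Regressors are injected through a `fit/predict` contract; predictions are
clipped to non-negative and renormalised so backends may emit raw scores.
A regressor failure marks that replicate×arm failed and the run continues.
The built-in baseline fits ordinary least squares from the features to the
clr-transformed labels and predicts through the softmax — the natural
dependency-free model for softmax-linear data, though a deliberately weak
one: clr targets of near-vertex labels are extreme (|log| up to ~46), so
its absolute scores are modest and it serves to measure *relative* effects
of resampling, not to set a performance bar.

Experiment sizes in the shipped tests and acceptance script are 550
training / 2,000 test points and 20 replicates, with the direction
experiment run at majority share ≈ 50% (class 0 ≈ 50%, the others ≈ 16–17%
each) — the imbalance profile at which per-class effects of oversampling
are most interpretable, since every minority class retains enough points to
oversample. Under a much harsher profile (a 4% class), oversampling that
class is unreliable by construction and the macro-F1 direction is not
stable; the error raised for classes with fewer than two candidates makes
this regime explicit.

The imbalance sweep reports the realised class-0 mass share of the training
data (mean over replicates) as its x-axis, since the expected share is a
property of `B` while the realised share is what the model actually saw.

## Numerical choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; sub-seeds are spawned as integers below 2³¹.
- Stored synthetic labels pass through the dataset's canonical unit-sum
  renormalisation; replaying a provenance row and renormalising reproduces
  the stored row bit-for-bit.
- Distance ties in neighbour search sort by (distance, index); class ties
  by lowest index.
- CSV serialisation uses 17 significant digits, making write/read an exact
  round trip at double precision.

## Known limitations

- Feature-space k-NN uses unscaled Euclidean distance; with features on
  very different scales the neighbourhood structure is dominated by the
  largest-scale feature. Standardise features first if that is a concern.
- Minority-class candidates are defined by label argmax; labels near the
  centre of the simplex contribute mass to a class without ever being
  candidates for it.
- The harness treats regressors as black boxes and performs no
  hyperparameter tuning; comparisons are at fixed regressor settings.
- No significance testing is performed on metric differences across arms;
  the summary reports means and standard deviations only.
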