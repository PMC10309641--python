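# compsmote

Oversampling for regression datasets whose labels are **compositional** —
probability vectors on the simplex — together with the synthetic-data
generator, evaluation metrics and benchmarking harness needed to study when
rebalancing such datasets helps.

## The problem

In many mapping and mixture problems (seabed cover from satellite segments,
tissue composition from spectra, community composition from samples) each
observation carries a label `y ∈ S^K = {y : y_j ≥ 0, Σ_j y_j = 1}` rather
than a single class. A regressor is trained to predict the whole probability
vector. When most of the label mass belongs to one class, models fit the
dominant class well and the rare ones poorly — the classic imbalance problem,
but in a setting where neither classification SMOTE nor single-target
regression resampling applies, because averaging compositions with ordinary
Euclidean arithmetic is not meaningful on the simplex.

Imbalance is measured through the **sum vector** `S_j = Σ_i y_ij`; the
majority class is `argmax(S)` and the minority class `argmin(S)`.

## The method

The oversampler adapts SMOTE to Aitchison geometry. Until the minority mass
catches up with the majority's, it repeatedly:

1. takes the current minority class `m = argmin(S)` and the set
   `D = {i : argmax(y_i) = m}` of original points dominated by `m`;
2. picks a random `r1 ∈ D` and a random `r2` among its `k` nearest
   neighbours within `D` (Euclidean distance on the features);
3. draws `w ~ U[0, 1]` and creates a synthetic point with features
   `x_new = w·x_r1 + (1−w)·x_r2` and label
   `y_new = (w ⊗ y_r1) ⊕ ((1−w) ⊗ y_r2)`,

where `⊕` (perturbation) and `⊗` (power) are the simplex analogues of
addition and scalar multiplication: `x ⊕ y = C(x_1 y_1, …, x_K y_K)` and
`α ⊗ x = C(x_1^α, …, x_K^α)` with `C` the closure (unit-sum normalisation).
Equivalently the label can be combined in log-ratio space,
`clr⁻¹(w·clr(y_r1) + (1−w)·clr(y_r2))` with `clr(x)_j = log(x_j / g(x))`
and `clr⁻¹ = softmax`; both variants are implemented and agree to numerical
precision. Because both parents are dominated by `m`, every synthetic label
satisfies `y_new[m] > y_new[M]`, so each iteration closes the gap between
minority and majority mass and the loop terminates.

Supporting components:

- **simplex_core** — closure, zero replacement (`1e-20`), clr/softmax,
  perturbation, power;
- **synthetic_data** — datasets with uniform features and labels drawn from
  `Dirichlet(α)`, `α = softmax(x'·B)` for a coefficient matrix `B`
  (row 0 = intercepts), plus deletion- and intercept-based imbalancing;
- **metrics** — cross-entropy, macro/per-class R², class-averaged RMSE,
  and accuracy/macro-F1 on the argmax classes;
- **evaluation** — replicated raw-vs-oversampled comparisons and imbalance
  sweeps with pluggable regressors (a least-squares-on-clr baseline is
  built in);
- **interface / CLI** — CSV I/O and the `compsmote` command with
  `generate`, `oversample`, `evaluate` and `benchmark` subcommands.

## Worked example

Create a 2-feature, 2-class dataset, make it imbalanced by deleting 90% of
the points dominated by class 0, and rebalance it:

```python
import numpy as np
from compsmote import GeneratorConfig, generate_dataset, oversample
from compsmote.synthetic_data import B_CLOSE, imbalance_by_deletion

full = generate_dataset(GeneratorConfig(n=400, p=2, k=2, seed=2), B_CLOSE)
data = imbalance_by_deletion(full, class_index=0, fraction=0.9, seed=2)

S = data.labels.sum(axis=0)
print(f"n = {data.n}, class sums before: {np.round(S, 1)}")

result = oversample(data, k=10, method="compositional", seed=0)
print(f"synthetic points created: {result.n_synthetic}")
print(f"class sums after: {np.round(result.class_sums, 1)}")
print(result.provenance.head(3).to_string(index=False))
```

Output:

```
n = 234, class sums before: [ 41.1 192.9]
synthetic points created: 189
class sums after: [211.8 211.2]
 r1  r2        w  target_class
208 105 0.269787             0
 58 110 0.016528             0
 30 203 0.912756             0
```

After deletion class 1 holds 192.9 of the 234 units of label mass (~82%);
189 synthetic class-0-dominated points bring class 0's mass (211.8) up to
the majority's (211.2). The provenance table records, for every synthetic
point, its two parents and the interpolation weight, so any point can be
reproduced exactly.

The same pipeline from the shell:

```sh
compsmote generate --n 400 --p 2 --k 2 --seed 2 --features X.csv --labels Y.csv
compsmote oversample --features X.csv --labels Y.csv --k-neighbors 10 \
    --method compositional --seed 0 --out-features synX.csv --out-labels synY.csv
```

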