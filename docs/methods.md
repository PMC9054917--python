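# Methods

## Model and assumptions

`mlmr` learns one scoring function per label in the RKHS of a Gaussian
kernel, jointly over labeled and unlabeled training instances. The
estimator is multi-label Laplacian-regularized least squares: a squared
loss on the labeled rows, an ambient RKHS-norm penalty `γ_A ‖f‖_K²`, and
an intrinsic penalty `(γ_I / n²) tr(Fᵀ L F)` that forces the n×L score
matrix `F` to vary slowly over a similarity graph built from *all*
instances. The method is useful exactly when the cluster/manifold
assumption holds — instances that are close on the data manifold tend to
share label vectors. When it does not (labels uncorrelated with feature
geometry), the intrinsic term is pure shrinkage and `γ_I` should be 0,
which degenerates the model to weighted kernel ridge regression per
label.

Because the loss is squared error per label and the penalties are sums
over labels, the L label functions couple only through the shared kernel
and graph; the coefficient matrix `Θ` (n×L) solves one linear system
with L right-hand sides:

```
(Ψ K Ξ + l γ_A I + (l γ_I / n²) L K Ξ) Θ = Y.
```

We solve this system directly (LAPACK `gesv` via `scipy.linalg.solve`)
rather than forming the printed inverse, and refuse to return
coefficients when the 2-norm condition number exceeds 1e12. `γ_A > 0` is
enforced — it is what guarantees a unique minimizer; `γ_I ≥ 0` is free.

**Reliance weighting.** The diagonal matrix `Ξ` rescales the kernel
columns per training instance, `K̃ = K Ξ`. Under the uniform strategy
`Ξ_i = ν₁` for labeled and `ν₂` for unlabeled instances. The weighted
kernel stays positive semi-definite only for `Ξ_i ≥ 0`, so negative
weights are rejected at construction. Settings of interest:
`ν₁ = ν₂ = 1` (unweighted model, "ML-MR"), `ν₁ = 1, ν₂ ∈ (0, 1)`
(weighted, "ML-MRRW", default 0.1), `ν₂ = 0` (purely supervised limit:
unlabeled coefficient rows are multiplied by zero wherever they could
reach a prediction, which the test suite verifies exactly).

A caveat we document rather than hide: the stationarity condition of the
weighted objective is not exactly the printed closed form when `Ξ ≠ I`
(extra terms of the form `γ_A (I − Ψ) K Ξ Θ` survive). We implement the
closed form as stated; the optimizer-equivalence test is therefore
asserted for `Ξ = I` only, where the closed form probably coincides with
the true minimizer (and demonstrably does, to 1e-6 relative, against
L-BFGS on random problems).

## Graph construction

Kernel `U_ij = exp(−‖x_i−x_j‖²/2σ²)`, kernel-induced distance
`H_ij = sqrt(U_ii + U_jj − 2U_ij) = sqrt(2 − 2U_ij)`, then one of three
sparsifiers, then edge weights, then `L = D − W`.

Numerical/convention choices:

* **ε rule.** Two modes are shipped. `conventional` (default) keeps
  edges with `H_ij ≤ ε` — the standard ε-ball. `as_printed` keeps edges
  with `1 − H_ij ≤ ε`, a literal alternative found in parts of the
  literature which selects the *complementary* (large-distance) edge
  set; it is exposed so either reading can be reproduced, with the
  discrepancy documented here.
* **kNN.** Row-wise k smallest distances, stable argsort so ties break
  toward the smaller instance index, then symmetrization
  `B_ij ← max(B_ij, B_ji)`; row degrees are ≥ k after the merge.
* **b-matching.** Exact minimum-weight b-matching via integer
  programming (`scipy.optimize.milp` on the edge-incidence LP with
  integrality) for n ≤ 12; above that a deterministic
  greedy-with-repair heuristic: edges added in ascending distance under
  degree caps, then deficits repaired by direct deficit-deficit edges or
  by rewiring an existing edge (s,t) into (u,s)+(v,t). If repair stalls
  the builder falls back to a circulant b-regular graph, so feasibility
  (exact degree b, symmetry, zero diagonal) is guaranteed whenever
  `n·b` is even and `b < n`. The returned metadata records which solver
  ran and whether optimality is certified.
* **Edge weights.** `distance` (default) sets `W_ij = H_ij B_ij`;
  `similarity` sets `W_ij = U_ij B_ij`. The default follows the source
  formulation in which the retained distance itself weights the edge;
  the similarity scheme is the textbook choice and is one flag away.
  Both produce symmetric non-negative `W`, hence a PSD Laplacian.
* **Bandwidth.** `σ` has no universal default; where the caller does not
  supply one the protocol and CLI use the median pairwise distance
  heuristic, a standard scale-free choice.

## Metrics

Average precision ranks all L labels per instance by descending score
(ties → smaller label index) and averages, over relevant labels, the
fraction of relevant labels at or above each relevant label's rank.
Instances with no relevant label are skipped and counted (`n_skipped`);
if every instance is skipped the metric is undefined and raises.
Micro-F1 pools tp/fp/fn over labels; macro-F1 averages per-label F1 with
the 0/0 := 0 convention. With continuous (tie-free) scores these
definitions coincide with scikit-learn's `label_ranking_average_precision_score`
and `f1_score`, which the tests use as an independent reference on 100
random instances.

## Significance harness

Within-block ranks (1 = best, average ranks at ties; `scipy.stats.rankdata`),
Friedman statistic `F_R = 12/(NK(K+1)) Σ R_i² − 3N(K+1)` gated by the
upper-α chi-square quantile with K−1 degrees of freedom, and post-hoc
pairwise comparisons of `D_ij = R_i − R_j` against
`CD = z · sqrt(N K (K+1) / 6)` with `z` the upper normal quantile at
`α/(K(K−1))`. The `N` inside the CD is a caller-supplied parameter,
decoupled from the Friedman block count: published analyses in this area
print CD values that correspond to `N = 1` even when the Friedman test
used more blocks, so the default is `N = 1` (with a warning when the
caller leaves it implicit) and the √N-scaled value is one argument away.

## Experiment protocol

Per cell (repetition × labeling rate): optional subsample, a 2/3–1/3
train/test split, masking of all but `max(1, round(η·n_train))` training
label vectors, a fit per algorithm on the shared resample, and the three
metrics on the held-out third. Cell seeds derive from
`SeedSequence(master_seed, spawn_key=(rep, rate_index))`, so any cell is
reproducible in isolation and all algorithms within a cell see identical
data. Aggregation takes the mean over repetitions within each rate
(matching the mean-with-error-bars reporting convention), yielding an
N-rates × K-algorithms block table for the Friedman harness; ranking
every (repetition, rate) cell instead is available via
`rank_per="repetition"`.

Defaults: rates {5%, 10%, …, 50%}, 100 repetitions, `γ_A = 0.01`,
`γ_I = 0.1`, kNN graph with k = 10. The regularization defaults are this
package's own choice — small ambient shrinkage plus an order-of-magnitude
stronger smoothness pull, a conventional starting point for
Laplacian-RLS — and every interface exposes them for tuning.

## Synthetic data

The generator draws C cluster centers (standard Gaussian directions
rescaled so the minimum pairwise center distance equals
`center_separation`), attaches a fixed random subset of
`labels_per_cluster` positive labels to each cluster, assigns instances
to clusters uniformly, adds isotropic Gaussian feature noise
(`cluster_spread`), and flips each label entry independently with
probability `label_flip_prob`. Labels therefore correlate with feature
geometry *by construction* — the exact assumption the model exploits —
and label co-occurrence within clusters mimics the correlated label
sets of gene-function data.

`yeast_like()` presets the shape of the classic yeast benchmark
(2417 × 103 features × 14 labels) with C = 8, 4 labels per cluster and
10% flip noise, giving mean label cardinality ≈ 4.6 (the real benchmark:
≈ 4.2). What this emulates: dimensionality, label-set size, label
correlation, cluster structure, and annotation noise. What it does not:
the real data's anisotropic feature covariance, heavy-tailed label
frequencies, and label hierarchies. Passing tests on this generator
show the machinery is correct and that reliance weighting helps when
the manifold assumption holds; they do not certify performance on any
real benchmark.

## Problem sizes and determinism

The shipped test suite and the acceptance script run the benchmark
comparison on the yeast-shaped generator subsampled to n = 400 with 20
repetitions over all ten rates — sizes chosen so the full sweep (400
closed-form fits) stays cheap while still averaging 20 independent
resamples per rate. Every stochastic component takes an
explicit seed; identical seeds give bit-identical records tables, model
archives and generated data.

## Known limitations

* Dense n×n matrices throughout: memory and the O(n³) solve cap
  practical n at a few tens of thousands; graph cost is the known
  bottleneck of this model class. No Nyström/anchor approximations.
* The closed form is implemented as printed for `Ξ ≠ I` (see caveat
  above); no claim of exact variational optimality is made in that
  regime.
* Only the uniform reliance strategy is implemented; per-instance
  learned weights are out of scope.
* The Friedman chi-square approximation is nominal for K > 5; for small
  K the gate is conservative and is reported as such, not corrected.
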