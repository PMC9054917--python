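# mlmr — graph-based semi-supervised multi-label classification

`mlmr` implements **multi-label manifold regularization**: an inductive,
graph-based semi-supervised learner for problems where each instance can
carry several labels at once and only a small fraction of instances is
labeled. The motivating application is gene-function annotation — e.g.
assigning yeast genes to 14 functional categories from 103 expression and
phylogenetic features — but the method is generic: any numeric feature
table with a partially observed ±1 label table works.

## The model

Given `n = l + u` training instances (`l` labeled, `u` unlabeled) with
features `x_i ∈ R^d` and labels `y_i ∈ {-1, +1}^L` (all-zero rows mark
unlabeled instances), the learner minimizes, over one RKHS function per
label,

```
(1/l) tr((Ψ F − Y)ᵀ(Ψ F − Y)) + γ_A ‖f‖_K² + (γ_I / n²) tr(Fᵀ L F)
```

where `F` is the n×L score matrix, `Ψ = diag(1…1, 0…0)` restricts the
squared loss to labeled instances, `K` is a Gaussian kernel
`K(x_i, x_j) = exp(−‖x_i − x_j‖² / 2σ²)`, and `L = D − W` is the
unnormalized Laplacian of a similarity graph over **all** instances
(ε-neighborhood, k-nearest-neighbor, or b-matching sparsification). The
minimizer is a kernel expansion `F = K Ξ Θ` with the closed form

```
Θ = (Ψ K Ξ + l γ_A I + (l γ_I / n²) L K Ξ)⁻¹ Y ,
```

computed by a linear solve. `Ξ = diag(ν₁…ν₁, ν₂…ν₂)` holds per-instance
**reliance weights**: with `ν₁ = ν₂ = 1` this is the plain multi-label
Laplacian-RLS model (*ML-MR*); with `ν₁ = 1 > ν₂ > 0` labeled instances
get more influence on out-of-sample prediction (*ML-MRRW*, default
`ν₂ = 0.1`). New instances are scored by `F̃ = K_e Ξ Θ` and thresholded at
0.

The package also ships the surrounding machinery: multi-label metrics
(ranking-based average precision, micro-/macro-F1), a Friedman +
critical-difference significance harness, a repeated-resampling
labeling-rate benchmark protocol, and a synthetic generator producing
clustered multi-label data on which the graph-smoothness assumption holds.

## Worked example

```python
import numpy as np
from mlmr import (KernelConfig, HyperParams, fit_pipeline, predict_scores,
                  threshold_labels, compute_all, median_heuristic_sigma)
from mlmr.synth import SynthConfig, generate

X, Y, _ = generate(SynthConfig(n=300, d=20, L=8, C=4, seed=0))
train, test = np.arange(200), np.arange(200, 300)
Y_partial = Y[train].astype(float)
Y_partial[40:] = 0.0          # keep 20% of training labels

model, graph = fit_pipeline(
    X[train], Y_partial,
    kernel_cfg=KernelConfig(sigma=median_heuristic_sigma(X[train])),
    hyper=HyperParams(gamma_A=0.01, gamma_I=0.1, nu1=1.0, nu2=0.1),
)
scores = predict_scores(model, X[test])
print(compute_all(scores, threshold_labels(scores), Y[test]))
```

prints

```
{'avgprec': 0.9031218253968254, 'micro_f1': 0.8309178743961353, 'macro_f1': 0.7153917134497241}
```

i.e. with only 40 of 200 training instances labeled, held-out relevant
labels are ranked near the top of each instance's label ordering
(average precision ≈ 0.90) and the thresholded label assignments reach
F1 ≈ 0.83 when counts are pooled across labels (micro) and ≈ 0.72 when
averaged per label (macro, which weights rare labels equally).

The same pipeline is available from the shell:

```bash
mlmr simulate --n 300 --seed 0 --out data/
mlmr fit --features data/features.csv --labels data/labels.csv --nu2 0.1 --out model.npz
mlmr predict --model model.npz --features data/features.csv --out pred/
mlmr benchmark --features data/features.csv --labels data/labels.csv --reps 10 --out bench/
mlmr stats --records bench/records.csv
```

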