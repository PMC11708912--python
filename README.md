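# mdsd — hub-gene screening from graphical-model solution paths

Co-expression networks built from gene expression data typically contain a
small number of hub genes that coordinate many downstream interactions.
Sparse Gaussian graphical-model estimators (correlation thresholding, the
graphical lasso, the hub graphical lasso) produce not one network but a
whole *solution path* of networks as their regularization parameters vary,
and the common practice of selecting a single "best" model throws most of
that information away — and tends to select very sparse or empty graphs
when samples are scarce.

This package screens for hub genes using the entire path. For node i and a
tuning-parameter grid Λ with |Λ| = m, the **Mean Degree Squared Distance**

    MDSD_i = 1/(m(p−1)) · Σ_{λ∈Λ} Σ_{j≠i} [d̂_i(λ) − d̂_j(λ)]²

(with the obvious M = Π m_k generalization for estimators with several
tuning parameters) measures how far node i's estimated degree d̂_i(λ) sits
from everyone else's across the whole path — an influence statistic in the
spirit of Cook's distance, and a resampling-free relative of stability
selection. Node i is called a hub when MDSD_i > γ · mean(MDSD), with
γ = 3 by default. Path models whose degree distribution is not
right-skewed (not power-law-like, skewness ≤ 0.5) can be dropped before
computing MDSD, which markedly improves hub detection at small sample
sizes.

The package ships:

* `MDSDHubDetector` — a scikit-learn-style estimator: expression matrix
  in, hub calls out;
* path estimators (`CorrelationThresholdPath`, `GraphicalLassoPath` with a
  fast native ADMM backend, `HubGraphicalLasso` / `HubGraphicalLassoPath`
  implementing the Θ = V + Vᵀ + Z hub decomposition);
* simulators for five benchmark topologies (star, super-hub,
  two-component, scale-free, inter-hub bottleneck) with positive-definite
  precision matrices and Gaussian sampling;
* hub-detection quality metrics (FDR, FPR, precision, TPR, MCC, bookmaker
  informedness) and a replicate-study harness;
* a `mdsd` command-line tool (`simulate`, `path`, `score`, `eval`, `plot`,
  `run-study`).

See `docs/methods.md` for the model, the solvers and all numerical
conventions.

## Worked example

Simulate a star network with 500 genes and five hub centers (each center
connected to 99 spokes), draw 110 samples, fit a 50-value graphical-lasso
path and screen hubs at γ = 3:

```python
import numpy as np
from mdsd import make_star_network, sample_gaussian
from mdsd import GraphicalLassoPath, MDSDHubDetector

truth = make_star_network(500, 5)          # centers: genes 1, 101, ... 401
data = sample_gaussian(truth, n=110, seed=1)

detector = MDSDHubDetector(estimator=GraphicalLassoPath(n_lambdas=50),
                           gamma=3.0)
detector.fit(data.to_numpy())

print("called hubs:", detector.hub_ids_)
print("true hubs:  ", sorted(truth.hub_ids))
print("cutoff:", round(detector.cutoff_, 2),
      "max MDSD:", round(detector.mdsd_.max(), 2))
```

```
called hubs: [1, 101, 201, 301, 401]
true hubs:   [1, 101, 201, 301, 401]
cutoff: 233.51 max MDSD: 1655.01
```

The five planted centers — and nothing else — exceed the cutoff: their
MDSD sits roughly 7× above the 3·mean cutoff, with every other node well
below it. At a smaller
sample size (n = 50) the unfiltered path gets noisy; passing
`s_min=0.5` to `MDSDHubDetector` drops the non-power-law-like dense models
and restores full sensitivity.

The same pipeline from the shell:

```sh
mdsd simulate --model star --p 500 --n 110 --hubs 5 --seed 1 --out sim/
mdsd path --input sim/expression.tsv --estimator glasso --nlambda 50 --out path/
mdsd score --path path/ --gamma 3 --out scores/
mdsd eval --scores scores/ --truth sim/truth.json
```

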