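# Methods

## The screening statistic

Gene co-expression networks are modelled as Gaussian graphical models
(GGMs): expression vectors Y ∈ R^p are taken as draws from N(0, Σ), and an
edge (i, j) exists exactly when the precision matrix Θ = Σ⁻¹ has a nonzero
off-diagonal entry θ_ij. Sparse estimators of Θ — here correlation
thresholding, the graphical lasso and the hub graphical lasso — produce a
*family* of graphs as their regularization parameters sweep a grid, and the
usual practice of picking one "best" model discards most of that
information. The package instead aggregates the whole path: with d̂_i(λ)
the degree of node i in the model fitted at grid point λ, the Mean Degree
Squared Distance of node i over a single-parameter grid Λ (|Λ| = m) is

    MDSD_i = 1/(m(p−1)) Σ_{λ∈Λ} Σ_{j≠i} [d̂_i(λ) − d̂_j(λ)]²,

and over a q-parameter grid the double sum runs over all M = Π m_k grid
points with a 1/(M(p−1)) normalization. Hub nodes keep an unusually high
degree across many models, so their MDSD is large relative to the bulk —
the statistic is an influence measure in the spirit of Cook's distance,
and is related to stability selection with the resampling step replaced by
a closed-form statistic over the path. A node is called a hub when

    MDSD_i > γ · (1/p) Σ_j MDSD_j,

with γ = 3 as the default multiplier (2.5 as a lenient alternative), by
analogy with common outlier-detection rules. The inequality is strict, so
ties fall to non-hub; an all-zero MDSD vector yields no hubs.

The implementation computes the inner sum per model through the O(p)
identity Σ_{j≠i}(d_i − d_j)² = p·d_i² − 2·d_i·S + Q, with S = Σ_j d_j and
Q = Σ_j d_j², giving O(pM) overall; the test suite checks bit-level
agreement with the literal O(p²M) double loop.

Useful identities asserted as properties: MDSD is invariant to the order
and duplication of path models, scales quadratically when all degrees are
scaled, and satisfies Σ_i MDSD_i = 2p²/(p−1) × the mean (population)
variance of the degree columns.

## Skewness filtering

Real co-expression networks have approximately power-law (right-skewed)
degree distributions. Along a glasso path the weakly regularized models
become dense and their degree distributions approximately symmetric; those
models contribute degree noise to every node's MDSD. The filter computes
the Fisher–Pearson moment skewness g1 = m₃/m₂^{3/2} (no small-sample
correction — the population-moment form is the plainest reading of
"skewness", and an adjusted variant is available by flag) of each model's
degree column and retains only models with defined skewness strictly above
a threshold s_min: 0.5 as the general default, 1.0 in the stricter
protocol used with the hub graphical lasso. Constant-degree models (e.g.
empty graphs), where skewness is undefined, are always dropped when the
filter is active; with the filter off they are retained and contribute
zero to every node. MDSD is renormalized by the retained model count, so
filtered and unfiltered values are on the same scale. If no model
survives, the pipeline raises an explicit error asking for a revised grid
rather than returning a vacuous result.

The cumulative-MDSD diagnostic orders the (single-axis) path by decreasing
tuning parameter — sparse models first — and reports the running prefix
sums C_i(k), which reach MDSD_i at k = M. C_i is non-decreasing in k but
deliberately *not* a monotone function of node degree, which is why the
full path, not a single model's degree ranking, is informative.

## Estimators

**Correlation thresholding** (the lossy screening rule): edge (i, j) iff
|r_ij| > λ for the sample Pearson correlation r. Thresholds live in
[0, 1]; edge sets are nested along the grid.

**Graphical lasso**: Θ̂(λ) = argmin_{Θ≻0} {−log det Θ + tr(SΘ) +
λ‖Θ‖_{1,off}}. The path engine is a native ADMM solver (splitting Θ = Z):
the Θ-update is the closed-form eigendecomposition prox of the log-det
term, the Z-update an elementwise soft-threshold at λ/ρ (diagonal
unpenalized, matching the scikit-learn convention), and the scaled dual
accumulates the gap. Iterates warm-start along the grid from the sparse
end, and ρ is rebalanced (doubled/halved with dual rescaling) when the
primal and dual residuals drift more than a factor 10 apart. Stopping:
both Frobenius residuals below 1e-5·p. The Z iterate is exactly sparse and
supplies the edge support. A per-λ coordinate-descent solve delegated to
`sklearn.covariance.graphical_lasso` is available as `backend="sklearn"`
and doubles as the independent cross-check: on small instances the two
backends give the same edge supports at the default tolerances, up to an
occasional borderline edge sitting exactly at the zero threshold. The native
engine exists because a 50-value path at p = 500 from a rank-deficient
sample correlation (n < p) must run in tens of seconds for the replicate
studies to be practical; coordinate descent with a duality-gap stopping
rule degrades badly in that regime.

λ grids default to 50 log-spaced values from λ_max = max_{i≠j} |s_ij| (the
smallest penalty giving an empty graph) down to 0.1·λ_max — the convention
of the standard R path utilities. Estimators work on the sample
correlation matrix by default (covariance by flag).

**Hub graphical lasso**: Θ is decomposed as V + Vᵀ + Z and estimated by

    argmin −log det Θ + tr(SΘ) + λ1‖Z‖_{1,off} + λ2‖V‖_{1,off}
           + λ3 Σ_j ‖(V − diag V)_j‖₂   s.t.  Θ = V + Vᵀ + Z,

so λ1 controls non-hub edge sparsity, λ2 within-column sparsity of V and
λ3 the number of active columns — each active column of V̂ is a candidate
hub. The solver is a consensus ADMM: prox copies of Θ (log-det
eigendecomposition prox), Z (soft-threshold λ1/ρ) and V (composite prox:
elementwise soft-threshold at λ2/ρ, then columnwise group soft-threshold
at λ3/ρ, diagonal excluded) are each matched to consensus copies that
satisfy the decomposition constraint exactly; the consensus update is the
closed-form Euclidean projection onto {Θ̃ = Ṽ + Ṽᵀ + Z̃}, i.e. with
A = Θ + W_Θ, B = V + W_V, C = Z + W_Z and Γ = (A − B − Bᵀ − C)/6,
Θ̃ = A − Γ, Ṽ = B + 2Γ, Z̃ = C + Γ. ADMM hyperparameters: ρ = 2.5,
max 1000 iterations, absolute residual tolerance 1e-5·p, matching the
conventions of the reference implementation of this estimator. At
convergence the reported constraint residual ‖Θ̂ − V̂ − V̂ᵀ − Ẑ‖_max is
below 1e-4 on all tested instances, Θ̂ is positive definite by
construction of the prox, and with λ2 = λ3 → ∞ the fit provably collapses
to the plain graphical lasso at λ1 (verified against the delegated solver).
Edge support along hglasso paths is read from the exactly-sparse surrogate
V̂ + V̂ᵀ + Ẑ with a 1e-6 zero tolerance — ADMM iterates carry approximate
zeros, so exact-zero tests on Θ̂ would be wrong.

Solver failures at individual grid points are warned about, recorded in
the path manifest and dropped — never silently zero-filled; MDSD then
normalizes by the retained count.

## Simulators

Five ground-truth topologies, each returned with a positive-definite
precision matrix whose support equals the adjacency:

* **star** — n_hubs disjoint star components of (near) equal size;
  remainder nodes join the last component. star(p, h) has p − h edges.
* **hub** — "super-hub" graphs: each of n_hubs random hubs connects to
  every other node independently with probability 0.7; non-hub pairs with
  background density 0.02.
* **two_hub** — block-diagonal union of two independent hub networks.
* **scale_free** — Barabási–Albert preferential attachment (m = 1 gives a
  spanning tree). Scale-free graphs have no sharply separated hubs, so
  true hubs are defined as nodes with degree > 3× the mean (the factor is
  a parameter).
* **inter_hub** — star modules whose centers are joined through one extra
  bottleneck node: degree n_modules (low), but its removal disconnects the
  modules (high betweenness).

Precision matrices follow the convention of the standard R simulation
utilities for GGMs: Θ_off = 0.3 × adjacency (optionally with random
signs), diagonal = |λ_min(Θ_off)| + 0.1 + u with u = 0.1, then
Σ = cov2cor(Θ⁻¹) so variables have unit variance. All constants are
exposed (`edge_value`, `conditioning`). This construction puts star
hub–spoke partial correlations near 0.09 at p = 500 — a genuinely
high-dimensional, low-signal regime in which the n = 110 experiments
below still succeed; inflating the diagonal further (e.g. adding 1) buries
the signal below sampling noise and no path estimator recovers the hubs.

Data are i.i.d. draws from N(0, Σ), deterministic given a seed. The
generator emulates the Gaussian, stationary, mean-zero world of the GGM
definition; it does not emulate counts, over-dispersion, batch structure
or outliers, so passing tests say nothing about normalization choices on
real RNA-seq data (the pipeline expects pre-normalized input and
deliberately does not reimplement variance-stabilizing transforms).

## Scoring

Hub calls against the planted hub set give TP/FP/TN/FN per replicate and
six metrics: FDR, FPR, precision, TPR, MCC and bookmaker informedness
(BM = TPR − FPR). Conventions for degenerate cases: FDR and precision are
undefined (NaN) when no calls are made and are excluded from replicate
averages, with the number of zero-call replicates reported; MCC is 0
whenever a factor of its denominator is 0 (the standard neutral
convention). Replicate summaries are means of per-replicate metrics, not
metrics of pooled counts.

## Study regimes and problem sizes

The two headline experiments use a star network with p = 500 and five
centers (hub degree 99, all other degrees 1), a 50-value glasso λ grid and
γ = 3:

* n = 110, no filter — the five centers, and only those, are flagged in
  the typical seed (the suite asserts median TP = 5, median FP = 0 over
  10 seeds).
* n = 50, skewness filter at 0.5 — the filter restores full sensitivity
  (median TP = 5) where the unfiltered path misses centers; with only 50
  samples against 500 variables a small number of non-center nodes can
  exceed the 3·mean cutoff in some seeds, so specificity is not asserted
  in this regime.

Replicate studies in the unit tests run at p = 100 and R ≤ 5 to keep the
default suite fast; the p = 500 regimes above are exercised once each, in
the end-to-end tests and in `scripts/acceptance.py` (10 seeds per regime).

## Known limitations

* The hub graphical lasso path at genome scale (p ≈ 1000, dozens of grid
  points) takes hours, as expected for eigendecomposition-based ADMM; the
  package targets desk-scale studies and pre-filtered gene sets (the
  `select_top_variance_genes` helper implements the usual top-variance
  pre-filter).
* γ and s_min are screening conventions, not calibrated error rates; no
  p-values or FDR control are attached to the cutoff.
* The statistic can in principle be large for a low-degree node in a
  network dominated by many high-degree nodes; the degree-path and
  cumulative-MDSD plots exist to diagnose exactly that situation.
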