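"""Sparse-graph estimators producing regularization solution paths.

Three route families from an expression matrix (or a precomputed
correlation/covariance matrix) to a family of undirected graphs indexed by
tuning-parameter values:

* correlation thresholding — edge when ``|r_ij| > λ`` (the lossy screening
  rule);
* the graphical lasso — L1-penalized Gaussian maximum likelihood, solved
  natively by ADMM with warm starts along the λ grid (scikit-learn's
  ``graphical_lasso`` is available as an alternative backend and serves as a
  cross-check on small problems);
* the hub graphical lasso — the precision matrix is decomposed as
  ``Θ = V + Vᵀ + Z`` with an elementwise L1 penalty ``λ1`` on Z, an
  elementwise L1 penalty ``λ2`` and a columnwise group-L2 penalty ``λ3`` on V,
  so that selected columns of V correspond to hub nodes.

All estimators follow the scikit-learn protocol: configure in ``__init__``,
``fit(X)``, read fitted attributes with trailing underscores.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "TuningGrid",
    "AdjacencyPath",
    "HglassoFit",
    "CorrelationThresholdPath",
    "GraphicalLassoPath",
    "HubGraphicalLasso",
    "HubGraphicalLassoPath",
    "correlation_threshold_path",
    "glasso_path",
    "hglasso_fit",
    "hglasso_path",
    "default_lambda_grid",
    "support_from_precision",
    "correlation_matrix",
]


# --------------------------------------------------------------------------
# grid and path containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningGrid:
    """An ordered Cartesian grid of positive tuning-parameter values.

    ``axes`` maps axis names to 1-D value arrays.  Models are enumerated in
    C order (last axis varies fastest); :meth:`points` yields one dict per
    model in that fixed order, so path columns are reproducible.
    """

    axes: tuple  # tuple of (name, tuple-of-values) pairs

    def __init__(self, axes, allow_zero=False):
        if isinstance(axes, dict):
            axes = list(axes.items())
        cleaned = []
        for name, values in axes:
            values = tuple(float(v) for v in np.atleast_1d(values))
            lo = 0.0 if allow_zero else None
            if any(v < 0 or (lo is None and v == 0) for v in values):
                raise ValueError(
                    f"tuning-parameter axis {name!r} must be strictly "
                    f"positive, got {values}"
                )
            if len(set(values)) != len(values):
                raise ValueError(f"axis {name!r} has duplicate values")
            cleaned.append((name, values))
        if not cleaned:
            raise ValueError("grid needs at least one axis")
        object.__setattr__(self, "axes", tuple(cleaned))

    @property
    def q(self) -> int:
        return len(self.axes)

    @property
    def sizes(self) -> tuple:
        return tuple(len(v) for _, v in self.axes)

    @property
    def n_models(self) -> int:
        return int(np.prod(self.sizes))

    @property
    def names(self) -> tuple:
        return tuple(n for n, _ in self.axes)

    def points(self):
        """Yield one ``{axis: value}`` dict per model, C enumeration order."""
        names = self.names
        for combo in itertools.product(*(v for _, v in self.axes)):
            yield dict(zip(names, combo))

    @property
    def values(self) -> np.ndarray:
        """Values of a single-axis grid as an array (error if q > 1)."""
        if self.q != 1:
            raise ValueError("grid has more than one axis")
        return np.asarray(self.axes[0][1])

    def to_dict(self) -> dict:
        return {
            "axes": {n: list(v) for n, v in self.axes},
            "order": "C (last axis fastest)",
            "n_models": self.n_models,
        }


@dataclass
class AdjacencyPath:
    """A solution path: one binary graph per grid point.

    ``graphs`` holds M boolean ``(p, p)`` adjacency arrays aligned with the
    grid enumeration order.  Models the solver failed on are recorded in
    ``failures`` (grid index -> message) and are absent from ``graphs`` /
    ``kept_indices``.
    """

    grid: TuningGrid
    graphs: list
    estimator_name: str
    zero_tolerance: float
    kept_indices: list = None
    failures: dict = field(default_factory=dict)
    node_ids: list = None

    def __post_init__(self):
        if self.kept_indices is None:
            self.kept_indices = list(range(len(self.graphs)))
        for g in self.graphs:
            if g.shape[0] != g.shape[1]:
                raise ValueError("adjacency must be square")
            if np.any(np.diag(g)):
                raise ValueError("adjacency must have zero diagonal")
        if self.node_ids is None and self.graphs:
            p = self.graphs[0].shape[0]
            self.node_ids = [f"G{i}" for i in range(1, p + 1)]

    @property
    def p(self) -> int:
        return self.graphs[0].shape[0]

    @property
    def n_models(self) -> int:
        return len(self.graphs)

    def degree_matrix(self) -> np.ndarray:
        """p × M matrix of node degrees, one column per retained model."""
        if not self.graphs:
            raise ValueError("path is empty")
        return np.column_stack([g.sum(axis=1) for g in self.graphs]).astype(int)


@dataclass
class HglassoFit:
    """Solution of one hub-graphical-lasso problem."""

    theta: np.ndarray
    v: np.ndarray
    z: np.ndarray
    lambdas: dict
    n_iter: int
    converged: bool
    primal_residual: float
    dual_residual: float

    @property
    def constraint_residual(self) -> float:
        """Max-norm violation of Θ = V + Vᵀ + Z."""
        return float(
            np.max(np.abs(self.theta - self.v - self.v.T - self.z))
        )

    def hub_column_sizes(self) -> np.ndarray:
        """Number of nonzero off-diagonal entries per column of V̂."""
        v = self.v.copy()
        np.fill_diagonal(v, 0.0)
        return (np.abs(v) > 1e-8).sum(axis=0)


# --------------------------------------------------------------------------
# input handling
# --------------------------------------------------------------------------

def correlation_matrix(X) -> np.ndarray:
    """Sample Pearson correlation of a samples × genes matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D samples x genes matrix with n >= 2")
    if not np.isfinite(X).all():
        raise ValueError("expression matrix contains non-finite values")
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    return R


def _as_symmetric(S, name="matrix", tol=1e-8):
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.isfinite(S).all():
        raise ValueError(f"{name} contains non-finite values")
    if np.max(np.abs(S - S.T)) > tol:
        raise ValueError(f"{name} is not symmetric")
    return (S + S.T) / 2.0


def _input_matrix(X, precomputed, use_correlation):
    """Resolve estimator input to a symmetric working matrix S."""
    if precomputed:
        return _as_symmetric(X, "precomputed input")
    X = np.asarray(X, dtype=float)
    if use_correlation:
        return correlation_matrix(X)
    if X.shape[0] < 2:
        raise ValueError("need n >= 2 samples")
    return np.cov(X, rowvar=False)


def default_lambda_grid(S, n_lambdas=50, ratio=0.1, name="lambda"):
    """Log-spaced grid from λ_max = max off-diagonal |s_ij| down to ratio·λ_max.

    λ_max is the smallest penalty giving an empty graphical-lasso graph.
    """
    if n_lambdas < 2:
        raise ValueError("need at least 2 grid values")
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    S = _as_symmetric(S)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError(
            "all off-diagonal entries are zero; no meaningful grid exists"
        )
    values = np.geomspace(lam_max, ratio * lam_max, n_lambdas)
    return TuningGrid([(name, values)])


def support_from_precision(theta, zero_tolerance=1e-6):
    """Binary edge structure from a (symmetric) precision-type matrix."""
    theta = _as_symmetric(theta, "precision", tol=max(zero_tolerance, 1e-8))
    adj = np.abs(theta) > zero_tolerance
    np.fill_diagonal(adj, False)
    return adj


# --------------------------------------------------------------------------
# ADMM solvers
# --------------------------------------------------------------------------

def _logdet_prox(A, S, rho):
    """argmin_Θ  -logdet Θ + tr(SΘ) + (ρ/2)‖Θ − A‖²  via eigendecomposition."""
    d, Q = np.linalg.eigh(rho * A - S)
    theta_d = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
    return (Q * theta_d) @ Q.T


def _soft(A, thr):
    return np.sign(A) * np.maximum(np.abs(A) - thr, 0.0)


def _admm_glasso(S, lam, rho=1.0, Z=None, U=None, max_iter=1000, tol=1e-5,
                 adapt_rho=True):
    """One graphical-lasso solve; (Z, U) warm starts carry along a path.

    Splitting Θ = Z with scaled dual U; the Z iterate is exactly sparse and
    provides the edge support.  ρ is rebalanced when the primal and dual
    residuals drift apart (halved/doubled with dual rescaling).
    """
    p = S.shape[0]
    if Z is None:
        Z = np.eye(p)
    if U is None:
        U = np.zeros((p, p))
    r = s = np.inf
    for it in range(max_iter):
        Theta = _logdet_prox(Z - U, S, rho)
        Z_old = Z
        A = Theta + U
        Z = _soft(A, lam / rho)
        np.fill_diagonal(Z, np.diag(A))
        U = U + Theta - Z
        r = np.linalg.norm(Theta - Z)
        s = rho * np.linalg.norm(Z - Z_old)
        if r < tol * p and s < tol * p:
            return Theta, Z, U, it + 1, rho, True
        if adapt_rho:
            if r > 10.0 * s:
                rho *= 2.0
                U /= 2.0
            elif s > 10.0 * r:
                rho /= 2.0
                U *= 2.0
    return Theta, Z, U, max_iter, rho, False


def _admm_hglasso(S, lam1, lam2, lam3, rho=2.5, max_iter=1000, tol=1e-5,
                  init=None):
    """Consensus ADMM for the hub graphical lasso, Θ = V + Vᵀ + Z.

    Each of Θ, Z, V gets a prox update against its consensus copy — Θ by
    the log-det eigendecomposition prox, Z by elementwise soft-thresholding
    at λ1/ρ (off-diagonal), V by the composite prox: elementwise
    soft-threshold at λ2/ρ followed by a columnwise group soft-threshold at
    λ3/ρ, diagonal excluded.  The consensus copies (Θ̃, Ṽ, Z̃) are the
    Euclidean projection of the shifted iterates onto the subspace
    Θ̃ = Ṽ + Ṽᵀ + Z̃, which is closed-form: with A = Θ + WΘ, B = V + WV,
    C = Z + WZ and Γ = (A − B − Bᵀ − C)/6,

        Θ̃ = A − Γ,   Ṽ = B + 2Γ,   Z̃ = C + Γ.

    Scaled duals WΘ, WV, WZ track the consensus gaps.
    """
    p = S.shape[0]
    if init is None:
        Theta = np.diag(1.0 / np.maximum(np.diag(S), 1e-8))
        Z = Theta.copy()
        V = np.zeros((p, p))
        Tt, Vt, Zt = Theta.copy(), V.copy(), Z.copy()
        WT = np.zeros((p, p))
        WV = np.zeros((p, p))
        WZ = np.zeros((p, p))
    else:
        Theta, V, Z, Tt, Vt, Zt, WT, WV, WZ = (m.copy() for m in init)
    r = s = np.inf
    for it in range(max_iter):
        Theta = _logdet_prox(Tt - WT, S, rho)
        # Z prox: L1 off the diagonal
        CZ = Zt - WZ
        Z = _soft(CZ, lam1 / rho)
        np.fill_diagonal(Z, np.diag(CZ))
        # V prox: elementwise L1 then columnwise group L2, diagonal free
        CV = Vt - WV
        diag_cv = np.diag(CV).copy()
        V = _soft(CV, lam2 / rho)
        np.fill_diagonal(V, 0.0)
        norms = np.linalg.norm(V, axis=0)
        scale = np.maximum(0.0, 1.0 - (lam3 / rho) / np.maximum(norms, 1e-12))
        V *= scale[np.newaxis, :]
        np.fill_diagonal(V, diag_cv)
        # projection onto the decomposition subspace
        A = Theta + WT
        B = V + WV
        C = Z + WZ
        Gamma = (A - B - B.T - C) / 6.0
        Tt_old, Vt_old, Zt_old = Tt, Vt, Zt
        Tt = A - Gamma
        Vt = B + 2.0 * Gamma
        Zt = C + Gamma
        WT = WT + Theta - Tt
        WV = WV + V - Vt
        WZ = WZ + Z - Zt
        r = np.sqrt(np.linalg.norm(Theta - Tt) ** 2
                    + np.linalg.norm(V - Vt) ** 2
                    + np.linalg.norm(Z - Zt) ** 2)
        s = rho * np.sqrt(np.linalg.norm(Tt - Tt_old) ** 2
                          + np.linalg.norm(Vt - Vt_old) ** 2
                          + np.linalg.norm(Zt - Zt_old) ** 2)
        if r < tol * p and s < tol * p:
            break
    converged = r < tol * p and s < tol * p
    state = (Theta, V, Z, Tt, Vt, Zt, WT, WV, WZ)
    return Theta, V, Z, state, it + 1, converged, r, s


# --------------------------------------------------------------------------
# estimator classes
# --------------------------------------------------------------------------

class _PathEstimatorBase(BaseEstimator):
    """Shared fit plumbing: resolve input to S, build grid, fill path_."""

    def _resolve(self, X):
        return _input_matrix(X, self.precomputed, self.use_correlation)

    def degree_matrix(self):
        check_is_fitted(self, "path_")
        return self.path_.degree_matrix()


class CorrelationThresholdPath(_PathEstimatorBase):
    """Edge when the absolute Pearson correlation exceeds a threshold.

    The lossy screening rule: graph at λ has edge (i, j) iff ``|r_ij| > λ``.
    Thresholds live in [0, 1]; edge sets are nested and shrink as λ grows.

    Parameters
    ----------
    thresholds : array-like or None
        Explicit threshold grid.  When None, ``n_thresholds`` values evenly
        spaced on (0, max |r_ij|] are used.
    n_thresholds : int
        Grid size when ``thresholds`` is None.
    precomputed : bool
        When True, ``fit`` expects a correlation matrix instead of data.
    """

    def __init__(self, thresholds=None, n_thresholds=50, precomputed=False):
        self.thresholds = thresholds
        self.n_thresholds = n_thresholds
        self.precomputed = precomputed

    use_correlation = True

    def fit(self, X, y=None):
        R = self._resolve(X)
        if self.precomputed and np.max(np.abs(np.diag(R) - 1.0)) > 1e-6:
            raise ValueError("precomputed input must be a correlation matrix "
                             "with unit diagonal")
        if np.max(np.abs(R)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.thresholds is not None:
            values = np.asarray(self.thresholds, dtype=float)
        else:
            off_max = np.max(np.abs(R - np.diag(np.diag(R))))
            if off_max <= 0:
                raise ValueError("all correlations are zero")
            values = np.linspace(off_max / self.n_thresholds, off_max,
                                 self.n_thresholds)
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("thresholds must lie in [0, 1]")
        grid = TuningGrid([("lambda", values)], allow_zero=True)
        absR = np.abs(R)
        graphs = []
        for pt in grid.points():
            adj = absR > pt["lambda"]
            np.fill_diagonal(adj, False)
            graphs.append(adj)
        self.correlation_ = R
        self.grid_ = grid
        self.path_ = AdjacencyPath(grid, graphs, "threshold", 0.0)
        return self


class GraphicalLassoPath(_PathEstimatorBase):
    """Graphical-lasso solution path over a λ grid.

    Solves the L1-penalized Gaussian log-likelihood problem for each λ and
    records the estimated edge structure.  The default backend is a native
    ADMM solver warm-started along the (decreasing) grid; ``backend="sklearn"``
    delegates each solve to :func:`sklearn.covariance.graphical_lasso`.

    Parameters
    ----------
    lambdas : array-like or None
        Explicit penalty grid; when None a log-spaced grid of ``n_lambdas``
        values from λ_max down to ``lambda_ratio``·λ_max is built from the
        working matrix.
    use_correlation : bool
        Fit on the sample correlation (default) or covariance matrix.
    zero_tolerance : float
        Off-diagonal magnitudes above this count as edges.
    """

    def __init__(self, lambdas=None, n_lambdas=50, lambda_ratio=0.1,
                 backend="admm", rho=1.0, tol=1e-5, max_iter=1000,
                 zero_tolerance=1e-6, use_correlation=True,
                 precomputed=False):
        self.lambdas = lambdas
        self.n_lambdas = n_lambdas
        self.lambda_ratio = lambda_ratio
        self.backend = backend
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter
        self.zero_tolerance = zero_tolerance
        self.use_correlation = use_correlation
        self.precomputed = precomputed

    def fit(self, X, y=None):
        S = self._resolve(X)
        if self.lambdas is not None:
            grid = TuningGrid([("lambda", self.lambdas)])
        else:
            grid = default_lambda_grid(S, self.n_lambdas, self.lambda_ratio)
        lambdas = grid.values
        order = np.argsort(lambdas)[::-1]  # warm start dense-ward
        graphs_by_index = {}
        failures = {}
        precisions = {}
        if self.backend == "admm":
            Z = U = None
            rho = self.rho
            for k in order:
                lam = lambdas[k]
                Theta, Z, U, n_iter, rho, ok = _admm_glasso(
                    S, lam, rho=rho, Z=Z, U=U, max_iter=self.max_iter,
                    tol=self.tol)
                if not ok:
                    msg = (f"glasso ADMM did not converge at lambda={lam:.4g} "
                           f"({self.max_iter} iterations); model dropped")
                    warnings.warn(msg)
                    failures[int(k)] = msg
                    continue
                adj = np.abs(Z) > self.zero_tolerance
                np.fill_diagonal(adj, False)
                graphs_by_index[int(k)] = adj
                precisions[int(k)] = Z
        elif self.backend == "sklearn":
            from sklearn.covariance import graphical_lasso as _sk_glasso
            for k in order:
                lam = lambdas[k]
                try:
                    _, prec = _sk_glasso(S, alpha=float(lam),
                                         max_iter=self.max_iter)
                except Exception as exc:  # per-model failure, never zero-fill
                    msg = f"sklearn glasso failed at lambda={lam:.4g}: {exc}"
                    warnings.warn(msg)
                    failures[int(k)] = msg
                    continue
                graphs_by_index[int(k)] = support_from_precision(
                    prec, self.zero_tolerance)
                precisions[int(k)] = prec
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        kept = sorted(graphs_by_index)
        self.working_matrix_ = S
        self.grid_ = grid
        self.precisions_ = [precisions[k] for k in kept]
        self.path_ = AdjacencyPath(grid, [graphs_by_index[k] for k in kept],
                                   f"glasso[{self.backend}]",
                                   self.zero_tolerance,
                                   kept_indices=kept, failures=failures)
        return self


class HubGraphicalLasso(BaseEstimator):
    """Hub graphical lasso at a single (λ1, λ2, λ3) point, solved by ADMM.

    The precision matrix is decomposed as Θ = V + Vᵀ + Z.  λ1 controls the
    sparsity of Z (edges between non-hub nodes), λ2 the within-column
    sparsity of V, and λ3 the number of active columns of V — each active
    column is a candidate hub.

    Fitted attributes: ``theta_``, ``v_``, ``z_``, ``n_iter_``,
    ``converged_``, ``fit_`` (an :class:`HglassoFit`).
    """

    def __init__(self, lambda1=0.4, lambda2=0.3, lambda3=1.0, rho=2.5,
                 max_iter=1000, tol=1e-5, use_correlation=True,
                 precomputed=False):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol
        self.use_correlation = use_correlation
        self.precomputed = precomputed

    def fit(self, X, y=None):
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        S = _input_matrix(X, self.precomputed, self.use_correlation)
        Theta, V, Z, _, n_iter, ok, r, s = _admm_hglasso(
            S, self.lambda1, self.lambda2, self.lambda3, rho=self.rho,
            max_iter=self.max_iter, tol=self.tol)
        if not ok:
            warnings.warn(
                f"hglasso ADMM reached max_iter={self.max_iter} without "
                f"convergence (primal residual {r:.3g})")
        self.theta_ = Theta
        self.v_ = V
        self.z_ = Z
        self.n_iter_ = n_iter
        self.converged_ = ok
        self.fit_ = HglassoFit(
            theta=Theta, v=V, z=Z,
            lambdas={"lambda1": self.lambda1, "lambda2": self.lambda2,
                     "lambda3": self.lambda3},
            n_iter=n_iter, converged=ok,
            primal_residual=float(r), dual_residual=float(s))
        return self


class HubGraphicalLassoPath(_PathEstimatorBase):
    """Hub-graphical-lasso path over the Cartesian (λ1, λ2, λ3) grid.

    Models are enumerated with λ1 as the outer axis and λ3 as the fastest
    axis; the sparse surrogate ``V + Vᵀ + Z`` supplies the edge structure of
    each model.
    """

    def __init__(self, lambda1_values=(0.4,),
                 lambda2_values=tuple(np.linspace(0.1, 1.0, 10)),
                 lambda3_values=(0.5, 1.0, 2.0), rho=2.5, max_iter=1000,
                 tol=1e-5, zero_tolerance=1e-6, use_correlation=True,
                 precomputed=False):
        self.lambda1_values = lambda1_values
        self.lambda2_values = lambda2_values
        self.lambda3_values = lambda3_values
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol
        self.zero_tolerance = zero_tolerance
        self.use_correlation = use_correlation
        self.precomputed = precomputed

    def fit(self, X, y=None):
        S = self._resolve(X)
        grid = TuningGrid([
            ("lambda1", self.lambda1_values),
            ("lambda2", self.lambda2_values),
            ("lambda3", self.lambda3_values),
        ])
        graphs = []
        kept = []
        failures = {}
        fits = []
        init = None
        for k, pt in enumerate(grid.points()):
            Theta, V, Z, state, n_iter, ok, r, s = _admm_hglasso(
                S, pt["lambda1"], pt["lambda2"], pt["lambda3"],
                rho=self.rho, max_iter=self.max_iter, tol=self.tol,
                init=init)
            init = state  # warm start the next grid point
            if not ok:
                msg = (f"hglasso ADMM did not converge at {pt} "
                       f"(primal residual {r:.3g}); model dropped")
                warnings.warn(msg)
                failures[k] = msg
                continue
            logger.debug("hglasso model %d %s converged in %d iterations",
                         k, pt, n_iter)
            surrogate = V + V.T + Z
            adj = np.abs(surrogate) > self.zero_tolerance
            np.fill_diagonal(adj, False)
            graphs.append(adj)
            kept.append(k)
            fits.append(HglassoFit(
                theta=Theta, v=V, z=Z, lambdas=dict(pt), n_iter=n_iter,
                converged=ok, primal_residual=float(r),
                dual_residual=float(s)))
        self.working_matrix_ = S
        self.grid_ = grid
        self.fits_ = fits
        self.path_ = AdjacencyPath(grid, graphs, "hglasso",
                                   self.zero_tolerance, kept_indices=kept,
                                   failures=failures)
        return self


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def correlation_threshold_path(correlations, grid=None, thresholds=None,
                               n_thresholds=50):
    """Threshold a correlation matrix over a λ grid; see the class docs."""
    if grid is not None:
        thresholds = grid.values
    est = CorrelationThresholdPath(thresholds=thresholds,
                                   n_thresholds=n_thresholds,
                                   precomputed=True)
    return est.fit(correlations).path_


def glasso_path(S, grid=None, zero_tolerance=1e-6, **kwargs):
    """Graphical-lasso path from a covariance/correlation matrix."""
    lambdas = grid.values if grid is not None else None
    est = GraphicalLassoPath(lambdas=lambdas, zero_tolerance=zero_tolerance,
                             precomputed=True, **kwargs)
    return est.fit(S).path_


def hglasso_fit(S, lambda1, lambda2, lambda3, **kwargs):
    """Single hub-graphical-lasso solve from a matrix S."""
    est = HubGraphicalLasso(lambda1, lambda2, lambda3, precomputed=True,
                            **kwargs)
    return est.fit(S).fit_


def hglasso_path(S, lambda1_values, lambda2_values, lambda3_values,
                 zero_tolerance=1e-6, **kwargs):
    """Hub-graphical-lasso path from a matrix S over the product grid."""
    est = HubGraphicalLassoPath(lambda1_values, lambda2_values,
                                lambda3_values,
                                zero_tolerance=zero_tolerance,
                                precomputed=True, **kwargs)
    return est.fit(S).path_
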