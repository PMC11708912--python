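"""Ground-truth network simulators for hub-recovery benchmarks.

Five graph topologies commonly used to benchmark hub detection in gene
co-expression analysis: star graphs, super-hub networks, two-component
super-hub networks, Barabási–Albert scale-free graphs, and modular networks
with an intermodular bottleneck node.  Each generator returns a
:class:`GroundTruthNetwork` holding the binary adjacency, a positive-definite
precision matrix whose off-diagonal support equals the adjacency, and the set
of designated true hubs.  Gaussian expression data are drawn from
``N(0, Σ)`` with ``Σ`` the correlation matrix obtained by inverting the
precision matrix and rescaling to unit variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthNetwork",
    "make_star_network",
    "make_hub_network",
    "make_two_component_hub_network",
    "make_scale_free_network",
    "make_inter_hub_network",
    "make_network",
    "precision_from_adjacency",
    "sample_gaussian",
]

NETWORK_MODELS = ("star", "hub", "two_hub", "scale_free", "inter_hub")


@dataclass
class GroundTruthNetwork:
    """A simulated network with known hubs.

    Attributes
    ----------
    adjacency : ndarray of shape (p, p)
        Symmetric binary edge indicator with zero diagonal.
    precision : ndarray of shape (p, p)
        Symmetric positive-definite matrix whose off-diagonal support
        equals ``adjacency``; edges of the Gaussian graphical model are
        exactly its nonzero off-diagonal entries.
    hub_ids : frozenset of int
        1-based indices of the designated true hub nodes.
    model_name : str
        One of ``star``, ``hub``, ``two_hub``, ``scale_free``, ``inter_hub``.
    """

    adjacency: np.ndarray
    precision: np.ndarray
    hub_ids: frozenset
    model_name: str
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def covariance(self) -> np.ndarray:
        """Correlation-scaled covariance Σ = cov2cor(Θ⁻¹)."""
        sigma = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(sigma))
        return sigma / np.outer(d, d)

    def to_dict(self) -> dict:
        """JSON-ready summary: model, p, 1-based hub ids and edge list."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return {
            "model": self.model_name,
            "p": int(self.p),
            "hub_ids": sorted(int(h) for h in self.hub_ids),
            "edges": [[int(a) + 1, int(b) + 1] for a, b in zip(i, j)],
        }


def _validate_counts(p: int, n_hubs: int) -> None:
    if p < 2:
        raise ValueError(f"need at least 2 nodes, got p={p}")
    if n_hubs < 1:
        raise ValueError(f"need at least one hub, got n_hubs={n_hubs}")


def _finalize(adjacency, hubs_0based, model_name, edge_value, conditioning,
              rng, random_sign=False, meta=None):
    precision = precision_from_adjacency(
        adjacency, edge_value=edge_value, conditioning=conditioning,
        random_sign=random_sign, rng=rng,
    )
    return GroundTruthNetwork(
        adjacency=adjacency,
        precision=precision,
        hub_ids=frozenset(int(h) + 1 for h in hubs_0based),
        model_name=model_name,
        meta=meta or {},
    )


def make_star_network(p, n_hubs=5, *, edge_value=0.3, conditioning=0.1,
                      random_sign=False, seed=None):
    """Union of ``n_hubs`` disjoint star components covering ``p`` nodes.

    Nodes are partitioned into ``n_hubs`` consecutive components of (near)
    equal size; within each component the first node is the center,
    connected to every other node of the component, and there are no other
    edges.  Remainder nodes when ``n_hubs`` does not divide ``p`` go to the
    last component.  Hubs are the centers.
    """
    _validate_counts(p, n_hubs)
    if p < 2 * n_hubs:
        raise ValueError(
            f"p={p} too small for {n_hubs} star components of size >= 2"
        )
    rng = np.random.default_rng(seed)
    size = p // n_hubs
    adjacency = np.zeros((p, p), dtype=np.int8)
    hubs = []
    for k in range(n_hubs):
        lo = k * size
        hi = (lo + size) if k < n_hubs - 1 else p
        hubs.append(lo)
        adjacency[lo, lo + 1:hi] = 1
        adjacency[lo + 1:hi, lo] = 1
    return _finalize(adjacency, hubs, "star", edge_value, conditioning, rng,
                     random_sign)


def make_hub_network(p, n_hubs=2, *, hub_connect_prob=0.7,
                     background_density=0.02, edge_value=0.3,
                     conditioning=0.1, random_sign=False, seed=None):
    """Super-hub network: a few nodes each wired to most other nodes.

    ``n_hubs`` randomly chosen hubs connect independently to each remaining
    node with probability ``hub_connect_prob``; every non-hub pair is
    connected with probability ``background_density``.
    """
    _validate_counts(p, n_hubs)
    if n_hubs >= p:
        raise ValueError(f"n_hubs={n_hubs} must be smaller than p={p}")
    rng = np.random.default_rng(seed)
    hubs = rng.choice(p, size=n_hubs, replace=False)
    hub_set = set(int(h) for h in hubs)
    adjacency = np.zeros((p, p), dtype=np.int8)
    non_hubs = np.array([i for i in range(p) if i not in hub_set])
    # background edges among non-hubs
    if background_density > 0 and len(non_hubs) >= 2:
        iu, ju = np.triu_indices(len(non_hubs), k=1)
        on = rng.random(len(iu)) < background_density
        a, b = non_hubs[iu[on]], non_hubs[ju[on]]
        adjacency[a, b] = 1
        adjacency[b, a] = 1
    for h in hubs:
        others = np.array([i for i in range(p) if i != h])
        on = rng.random(len(others)) < hub_connect_prob
        adjacency[h, others[on]] = 1
        adjacency[others[on], h] = 1
    return _finalize(adjacency, hubs, "hub", edge_value, conditioning, rng,
                     random_sign)


def make_two_component_hub_network(p, n_hubs_per_component=1, *,
                                   hub_connect_prob=0.7,
                                   background_density=0.02, edge_value=0.3,
                                   conditioning=0.1, random_sign=False,
                                   seed=None):
    """Block-diagonal union of two independent super-hub networks.

    The node set splits into halves (sizes ``ceil(p/2)`` and ``floor(p/2)``);
    no edges cross between the blocks, so hubs of either block never reach
    the other.
    """
    rng = np.random.default_rng(seed)
    sizes = [(p + 1) // 2, p // 2]
    seeds = rng.integers(0, 2**31 - 1, size=2)
    blocks = [
        make_hub_network(sz, n_hubs_per_component,
                         hub_connect_prob=hub_connect_prob,
                         background_density=background_density,
                         edge_value=edge_value, conditioning=conditioning,
                         random_sign=random_sign, seed=int(s))
        for sz, s in zip(sizes, seeds)
    ]
    adjacency = np.zeros((p, p), dtype=np.int8)
    hubs = []
    off = 0
    for blk in blocks:
        q = blk.p
        adjacency[off:off + q, off:off + q] = blk.adjacency
        hubs.extend(h - 1 + off for h in blk.hub_ids)
        off += q
    return _finalize(adjacency, hubs, "two_hub", edge_value, conditioning,
                     rng, random_sign)


def make_scale_free_network(p, edges_per_step=1, *, hub_degree_factor=3.0,
                            edge_value=0.3, conditioning=0.1,
                            random_sign=False, seed=None):
    """Barabási–Albert preferential-attachment graph.

    Scale-free networks have no sharply separated hubs; nodes whose degree
    exceeds ``hub_degree_factor`` times the mean degree are designated true
    hubs for scoring purposes.
    """
    if p < 2:
        raise ValueError(f"need at least 2 nodes, got p={p}")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(p, edges_per_step,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    adjacency = nx.to_numpy_array(g, nodelist=range(p), dtype=np.int8)
    deg = adjacency.sum(axis=1)
    hubs = np.where(deg > hub_degree_factor * deg.mean())[0]
    return _finalize(adjacency, hubs, "scale_free", edge_value, conditioning,
                     rng, random_sign,
                     meta={"hub_degree_factor": hub_degree_factor})


def make_inter_hub_network(p, n_modules=2, *, edge_value=0.3,
                           conditioning=0.1, random_sign=False, seed=None):
    """Star modules joined through a low-degree bottleneck node.

    ``n_modules`` star modules each contribute an intramodular hub; one extra
    node connects only to the module hubs.  Its degree equals ``n_modules``
    (far below the module hubs), but removing it disconnects the modules —
    a bottleneck with high betweenness and low degree.  Hubs are the module
    centers plus the bottleneck.
    """
    if n_modules < 2:
        raise ValueError(f"need at least 2 modules, got n_modules={n_modules}")
    if p < 2 * n_modules + 1:
        raise ValueError(
            f"p={p} too small for {n_modules} modules plus a bottleneck"
        )
    rng = np.random.default_rng(seed)
    star = make_star_network(p - 1, n_modules, edge_value=edge_value,
                             conditioning=conditioning, seed=seed)
    adjacency = np.zeros((p, p), dtype=np.int8)
    adjacency[:p - 1, :p - 1] = star.adjacency
    bottleneck = p - 1
    module_hubs = [h - 1 for h in star.hub_ids]
    for h in module_hubs:
        adjacency[bottleneck, h] = 1
        adjacency[h, bottleneck] = 1
    hubs = module_hubs + [bottleneck]
    return _finalize(adjacency, hubs, "inter_hub", edge_value, conditioning,
                     rng, random_sign)


_MAKERS = {
    "star": make_star_network,
    "hub": make_hub_network,
    "two_hub": make_two_component_hub_network,
    "scale_free": make_scale_free_network,
    "inter_hub": make_inter_hub_network,
}


def make_network(model_name, p, **kwargs):
    """Dispatch to one of the five generators by model name."""
    try:
        maker = _MAKERS[model_name]
    except KeyError:
        raise ValueError(
            f"unknown model {model_name!r}; choose from {NETWORK_MODELS}"
        ) from None
    return maker(p, **kwargs)


def precision_from_adjacency(adjacency, *, edge_value=0.3, conditioning=0.1,
                             random_sign=False, rng=None):
    """Build a positive-definite precision matrix supported on an adjacency.

    Off-diagonal entries are ``edge_value * adjacency`` (optionally with
    independent random signs); the diagonal is set to
    ``|λ_min| + 0.1 + conditioning`` so the smallest eigenvalue is at least
    ``conditioning``, matching the convention of the standard R simulation
    utilities for Gaussian graphical models.
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency must have zero diagonal")
    theta = edge_value * adjacency.astype(float)
    if random_sign:
        rng = np.random.default_rng(rng)
        signs = np.where(rng.random(adjacency.shape) < 0.5, -1.0, 1.0)
        signs = np.triu(signs, 1)
        signs = signs + signs.T
        theta *= signs
    lam_min = np.linalg.eigvalsh(theta)[0] if adjacency.any() else 0.0
    np.fill_diagonal(theta, abs(lam_min) + 0.1 + conditioning)
    return theta


def sample_gaussian(truth, n, seed=None, gene_prefix="G", sample_prefix="S"):
    """Draw ``n`` i.i.d. observations from ``N(0, Σ)``, Σ = cov2cor(Θ⁻¹).

    Returns a samples × genes :class:`pandas.DataFrame` with gene identifiers
    as columns.  Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got n={n}")
    sigma = truth.covariance()
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, truth.p)) @ chol.T
    genes = [f"{gene_prefix}{i}" for i in range(1, truth.p + 1)]
    samples = [f"{sample_prefix}{i}" for i in range(1, n + 1)]
    return pd.DataFrame(values, index=samples, columns=genes)
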