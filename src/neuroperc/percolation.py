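"""Functional-graph sampling and directed-graph percolation theory.

A functional graph is one Bernoulli realization of the coactivation
probabilities: every static edge is kept independently with probability
P_ij.  Its joint in/out-degree distribution P(u, v) is the sole input to
the theory.  With the probability generating function

    G(x, y) = Σ_{u,v} P(u, v) x^u y^v,

the probabilities that a random edge leads to / comes from the giant
strongly connected component (GSCC) solve the self-consistent equations

    P_in  = 1 − (1/⟨k⟩) ∂G/∂x |_(1, 1−P_in),
    P_out = 1 − (1/⟨k⟩) ∂G/∂y |_(1−P_out, 1),

the probability that a neuron belongs to the GSCC is

    φ = 1 − G(1−P̂_out, 1) − G(1, 1−P̂_in) + G(1−P̂_out, 1−P̂_in),

and the site-dilution percolation threshold is ρ_c = ⟨k⟩ / ⟨uv⟩.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse, stats
from scipy.sparse import csgraph

from neuroperc.coactivation import CoactivationGraph
from neuroperc.connectome import Connectome


class PercolationSolverError(RuntimeError):
    """Fixed-point iteration failed to converge."""


@dataclass
class FunctionalGraph:
    """One realization of dynamic connectivity; always a subgraph of the
    static edge set."""

    edges: set[tuple[int, int]]
    parent: Connectome | None
    lam: float
    replicate_index: int

    def node_list(self) -> list[int]:
        if self.parent is not None:
            return [int(i) for i in self.parent.neuron_ids()]
        seen = {v for e in self.edges for v in e}
        return sorted(seen)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_list())
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ClusterStats:
    count: int
    mean_size: float
    second_moment_size: float
    mode: str  # "WCC" or "SCC"


@dataclass
class JointDegreeDistribution:
    """Empirical P(u, v) with the moments the theory needs.

    Graph-derived distributions carry the integer node tallies so the
    degree moments are exact (integer dot products, one final division);
    then the u- and v-marginal means coincide bit-for-bit (handshake
    identity)."""

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    counts: np.ndarray | None = None   # integer node tallies, optional
    n_nodes: int | None = None

    def __post_init__(self) -> None:
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if (self.p < 0).any():
            raise ValueError("probabilities must be non-negative")

    def _moment(self, weights: np.ndarray) -> float:
        if self.counts is not None and self.n_nodes:
            return float(np.dot(self.counts, weights)) / self.n_nodes
        return float((self.p * weights).sum())

    @property
    def mean_degree(self) -> float:
        """⟨k⟩ from the in-degree marginal."""
        return self._moment(self.u)

    @property
    def mean_degree_out(self) -> float:
        return self._moment(self.v)

    @property
    def uv_moment(self) -> float:
        return self._moment(self.u * self.v)

    def pmf(self) -> dict[tuple[int, int], float]:
        return {
            (int(a), int(b)): float(q) for a, b, q in zip(self.u, self.v, self.p)
        }

    def G(self, x: float, y: float) -> float:
        return float((self.p * x**self.u * y**self.v).sum())


@dataclass
class PercolationSolution:
    p_in_hat: float
    p_out_hat: float
    nontrivial: bool
    phi: float
    residuals: tuple[float, float]  # final |W_in|, |W_out|


@dataclass(frozen=True)
class DilutionResult:
    rho_c: float
    meaningful: bool
    tolerable_attack: float  # 1 - rho_c when meaningful, else nan


# ---------------------------------------------------------------------------
# Sampling and experimental statistics
# ---------------------------------------------------------------------------

def sample_functional_graph(
    cg: CoactivationGraph,
    seed: int,
    replicate: int,
    parent: Connectome | None = None,
) -> FunctionalGraph:
    """Keep each static edge independently with probability P_ij; one
    Bernoulli draw per edge, deterministic per (seed, replicate)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, replicate)))
    items = sorted(cg.probabilities.items())
    if items:
        probs = np.array([p for _, p in items])
        keep = rng.random(len(items)) < probs
        edges = {e for (e, _), k in zip(items, keep) if k}
    else:
        edges = set()
    return FunctionalGraph(
        edges=edges, parent=parent, lam=cg.lam, replicate_index=replicate
    )


def binomial_mode(p: float, xi: int = 100) -> tuple[int, float]:
    """Mode of Binomial(xi, p) (smallest index on ties) and its mass."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    k = np.arange(xi + 1)
    mass = stats.binom.pmf(k, xi, p)
    xi_hat = int(np.argmax(mass))  # argmax returns the first (smallest) index
    return xi_hat, float(mass[xi_hat])


def _adjacency(g: nx.DiGraph) -> tuple[sparse.csr_matrix, list]:
    nodes = list(g.nodes())
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", weight=None)
    return a, nodes


def component_stats(g: nx.DiGraph, mode: str) -> ClusterStats:
    """Cluster count and first/second size moments (singletons included).

    ``mode`` is ``"WCC"`` (direction ignored) or ``"SCC"`` (mutual
    reachability)."""
    if g.number_of_nodes() == 0:
        raise ValueError("node set must be non-empty")
    if mode not in ("WCC", "SCC"):
        raise ValueError("mode must be 'WCC' or 'SCC'")
    a, _ = _adjacency(g)
    n_comp, labels = csgraph.connected_components(
        a, directed=True, connection="weak" if mode == "WCC" else "strong"
    )
    sizes = np.bincount(labels).astype(float)
    return ClusterStats(
        count=int(n_comp),
        mean_size=float(sizes.mean()),
        second_moment_size=float((sizes**2).mean()),
        mode=mode,
    )


def gscc_summary(g: nx.DiGraph) -> tuple[int, float, float, float]:
    """(size, mean in-degree, mean out-degree, membership fraction) of the
    largest SCC; degrees are measured inside the induced subgraph and ties
    are broken toward the component containing the smallest node id."""
    if g.number_of_nodes() == 0:
        raise ValueError("node set must be non-empty")
    a, nodes = _adjacency(g)
    _, labels = csgraph.connected_components(a, directed=True, connection="strong")
    sizes = np.bincount(labels)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # smallest minimum node id wins (node order = insertion order)
        order = sorted(nodes)
        rank = {v: r for r, v in enumerate(order)}
        min_rank = [min(rank[nodes[i]] for i in np.flatnonzero(labels == b)) for b in best]
        winner = best[int(np.argmin(min_rank))]
    else:
        winner = best[0]
    members = [nodes[i] for i in np.flatnonzero(labels == winner)]
    sub = g.subgraph(members)
    size = len(members)
    mean_deg = sub.number_of_edges() / size
    return size, float(mean_deg), float(mean_deg), size / g.number_of_nodes()


def empirical_joint_degree(g: nx.DiGraph) -> JointDegreeDistribution:
    """Exact tallies of (in-degree, out-degree) pairs over all nodes."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("node set must be non-empty")
    tally: dict[tuple[int, int], int] = {}
    out_deg = dict(g.out_degree())
    for node, u in g.in_degree():
        key = (int(u), int(out_deg[node]))
        tally[key] = tally.get(key, 0) + 1
    keys = sorted(tally)
    u = np.array([k[0] for k in keys], dtype=float)
    v = np.array([k[1] for k in keys], dtype=float)
    counts = np.array([tally[k] for k in keys], dtype=np.int64)
    return JointDegreeDistribution(
        u=u, v=v, p=counts / n, counts=counts, n_nodes=n
    )


# ---------------------------------------------------------------------------
# Theory
# ---------------------------------------------------------------------------

def _w_residuals(d: JointDegreeDistribution, p_in: float, p_out: float) -> tuple[float, float]:
    k = d.mean_degree
    w_in = 1.0 - p_in - (d.p * d.u * (1.0 - p_in) ** d.v).sum() / k
    w_out = 1.0 - p_out - (d.p * d.v * (1.0 - p_out) ** d.u).sum() / k
    return float(w_in), float(w_out)


def solve_percolation(
    d: JointDegreeDistribution,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 1.0,
) -> PercolationSolution:
    """Solve the self-consistent edge-percolation equations.

    Fixed-point iteration started from 1 converges monotonically to the
    largest (physical) root; a root below 10·tol is declared trivial, in
    which case φ = 0.
    """
    k = d.mean_degree
    if k <= 0:
        raise ValueError("mean degree must be positive")
    pu, pv = d.p * d.u, d.p * d.v

    def f_in(x: float) -> float:
        return 1.0 - float((pu * (1.0 - x) ** d.v).sum()) / k

    def f_out(x: float) -> float:
        return 1.0 - float((pv * (1.0 - x) ** d.u).sum()) / k

    def iterate(f) -> float:
        x = 1.0
        for _ in range(max_iter):
            x_new = (1.0 - damping) * x + damping * f(x)
            if abs(x_new - x) < tol:
                return x_new
            x = x_new
        raise PercolationSolverError(
            f"no convergence in {max_iter} iterations (last x = {x:.3g})"
        )

    p_in = iterate(f_in)
    p_out = iterate(f_out)
    nontrivial = p_in > 10 * tol and p_out > 10 * tol
    if not nontrivial:
        p_in = p_out = 0.0
    sol = PercolationSolution(
        p_in_hat=p_in,
        p_out_hat=p_out,
        nontrivial=nontrivial,
        phi=0.0,
        residuals=tuple(abs(r) for r in _w_residuals(d, p_in, p_out)),
    )
    sol.phi = gscc_probability(sol, d)
    return sol


def gscc_probability(sol: PercolationSolution, d: JointDegreeDistribution) -> float:
    """φ by inclusion–exclusion over reaching / being reached by the GSCC."""
    if not sol.nontrivial:
        return 0.0
    phi = (
        1.0
        - d.G(1.0 - sol.p_out_hat, 1.0)
        - d.G(1.0, 1.0 - sol.p_in_hat)
        + d.G(1.0 - sol.p_out_hat, 1.0 - sol.p_in_hat)
    )
    return float(min(1.0, max(0.0, phi)))


def dilution_threshold(d: JointDegreeDistribution) -> DilutionResult:
    """Site-dilution threshold ρ_c = ⟨k⟩ / ⟨uv⟩ (may exceed 1, in which
    case no retention probability can sustain the GSCC)."""
    uv = d.uv_moment
    if uv <= 0:
        raise ValueError("uv moment is zero; threshold undefined")
    rho_c = d.mean_degree / uv
    meaningful = 0.0 <= rho_c <= 1.0
    return DilutionResult(
        rho_c=float(rho_c),
        meaningful=meaningful,
        tolerable_attack=float(1.0 - rho_c) if meaningful else float("nan"),
    )


def phi_upper_bound(c: Connectome) -> float:
    """φ of the full static adjacency graph: the ceiling no functional
    realization can exceed."""
    d = empirical_joint_degree(c.to_digraph())
    return solve_percolation(d).phi
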