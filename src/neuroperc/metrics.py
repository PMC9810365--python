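"""Efficiency, robustness and economy metrics for directed graphs.

Conventions follow the brain-connectivity-toolbox style on binary directed
graphs: shortest paths over all ordered pairs with unreachable pairs
assigned distance n + 1 (so the sample size never shrinks), Fagiolo's
directed clustering and transitivity, a rich-club curve on total degree
normalized by the directed maximum N(N−1), and physical Rentian scaling
log(e) = α log(n) + β over a cubic partition of the embedding volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse, stats
from scipy.sparse import csgraph

from neuroperc.percolation import component_stats


class InsufficientPartitionError(ValueError):
    """Too few usable cubes for a Rentian regression."""


@dataclass
class RentianFit:
    exponent: float      # Rentian alpha
    intercept: float     # beta
    r_squared: float
    rmse: float
    n_cubes_used: int
    m_cubes: int


@dataclass
class MetricReport:
    characteristic_path_length: float
    global_efficiency: float
    assortativity: float               # nan when undefined
    rich_club_curve: dict[int, float]
    rich_club_max: float
    mean_clustering: float
    transitivity: float
    scc_wcc_count_ratio: float
    scc_wcc_mean_size_ratio: float
    gscc_gwcc_size_ratio: float


def _binary_adjacency(g: nx.DiGraph) -> sparse.csr_matrix:
    return nx.to_scipy_sparse_array(g, nodelist=list(g.nodes()), format="csr", weight=None)


def path_metrics(g: nx.DiGraph) -> tuple[float, float]:
    """(characteristic path length, global efficiency) over ordered pairs,
    with unreachable pairs assigned distance n + 1."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    a = _binary_adjacency(g)
    dist = csgraph.shortest_path(a, method="D", directed=True, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    d[np.isinf(d)] = n + 1
    return float(d.mean()), float((1.0 / d).mean())


def assortativity(g: nx.DiGraph) -> float:
    """Pearson correlation, over edges, of the source out-degree against
    the target in-degree; nan when either sequence is constant."""
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges")
    out_deg = dict(g.out_degree())
    in_deg = dict(g.in_degree())
    x = np.array([out_deg[a] for a, _ in g.edges()], float)
    y = np.array([in_deg[b] for _, b in g.edges()], float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def rich_club_curve(g: nx.DiGraph) -> tuple[dict[int, float], float]:
    """φ(k) = E_{>k} / (N_{>k}(N_{>k}−1)) for k from 0 to max degree − 1,
    degrees (in + out) taken from the original graph; entries with fewer
    than two surviving nodes are omitted."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph must be non-empty")
    nodes = list(g.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    deg = np.array([g.in_degree(v) + g.out_degree(v) for v in nodes])
    if g.number_of_edges():
        src = np.array([idx[a] for a, _ in g.edges()])
        dst = np.array([idx[b] for _, b in g.edges()])
    else:
        src = dst = np.array([], dtype=int)
    curve: dict[int, float] = {}
    for k in range(int(deg.max()) if len(deg) else 0):
        survive = deg > k
        n_k = int(survive.sum())
        if n_k < 2:
            continue
        e_k = int((survive[src] & survive[dst]).sum())
        curve[k] = e_k / (n_k * (n_k - 1))
    max_val = max(curve.values()) if curve else float("nan")
    return curve, max_val


def clustering_metrics(g: nx.DiGraph) -> tuple[float, float]:
    """Directed binary clustering (mean over nodes with a defined
    denominator) and global transitivity, both in Fagiolo's convention:
    triangles counted over all edge-direction combinations via
    diag((A+Aᵀ)³)/2 and normalized by d_tot(d_tot−1) − 2 d_bidirectional."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("graph must be non-empty")
    if g.number_of_edges() == 0:
        return 0.0, 0.0
    a = _binary_adjacency(g).astype(np.int64)
    s = a + a.T
    s3 = (s @ s @ s).diagonal()
    tri = s3 / 2.0
    d_tot = np.asarray(a.sum(axis=0)).ravel() + np.asarray(a.sum(axis=1)).ravel()
    d_bi = (a.multiply(a.T)).sum(axis=1)
    d_bi = np.asarray(d_bi).ravel()
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    defined = denom > 0
    mean_clust = float((tri[defined] / denom[defined]).mean()) if defined.any() else 0.0
    denom_sum = float(denom.sum())
    transitivity = float(tri.sum() / denom_sum) if denom_sum > 0 else 0.0
    return mean_clust, transitivity


def rentian_fit(
    g: nx.DiGraph,
    coords: dict | np.ndarray,
    m_cubes: int = 300,
    min_occupied: int = 10,
    n_offsets: int = 1,
    seed: int = 0,
) -> RentianFit:
    """Physical Rentian scaling of a spatially embedded graph.

    The bounding box is tiled by axis-aligned cubes of side
    (V_bbox / m_cubes)^(1/3), anchored at the box corner; with
    ``n_offsets`` > 1, additional randomly shifted grids contribute extra
    (n, e) samples (useful when a single anchored grid gives every cube an
    identical occupancy, as on a uniform lattice).  For each cube, n is the
    number of nodes inside (half-open intervals) and e the number of edges
    with exactly one endpoint inside; cubes with n ≥ 1 and e ≥ 1 enter the
    least-squares fit of log e on log n.
    """
    nodes = list(g.nodes())
    if isinstance(coords, dict):
        pos = np.array([coords[v] for v in nodes], float)
    else:
        pos = np.asarray(coords, float)
    if pos.shape != (len(nodes), 3):
        raise ValueError("coords must provide a 3-vector per node")
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    if np.any(hi - lo <= 0):
        raise InsufficientPartitionError("degenerate bounding box")
    side = float(np.prod(hi - lo) / m_cubes) ** (1.0 / 3.0)
    idx = {v: i for i, v in enumerate(nodes)}
    if g.number_of_edges():
        src = np.array([idx[a] for a, _ in g.edges()])
        dst = np.array([idx[b] for _, b in g.edges()])
    else:
        src = dst = np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    log_n: list[float] = []
    log_e: list[float] = []
    for off in range(n_offsets):
        origin = lo if off == 0 else lo - rng.uniform(0.0, side, size=3)
        cell = np.floor((pos - origin) / side).astype(np.int64)
        # pack the 3-D cell index into one id
        span = cell.max(axis=0) + 1
        flat = (cell[:, 0] * span[1] + cell[:, 1]) * span[2] + cell[:, 2]
        for cube in np.unique(flat):
            inside = flat == cube
            n_in = int(inside.sum())
            e_cross = int((inside[src] ^ inside[dst]).sum()) if len(src) else 0
            if n_in >= 1 and e_cross >= 1:
                log_n.append(np.log(n_in))
                log_e.append(np.log(e_cross))
    if len(log_n) < min_occupied:
        raise InsufficientPartitionError(
            f"only {len(log_n)} usable cubes (< {min_occupied})"
        )
    x = np.array(log_n)
    y = np.array(log_e)
    if np.ptp(x) == 0:
        raise InsufficientPartitionError("no occupancy variation across cubes")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return RentianFit(
        exponent=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_cubes_used=len(x),
        m_cubes=m_cubes,
    )


def component_ratios(g: nx.DiGraph) -> tuple[float, float, float]:
    """(SCC/WCC count ratio, SCC/WCC mean-size ratio, GSCC/GWCC size
    ratio)."""
    scc = component_stats(g, "SCC")
    wcc = component_stats(g, "WCC")
    a = _binary_adjacency(g)
    _, lab_s = csgraph.connected_components(a, directed=True, connection="strong")
    _, lab_w = csgraph.connected_components(a, directed=True, connection="weak")
    gscc = int(np.bincount(lab_s).max())
    gwcc = int(np.bincount(lab_w).max())
    return (
        scc.count / wcc.count,
        scc.mean_size / wcc.mean_size,
        gscc / gwcc,
    )


def metric_report(g: nx.DiGraph, coords=None, m_cubes: int = 300) -> MetricReport:
    """Assemble the full suite on one graph (Rentian fit reported
    separately because it needs coordinates)."""
    cpl, eff = path_metrics(g)
    try:
        assort = assortativity(g)
    except ValueError:
        assort = float("nan")
    curve, curve_max = rich_club_curve(g)
    clust, trans = clustering_metrics(g)
    r_count, r_size, r_giant = component_ratios(g)
    return MetricReport(
        characteristic_path_length=cpl,
        global_efficiency=eff,
        assortativity=assort,
        rich_club_curve=curve,
        rich_club_max=curve_max,
        mean_clustering=clust,
        transitivity=trans,
        scc_wcc_count_ratio=r_count,
        scc_wcc_mean_size_ratio=r_size,
        gscc_gwcc_size_ratio=r_giant,
    )
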