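"""Synthetic connectomes, configuration-model digraphs and fixture graphs.

Everything downstream of the loader is exercised against generated data
with the statistical structure the analysis assumes: heavy-tailed in/out
degrees with tunable exponent, strong in/out symmetry, integer synapse
multiplicities per edge and coordinates inside a bounded 3-D volume.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from neuroperc.connectome import Connectome, build_connectome


class GenerationError(RuntimeError):
    """The requested random structure could not be realized."""


# ---------------------------------------------------------------------------
# Degree models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoissonDegrees:
    """Poisson(c) in- and out-degrees."""

    c: float

    def ppf(self, q: np.ndarray) -> np.ndarray:
        return stats.poisson.ppf(np.clip(q, 0.0, 1.0 - 1e-12), self.c).astype(np.int64)

    @property
    def mean(self) -> float:
        return self.c


@dataclass(frozen=True)
class PowerLawDegrees:
    """Truncated Pareto degrees, density ∝ x^(−exponent) on [x_min, x_max]."""

    exponent: float
    x_min: float = 1.0
    x_max: float = 300.0

    def __post_init__(self) -> None:
        if self.exponent <= 1.0:
            raise ValueError("power-law exponent must exceed 1")
        if not 0 < self.x_min < self.x_max:
            raise ValueError("need 0 < x_min < x_max")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        a = 1.0 - self.exponent
        lo, hi = self.x_min**a, self.x_max**a
        x = ((1.0 - q) * lo + q * hi) ** (1.0 / a)
        return np.rint(x).astype(np.int64)

    @property
    def mean(self) -> float:
        a = self.exponent
        lo, hi = self.x_min, self.x_max
        if abs(a - 2.0) < 1e-12:
            return (a - 1) * lo ** (a - 1) * np.log(hi / lo)
        return (a - 1) / (2 - a) * (hi ** (2 - a) - lo ** (2 - a)) * lo ** (a - 1)


DegreeModel = PoissonDegrees | PowerLawDegrees


@dataclass(frozen=True)
class ConnectomeSpec:
    """Recipe for a synthetic connectome.

    Defaults emulate the fly central-brain wiring statistics at desk scale:
    heavy-tailed degrees (truncated Pareto 2.5 on [4, 300], mean total
    degree ≈ 21), strong in/out coupling (Gaussian-copula rank correlation
    0.95), shifted-geometric synapse multiplicities with mean 7.8 clefts
    per adjacency, and a ~2.5e5 nm cubic volume.
    """

    n_neurons: int = 2000
    n_regions: int = 8
    degree_model: DegreeModel = field(
        default_factory=lambda: PowerLawDegrees(2.5, 4.0, 300.0)
    )
    inout_symmetry: float = 0.95
    synapse_count_mean: float = 7.8
    volume_nm: tuple[float, float, float] = (2.5e5, 2.5e5, 2.5e5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.n_regions > self.n_neurons:
            raise ValueError("n_regions exceeds n_neurons")
        if not 0.0 <= self.inout_symmetry <= 1.0:
            raise ValueError("inout_symmetry must lie in [0, 1]")
        if self.synapse_count_mean < 1.0:
            raise ValueError("mean synapse count must be >= 1")
        if any(v <= 0 for v in self.volume_nm):
            raise ValueError("volume must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "ConnectomeSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dm = raw.pop("degree_model", None)
        if isinstance(dm, dict):
            kind = dm.pop("kind")
            raw["degree_model"] = (
                PoissonDegrees(**dm) if kind == "poisson" else PowerLawDegrees(**dm)
            )
        if "volume_nm" in raw:
            raw["volume_nm"] = tuple(raw["volume_nm"])
        return cls(**raw)


@dataclass(frozen=True)
class JointDegreeSpec:
    """Finite-support joint in/out degree distribution used as a sampling
    target for the configuration model."""

    support: tuple[tuple[int, int], ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")
        if len(self.support) != len(p):
            raise ValueError("support/probabilities length mismatch")

    @classmethod
    def independent_poisson(cls, c: float, truncate: int = 30) -> "JointDegreeSpec":
        """P(u, v) = Pois(u; c) Pois(v; c), truncated and renormalized."""
        k = np.arange(truncate + 1)
        pk = stats.poisson.pmf(k, c)
        pk /= pk.sum()
        support = tuple((int(u), int(v)) for u in k for v in k)
        probs = tuple(float(pk[u] * pk[v]) for u in k for v in k)
        return cls(support, probs)

    @classmethod
    def point_mass(cls, u: int, v: int) -> "JointDegreeSpec":
        return cls(((u, v),), (1.0,))


# ---------------------------------------------------------------------------
# Configuration-model digraphs
# ---------------------------------------------------------------------------

def _erased_stub_match(
    u: np.ndarray, v: np.ndarray, rng: np.random.Generator
) -> nx.DiGraph:
    """Random stub matching; multi-edges and self-loops are discarded
    (erased configuration model), so the result is a simple digraph."""
    n = len(u)
    in_stubs = np.repeat(np.arange(n), u)
    out_stubs = np.repeat(np.arange(n), v)
    rng.shuffle(in_stubs)
    pairs = set()
    for a, b in zip(out_stubs, in_stubs):
        if a != b:
            pairs.add((int(a), int(b)))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(pairs)
    return g


def _balance_stub_counts(
    u: np.ndarray,
    v: np.ndarray,
    sampler,
    rng: np.random.Generator,
    max_tries: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample individual (u, v) pairs until Σu = Σv (bounded retries)."""
    n = len(u)
    if max_tries is None:
        max_tries = 200 * n + 10_000
    diff = int(u.sum() - v.sum())
    tries = 0
    while diff != 0:
        if tries >= max_tries:
            raise GenerationError(
                "cannot balance in/out stubs; joint degree spec appears "
                "structurally infeasible (E[u] != E[v]?)"
            )
        i = int(rng.integers(n))
        nu, nv = sampler(rng)
        new_diff = diff - (int(u[i]) - int(v[i])) + (nu - nv)
        if abs(new_diff) <= abs(diff):
            u[i], v[i] = nu, nv
            diff = new_diff
        tries += 1
    return u, v


def make_configuration_digraph(
    spec: JointDegreeSpec, n: int, seed: int
) -> nx.DiGraph:
    """Sample an erased directed configuration-model graph with n nodes
    whose joint in/out-degree distribution targets ``spec``."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    support = np.asarray(spec.support, dtype=np.int64)
    probs = np.asarray(spec.probabilities, float)
    mean_u = float((support[:, 0] * probs).sum())
    mean_v = float((support[:, 1] * probs).sum())
    if abs(mean_u - mean_v) > 1e-9 * max(1.0, mean_u + mean_v):
        raise GenerationError(
            f"spec is stub-infeasible: E[u]={mean_u:g} != E[v]={mean_v:g}"
        )
    idx = rng.choice(len(support), size=n, p=probs)
    u = support[idx, 0].copy()
    v = support[idx, 1].copy()

    def sampler(r: np.random.Generator) -> tuple[int, int]:
        j = int(r.choice(len(support), p=probs))
        return int(support[j, 0]), int(support[j, 1])

    u, v = _balance_stub_counts(u, v, sampler, rng)
    return _erased_stub_match(u, v, rng)


# ---------------------------------------------------------------------------
# Synthetic connectomes
# ---------------------------------------------------------------------------

def _octant_regions(pos: np.ndarray, n_regions: int) -> np.ndarray:
    """Recursive median splits of space into ``n_regions`` blocks: the
    largest block is split along its widest axis until enough blocks."""
    blocks = [np.arange(len(pos))]
    while len(blocks) < n_regions:
        sizes = [len(b) for b in blocks]
        k = int(np.argmax(sizes))
        block = blocks.pop(k)
        span = pos[block].max(axis=0) - pos[block].min(axis=0)
        axis = int(np.argmax(span))
        order = block[np.argsort(pos[block, axis], kind="stable")]
        half = len(order) // 2
        blocks.insert(k, order[half:])
        blocks.insert(k, order[:half])
    labels = np.empty(len(pos), dtype=np.int64)
    for r, b in enumerate(blocks):
        labels[b] = r
    return labels


def _correlated_uniforms(
    n: int, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Comonotone-mixture pair of uniform ranks: with probability r the two
    ranks coincide, otherwise they are independent.  This transfers the
    symmetry knob directly onto the Pearson correlation of the degree pair
    regardless of how heavy the marginal tail is."""
    u1 = rng.random(n)
    u_ind = rng.random(n)
    same = rng.random(n) < r
    return u1, np.where(same, u1, u_ind)


def make_synthetic_connectome(spec: ConnectomeSpec) -> Connectome:
    """Generate a connectome per ``spec``: uniform positions, block regions,
    copula-coupled in/out degrees, erased stub matching, and shifted-
    geometric synapse multiplicities.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    vol = np.asarray(spec.volume_nm, float)
    # positions quantized to the 10-nm imaging resolution: exact integers,
    # so CSV round-trips are byte-identical
    pos = np.round(rng.uniform(0.0, 1.0, size=(n, 3)) * vol / 10.0) * 10.0
    regions = _octant_regions(pos, spec.n_regions)

    q_in, q_out = _correlated_uniforms(n, spec.inout_symmetry, rng)
    d_in = spec.degree_model.ppf(q_in)
    d_out = spec.degree_model.ppf(q_out)

    # repair the stub imbalance by unit increments on the deficient side
    diff = int(d_out.sum() - d_in.sum())
    if diff > 0:
        d_in[rng.integers(0, n, size=diff)] += 1
    elif diff < 0:
        d_out[rng.integers(0, n, size=-diff)] += 1

    g = _erased_stub_match(d_in, d_out, rng)
    edge_arr = np.array(sorted(g.edges()), dtype=np.int64).reshape(-1, 2)
    p_geom = 1.0 / spec.synapse_count_mean
    counts = rng.geometric(p_geom, size=len(edge_arr)) if len(edge_arr) else np.array([], int)

    nodes = pd.DataFrame(
        {
            "neuron_id": np.arange(n, dtype=np.int64),
            "region": regions,
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "z_nm": pos[:, 2],
        }
    )
    edges = pd.DataFrame(
        {
            "pre_id": edge_arr[:, 0],
            "post_id": edge_arr[:, 1],
            "synapse_count": counts.astype(np.int64),
        }
    )
    return build_connectome(nodes, edges)


# ---------------------------------------------------------------------------
# Known-answer fixture graphs
# ---------------------------------------------------------------------------

def make_fixture_graphs(k_grid: int = 6) -> dict[str, nx.DiGraph]:
    """Small digraphs with hand-checkable structure.

    - ``cycle5``: directed 5-cycle (one SCC of size 5)
    - ``two_triads``: two disjoint directed 3-cycles
    - ``star_out``: hub with 6 outgoing leaves (all SCCs singletons)
    - ``grid3d``: k×k×k lattice, bidirectional nearest-neighbor edges,
      integer coordinates stored as the ``pos`` node attribute
    """
    cycle5 = nx.DiGraph([(i, (i + 1) % 5) for i in range(5)])
    two_triads = nx.DiGraph(
        [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]
    )
    star_out = nx.DiGraph([(0, leaf) for leaf in range(1, 7)])

    grid3d = nx.DiGraph()
    k = k_grid
    for x in range(k):
        for y in range(k):
            for z in range(k):
                grid3d.add_node((x, y, z), pos=(x, y, z))
    for x in range(k):
        for y in range(k):
            for z in range(k):
                for dx, dy, dz in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    nx_, ny_, nz_ = x + dx, y + dy, z + dz
                    if nx_ < k and ny_ < k and nz_ < k:
                        grid3d.add_edge((x, y, z), (nx_, ny_, nz_))
                        grid3d.add_edge((nx_, ny_, nz_), (x, y, z))
    return {
        "cycle5": cycle5,
        "two_triads": two_triads,
        "star_out": star_out,
        "grid3d": grid3d,
    }
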