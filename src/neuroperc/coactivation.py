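"""Excitation/inhibition assignment and LIF coactivation probabilities.

The pipeline stage between anatomy and function.  Given a connectome and a
global excitation-inhibition balance λ (the fraction of excitatory synapses
among all synapses):

1. neuron identities X_i ∈ {0, 1} are searched greedily so that the
   achieved synapse-weighted excitatory fraction λ̂ matches λ;
2. each directed edge receives a static strength
   S_ij = (α_ij / ⟨α⟩) (X_i Y_ij + (1 − X_i) Z_ij) with Y ~ U(0, 1] and
   Z ~ U[−1, 0], so excitatory neurons excite and inhibitory ones inhibit,
   scaled by the edge's synapse multiplicity α_ij relative to the mean;
3. the coactivation probability P_ij is the fraction of m stimulation
   trials in which continuously driving neuron i (plus enough randomly
   chosen presynaptic neighbors to cover ≥ 20% of j's in-degree) makes
   neuron j cross the spiking threshold of a leaky integrate-and-fire
   membrane within a 50 ms horizon.

Integration is explicit Euler with a 1 ms step.  Impulses arriving within
one step are applied simultaneously against the same pre-impulse membrane
potential, ΔV_j = Σ_h S_hj (V_h(spike) − V_j); a driven (forced) neuron's
potential at its spike instant is the threshold V̂.  Endogenous spikes are
delivered at the next step; after a spike the membrane resets to rest.
There is no refractory period.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numba
import numpy as np
import pandas as pd
from scipy import sparse

from neuroperc.connectome import Connectome


@dataclass(frozen=True)
class LIFConfig:
    """Membrane and protocol parameters (mV, ms)."""

    v_rest: float = -70.0
    v_threshold: float = -50.0
    tau_m: float = 10.0
    horizon: float = 50.0
    dt: float = 1.0
    trials: int = 100
    drive_fraction: float = 0.2
    leak_reversal: float = -70.0

    def __post_init__(self) -> None:
        if self.v_rest >= self.v_threshold:
            raise ValueError("v_rest must lie below v_threshold")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if abs(self.horizon / self.dt - round(self.horizon / self.dt)) > 1e-9:
            raise ValueError("horizon must be a multiple of dt")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not 0.0 < self.drive_fraction <= 1.0:
            raise ValueError("drive_fraction must be in (0, 1]")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt)) + 1


@dataclass
class EIAssignment:
    labels: dict[int, int]          # neuron id -> X_i (1 = excitatory)
    lambda_target: float
    lambda_achieved: float
    iterations: int
    converged: bool


@dataclass
class SynapticStrengths:
    """Per-edge static strengths, aligned with the connectome edge table."""

    pre: np.ndarray
    post: np.ndarray
    alpha: np.ndarray
    excit_draws: np.ndarray         # Y_ij in (0, 1]
    inhib_draws: np.ndarray         # Z_ij in [-1, 0]
    strengths: np.ndarray           # S_ij
    normalizer: float               # <alpha> over all edges

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {
            (int(a), int(b)): float(s)
            for a, b, s in zip(self.pre, self.post, self.strengths)
        }


@dataclass
class CoactivationGraph:
    """P_ij per static edge, with the λ and LIF configuration that
    produced it."""

    probabilities: dict[tuple[int, int], float]
    lam: float
    config: LIFConfig
    seed: int | None = None

    def mean_probability(self) -> float:
        if not self.probabilities:
            return 0.0
        return float(np.mean(list(self.probabilities.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.probabilities.items())
        return pd.DataFrame(
            {
                "pre_id": [k[0] for k, _ in rows],
                "post_id": [k[1] for k, _ in rows],
                "p_coact": [p for _, p in rows],
            }
        )

    def write(self, csv_path: str, sidecar_path: str | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"lambda": self.lam, "seed": self.seed, "lif": asdict(self.config)},
                    fh,
                    indent=2,
                )


# ---------------------------------------------------------------------------
# E/I label assignment
# ---------------------------------------------------------------------------

def assign_ei_labels(
    c: Connectome,
    lam: float,
    seed: int,
    tol: float = 1e-3,
    max_iter: int | None = None,
) -> EIAssignment:
    """Greedy single-flip search for labels achieving λ̂ ≈ λ.

    λ̂ is the fraction of synapses whose presynaptic neuron is excitatory.
    Starting from a Bernoulli(λ) initialization, one random neuron is
    flipped per iteration and the flip is kept only when it strictly
    reduces |λ̂ − λ|; the search stops at |λ̂ − λ| ≤ tol or after
    ``max_iter`` attempted flips (non-convergence is flagged, the best
    assignment is still returned).
    """
    if c.n_edges < 1:
        raise ValueError("connectome has no edges")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly inside (0, 1)")
    ids = c.neuron_ids()
    n = len(ids)
    out_sc = np.zeros(n, dtype=np.int64)
    idx = pd.Series(np.arange(n), index=ids)
    np.add.at(
        out_sc,
        idx.loc[c.edges["pre_id"]].to_numpy(),
        c.edges["synapse_count"].to_numpy(),
    )
    total = float(out_sc.sum())
    if max_iter is None:
        max_iter = 500 * n

    rng = np.random.default_rng(seed)
    x = (rng.random(n) < lam).astype(np.int8)
    excit = float(out_sc[x == 1].sum())
    err = abs(excit / total - lam)
    it = 0
    while err > tol and it < max_iter:
        i = int(rng.integers(n))
        delta = out_sc[i] if x[i] == 0 else -out_sc[i]
        new_err = abs((excit + delta) / total - lam)
        if new_err < err:
            x[i] ^= 1
            excit += delta
            err = new_err
        it += 1
    achieved = excit / total
    return EIAssignment(
        labels={int(i): int(v) for i, v in zip(ids, x)},
        lambda_target=lam,
        lambda_achieved=float(achieved),
        iterations=it,
        converged=err <= tol,
    )


def draw_static_strengths(
    c: Connectome, a: EIAssignment, seed: int
) -> SynapticStrengths:
    """Draw Y/Z uniforms per edge and combine them into S_ij."""
    if c.n_edges == 0:
        raise ValueError("normalizer undefined: connectome has no edges")
    missing = set(c.neuron_ids()) - set(a.labels)
    if missing:
        raise ValueError(f"labels missing for {len(missing)} neurons")
    rng = np.random.default_rng(seed)
    pre = c.edges["pre_id"].to_numpy()
    post = c.edges["post_id"].to_numpy()
    alpha = c.edges["synapse_count"].to_numpy(float)
    m = len(alpha)
    y = 1.0 - rng.random(m)          # (0, 1]
    z = -rng.random(m)               # (-1, 0], U[-1, 0] a.e.
    x_pre = np.array([a.labels[int(p)] for p in pre], dtype=float)
    normalizer = float(alpha.mean())
    s = (alpha / normalizer) * (x_pre * y + (1.0 - x_pre) * z)
    return SynapticStrengths(
        pre=pre, post=post, alpha=alpha,
        excit_draws=y, inhib_draws=z, strengths=s, normalizer=normalizer,
    )


# ---------------------------------------------------------------------------
# Local LIF networks
# ---------------------------------------------------------------------------

class _LocalNetwork:
    """The simulated neighborhood of one target neuron: the target plus all
    of its presynaptic neighbors, with the strengths of every static edge
    internal to that node set."""

    def __init__(
        self,
        preds: list[int],
        target: int,
        out_adj: dict[int, list[tuple[int, float]]],
    ) -> None:
        self.target = target
        self.nodes = list(preds) + [target]
        self.index = {v: k for k, v in enumerate(self.nodes)}
        nl = len(self.nodes)
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for h in self.nodes:
            for q, s in out_adj.get(h, ()):
                qi = self.index.get(q)
                if qi is not None:
                    rows.append(self.index[h])
                    cols.append(qi)
                    vals.append(s)
        w = sparse.csr_array(
            (np.asarray(vals, float), (np.asarray(rows), np.asarray(cols))),
            shape=(nl, nl),
        )
        self.indptr = w.indptr.astype(np.int64)
        self.indices = w.indices.astype(np.int64)
        self.data = w.data.astype(np.float64)

    @property
    def n_local(self) -> int:
        return len(self.nodes)


@numba.njit(cache=True)
def _lif_kernel(  # pragma: no cover - exercised through _simulate_batch
    indptr: np.ndarray,
    indices: np.ndarray,
    data: np.ndarray,
    driven: np.ndarray,
    vr: float,
    vt: float,
    decay: float,
    leak_to: float,
    n_steps: int,
) -> np.ndarray:
    """Row-wise Euler integration of stimulation trials.

    Each row of ``driven`` is one trial's forced-neuron mask over the local
    node list (target last).  The local strengths are CSR (indptr, indices,
    data).  A row exits early once the target fires, or once a spikeless
    step proves that no free node can ever cross threshold: the quiet
    dynamics of a node are the fixed affine map v <- A v + B, which stays
    below max(v, v*) when 0 < A < 1, inside the band around the fixed
    point v* = B/(1-A) when -1 < A <= 0, runs off to -inf when A > 1 and
    v < v*, and drifts by B when A = 1.
    """
    b, nl = driven.shape
    jt = nl - 1
    fired = np.zeros(b, np.bool_)
    db = np.zeros(nl)
    v = np.zeros(nl)
    pa = np.zeros(nl)
    pb = np.zeros(nl)
    npa = np.zeros(nl)
    npb = np.zeros(nl)
    for r in range(b):
        for q in range(nl):
            db[q] = 0.0
            v[q] = vr
            pa[q] = 0.0
            pb[q] = 0.0
        for h in range(nl):
            if driven[r, h]:
                for p in range(indptr[h], indptr[h + 1]):
                    db[indices[p]] += data[p]
        fired_r = False
        for _ in range(n_steps):
            for q in range(nl):
                if driven[r, q]:
                    continue
                # leak stage, then all impulses against the same
                # pre-impulse potential (affine update)
                vq = v[q] * (1.0 - decay) + leak_to * decay
                v[q] = vq * (1.0 - db[q] - pb[q]) + (vt * db[q] + pa[q])
            for q in range(nl):
                npa[q] = 0.0
                npb[q] = 0.0
            spiked = False
            for q in range(nl):
                if not driven[r, q] and v[q] >= vt:
                    spiked = True
                    if q == jt:
                        fired_r = True
                    for p in range(indptr[q], indptr[q + 1]):
                        npa[indices[p]] += data[p] * v[q]
                        npb[indices[p]] += data[p]
            if fired_r:
                break
            if spiked:
                for q in range(nl):
                    if not driven[r, q] and v[q] >= vt:
                        v[q] = vr
                for q in range(nl):
                    pa[q] = npa[q]
                    pb[q] = npb[q]
            else:
                for q in range(nl):
                    pa[q] = 0.0
                    pb[q] = 0.0
                safe = True
                for q in range(nl):
                    if driven[r, q]:
                        continue
                    a_map = (1.0 - decay) * (1.0 - db[q])
                    b_map = (leak_to * decay) * (1.0 - db[q]) + vt * db[q]
                    if abs(a_map) < 1.0 - 1e-12:
                        vs = b_map / (1.0 - a_map)
                        if a_map > 0.0:
                            safe = max(v[q], vs) < vt
                        else:
                            safe = vs + abs(v[q] - vs) < vt
                    elif a_map > 1.0 + 1e-12:
                        vs = b_map / (1.0 - a_map)
                        safe = v[q] < vs
                    else:
                        safe = b_map <= 0.0
                    if not safe:
                        break
                if safe:
                    break
        fired[r] = fired_r
    return fired


def _simulate_batch(
    net: _LocalNetwork, driven: np.ndarray, cfg: LIFConfig
) -> np.ndarray:
    """Integrate a batch of trials on one local network.

    ``driven`` is a (batch, n_local) boolean matrix of forced neurons.
    Returns a boolean vector: did the target cross threshold in each trial.
    """
    return _lif_kernel(
        net.indptr,
        net.indices,
        net.data,
        np.ascontiguousarray(driven),
        cfg.v_rest,
        cfg.v_threshold,
        cfg.dt / cfg.tau_m,
        cfg.leak_reversal,
        cfg.n_steps,
    )


def run_lif_trial(
    c: Connectome,
    s: SynapticStrengths,
    target: int,
    driven: set[int] | frozenset[int],
    cfg: LIFConfig,
    seed: int = 0,
) -> int:
    """Reference single-trial simulation; returns 1 iff the target crossed
    the spiking threshold at any step.

    Plain scalar loops over the target's presynaptic neighborhood; the
    dynamics are deterministic given the driven set (``seed`` is accepted
    for interface symmetry).  Used as the readable specification of one
    trial; :func:`estimate_coactivation` runs the identical scheme
    vectorized.
    """
    if target in driven:
        raise ValueError("the target must respond, not be forced")
    if not driven:
        raise ValueError("driven set must be non-empty")
    preds = sorted(int(p) for p in c.edges.loc[c.edges["post_id"] == target, "pre_id"])
    if not set(driven) <= set(preds):
        raise ValueError("driven set must be presynaptic to the target")
    nodes = preds + [target]
    node_set = set(nodes)
    w = {
        (h, q): v
        for (h, q), v in s.as_dict().items()
        if h in node_set and q in node_set
    }
    vr, vt = cfg.v_rest, cfg.v_threshold
    decay = cfg.dt / cfg.tau_m
    # total forced-drive strength into each free node (constant over steps)
    db = {
        u: sum(w[(h, u)] for h in driven if (h, u) in w)
        for u in nodes
        if u not in driven
    }
    v = {u: vr for u in nodes}
    pend: dict[int, list[tuple[float, float]]] = {u: [] for u in nodes}
    fired = 0
    for _ in range(cfg.n_steps):
        for u in nodes:
            if u in driven:
                continue
            # leak stage, then all impulses applied against the same
            # pre-impulse potential (affine update)
            vu = v[u] * (1.0 - decay) + cfg.leak_reversal * decay
            pa = sum(s_hu * v_spike for s_hu, v_spike in pend[u])
            pb = sum(s_hu for s_hu, _ in pend[u])
            v[u] = vu * (1.0 - db[u] - pb) + (vt * db[u] + pa)
        for u in nodes:
            pend[u] = []
        spikers = [u for u in nodes if u not in driven and v[u] >= vt]
        for h in spikers:
            if h == target:
                fired = 1
            for q in nodes:
                if (h, q) in w:
                    pend[q].append((w[(h, q)], v[h]))
        for h in spikers:
            v[h] = vr
    return fired


# ---------------------------------------------------------------------------
# Coactivation estimation
# ---------------------------------------------------------------------------

def _driven_size(indegree: int, drive_fraction: float) -> int:
    return max(1, math.ceil(drive_fraction * indegree))


def _out_adjacency(s: SynapticStrengths) -> dict[int, list[tuple[int, float]]]:
    adj: dict[int, list[tuple[int, float]]] = {}
    for a, b, w in zip(s.pre, s.post, s.strengths):
        adj.setdefault(int(a), []).append((int(b), float(w)))
    return adj


def _edge_rng(seed: int, i: int, j: int) -> np.random.Generator:
    """Deterministic per-edge substream; trial t uses the t-th draw, so the
    whole-graph result is independent of edge evaluation order."""
    return np.random.default_rng(np.random.SeedSequence((seed, int(i), int(j))))


def _driven_masks(
    net: _LocalNetwork, i: int, cfg: LIFConfig, rng: np.random.Generator
) -> np.ndarray:
    """(trials, n_local) boolean driven matrix: {i} plus a fresh random
    subset of the other presynaptic neighbors per trial."""
    nl = net.n_local
    p = nl - 1                      # number of presynaptic neighbors
    k = _driven_size(p, cfg.drive_fraction)
    m = cfg.trials
    masks = np.zeros((m, nl), dtype=bool)
    i_idx = net.index[i]
    masks[:, i_idx] = True
    if k > 1:
        others = np.array([q for q in range(p) if q != i_idx])
        # random (k-1)-subset per row, without replacement
        order = np.argpartition(rng.random((m, len(others))), k - 2, axis=1)[:, : k - 1]
        sel = others[order]
        rows = np.repeat(np.arange(m), k - 1)
        masks[rows, sel.ravel()] = True
    return masks


def _estimate_on_network(
    net: _LocalNetwork, i: int, cfg: LIFConfig, rng: np.random.Generator
) -> float:
    return _estimate_many(net, [i], cfg, {i: rng})[i]


def _estimate_many(
    net: _LocalNetwork,
    sources: list[int],
    cfg: LIFConfig,
    rngs: dict[int, np.random.Generator],
) -> dict[int, float]:
    """P_ij for several in-edges of one target, sharing one local network.

    Trials from all sources are pooled, deduplicated by driven set, and
    simulated in bounded chunks; the result per edge is the mean indicator
    over its own trials."""
    m = cfg.trials
    stacks = [_driven_masks(net, i, cfg, rngs[i]) for i in sources]
    masks = np.concatenate(stacks, axis=0)
    uniq, inverse = np.unique(masks, axis=0, return_inverse=True)
    fired = _simulate_batch(net, uniq, cfg)[inverse]
    return {
        i: float(fired[k * m : (k + 1) * m].mean())
        for k, i in enumerate(sources)
    }


def estimate_coactivation(
    c: Connectome,
    s: SynapticStrengths,
    edge: tuple[int, int],
    cfg: LIFConfig,
    seed: int,
) -> float:
    """P_ij for one static edge: the fraction of ``cfg.trials`` stimulation
    trials in which the target fires."""
    i, j = int(edge[0]), int(edge[1])
    mask = (c.edges["pre_id"] == i) & (c.edges["post_id"] == j)
    if not mask.any():
        raise ValueError(f"({i}, {j}) is not a static edge")
    preds = sorted(int(p) for p in c.edges.loc[c.edges["post_id"] == j, "pre_id"])
    if not preds:
        raise ValueError(f"neuron {j} has no presynaptic neighbors; corrupted graph")
    net = _LocalNetwork(preds, j, _out_adjacency(s))
    return _estimate_on_network(net, i, cfg, _edge_rng(seed, i, j))


def coactivation_graph(
    c: Connectome,
    s: SynapticStrengths,
    cfg: LIFConfig,
    seed: int,
    lam: float | None = None,
) -> CoactivationGraph:
    """P_ij for every static edge.  Edges sharing a target reuse one local
    network; per-edge substreams make the result independent of evaluation
    order."""
    probs: dict[tuple[int, int], float] = {}
    if c.n_edges:
        adj = _out_adjacency(s)
        by_target = c.edges.groupby("post_id")
        for j, grp in by_target:
            preds = sorted(int(p) for p in grp["pre_id"])
            net = _LocalNetwork(preds, int(j), adj)
            rngs = {i: _edge_rng(seed, i, int(j)) for i in preds}
            for i, p in _estimate_many(net, preds, cfg, rngs).items():
                probs[(i, int(j))] = p
    return CoactivationGraph(
        probabilities=probs, lam=float("nan") if lam is None else lam,
        config=cfg, seed=seed,
    )
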