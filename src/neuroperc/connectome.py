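"""Data model and I/O for directed connectomes.

A connectome is a directed simple graph of neurons.  Each neuron carries a
region label and a 3-D position in nanometres; each ordered neuron pair may
carry at most one *directionally adjacent* (DA) edge, weighted by the number
of synaptic clefts (synaptic connections, SC) it bundles.

Tables are plain CSV: nodes ``neuron_id,region,x_nm,y_nm,z_nm`` and edges
``pre_id,post_id,synapse_count``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

NODE_COLUMNS = ["neuron_id", "region", "x_nm", "y_nm", "z_nm"]
EDGE_COLUMNS = ["pre_id", "post_id", "synapse_count"]


class ConnectomeFormatError(ValueError):
    """A table is missing required columns."""


class ConnectomeReferentialError(ValueError):
    """An edge references a neuron id absent from the node table."""


class ConnectomeValidationError(ValueError):
    """Row-level contents violate an invariant (e.g. synapse_count < 1)."""


@dataclass
class LoadReport:
    """What the loader cleaned up: merged duplicates and dropped autapses."""

    n_duplicate_rows_merged: int = 0
    n_self_loops_dropped: int = 0


@dataclass
class Connectome:
    """Directed simple graph of neurons with synapse-count edge weights.

    ``nodes`` is indexed-free with columns ``neuron_id, region, x_nm, y_nm,
    z_nm``; ``edges`` has ``pre_id, post_id, synapse_count`` with one row per
    ordered (pre, post) pair and ``pre_id != post_id``.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in NODE_COLUMNS:
            if col not in self.nodes.columns:
                raise ConnectomeFormatError(f"node table missing column {col!r}")
        for col in EDGE_COLUMNS:
            if col not in self.edges.columns:
                raise ConnectomeFormatError(f"edge table missing column {col!r}")
        ids = self.nodes["neuron_id"]
        if ids.duplicated().any():
            raise ConnectomeValidationError("duplicate neuron ids")
        pos = self.nodes[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        if not np.isfinite(pos).all() or (pos < 0).any():
            raise ConnectomeValidationError("positions must be finite and non-negative")
        if len(self.edges):
            if (self.edges["synapse_count"] < 1).any():
                raise ConnectomeValidationError("synapse_count must be >= 1")
            if (self.edges["pre_id"] == self.edges["post_id"]).any():
                raise ConnectomeValidationError("self-loop edge present")
            if self.edges.duplicated(subset=["pre_id", "post_id"]).any():
                raise ConnectomeValidationError("duplicate (pre, post) edge rows")
            known = set(ids)
            dangling = ~(
                self.edges["pre_id"].isin(known) & self.edges["post_id"].isin(known)
            )
            if dangling.any():
                bad = self.edges.loc[dangling].iloc[0]
                raise ConnectomeReferentialError(
                    f"edge {int(bad.pre_id)}->{int(bad.post_id)} references unknown neuron"
                )

    # -- basic accessors --------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_synapses(self) -> int:
        return int(self.edges["synapse_count"].sum()) if len(self.edges) else 0

    def neuron_ids(self) -> np.ndarray:
        return self.nodes["neuron_id"].to_numpy()

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions, row order matching ``nodes``."""
        return self.nodes[["x_nm", "y_nm", "z_nm"]].to_numpy(float)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(int(i) for i in self.nodes["neuron_id"])
        g.add_weighted_edges_from(
            self.edges[EDGE_COLUMNS].itertuples(index=False, name=None),
            weight="synapse_count",
        )
        return g


def _clean_edges(edges: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    report = LoadReport()
    edges = edges.copy()
    self_loops = edges["pre_id"] == edges["post_id"]
    report.n_self_loops_dropped = int(self_loops.sum())
    edges = edges.loc[~self_loops]
    n_before = len(edges)
    edges = (
        edges.groupby(["pre_id", "post_id"], as_index=False, sort=True)["synapse_count"]
        .sum()
    )
    report.n_duplicate_rows_merged = n_before - len(edges)
    return edges, report


def build_connectome(nodes: pd.DataFrame, edges: pd.DataFrame) -> Connectome:
    """Validate raw tables into a Connectome, merging duplicate edge rows
    and dropping autapse rows (counted in the load report)."""
    for col in NODE_COLUMNS:
        if col not in nodes.columns:
            raise ConnectomeFormatError(f"node table missing column {col!r}")
    for col in EDGE_COLUMNS:
        if col not in edges.columns:
            raise ConnectomeFormatError(f"edge table missing column {col!r}")
    if len(edges) and (edges["synapse_count"] < 1).any():
        raise ConnectomeValidationError("synapse_count must be >= 1")
    edges, report = _clean_edges(edges)
    nodes = nodes[NODE_COLUMNS].reset_index(drop=True)
    return Connectome(nodes=nodes, edges=edges, load_report=report)


def load_connectome(nodes_table: str, edges_table: str) -> Connectome:
    """Read node and edge CSVs and return a validated :class:`Connectome`."""
    nodes = pd.read_csv(nodes_table)
    edges = pd.read_csv(edges_table)
    return build_connectome(nodes, edges)


def write_connectome(c: Connectome, nodes_table: str, edges_table: str) -> None:
    """Write the node/edge tables in the canonical CSV dialect (sorted,
    comma-separated, header row) so repeated writes are byte-identical."""
    nodes = c.nodes.sort_values("neuron_id")
    edges = c.edges.sort_values(["pre_id", "post_id"])
    nodes.to_csv(nodes_table, index=False)
    edges.to_csv(edges_table, index=False)


# ---------------------------------------------------------------------------
# Descriptive variables
# ---------------------------------------------------------------------------

def neuron_degree_table(c: Connectome) -> pd.DataFrame:
    """Per-neuron synaptic and adjacency degrees.

    Columns: ISC/OSC/SC (in/out/total synapse counts), IDA/ODA/DA (in/out/
    total adjacency counts) and the per-neighbor multiset columns
    ``isc_per_ida`` / ``osc_per_oda`` / ``sc_per_da`` (lists of the synapse
    counts on each incident edge).  SC = ISC + OSC and DA = IDA + ODA hold
    per row by construction.
    """
    ids = c.neuron_ids()
    idx = pd.Series(np.arange(len(ids)), index=ids)
    isc = np.zeros(len(ids), dtype=np.int64)
    osc = np.zeros(len(ids), dtype=np.int64)
    ida = np.zeros(len(ids), dtype=np.int64)
    oda = np.zeros(len(ids), dtype=np.int64)
    in_lists: list[list[int]] = [[] for _ in ids]
    out_lists: list[list[int]] = [[] for _ in ids]
    if len(c.edges):
        pre = idx.loc[c.edges["pre_id"]].to_numpy()
        post = idx.loc[c.edges["post_id"]].to_numpy()
        w = c.edges["synapse_count"].to_numpy()
        np.add.at(isc, post, w)
        np.add.at(osc, pre, w)
        np.add.at(ida, post, 1)
        np.add.at(oda, pre, 1)
        for p, q, a in zip(pre, post, w):
            out_lists[p].append(int(a))
            in_lists[q].append(int(a))
    return pd.DataFrame(
        {
            "neuron_id": ids,
            "ISC": isc,
            "OSC": osc,
            "SC": isc + osc,
            "IDA": ida,
            "ODA": oda,
            "DA": ida + oda,
            "isc_per_ida": in_lists,
            "osc_per_oda": out_lists,
            "sc_per_da": [i + o for i, o in zip(in_lists, out_lists)],
        }
    )


def region_projection_table(
    c: Connectome, count_synapses: bool = True
) -> pd.DataFrame:
    """Macroscopic (brain-region) projection counts.

    An inter-region edge contributes its synapse count (or 1 adjacency when
    ``count_synapses`` is False) to the POP of its pre-region toward the
    post-region, and symmetrically to the post-region's PIP.  Intra-region
    edges are excluded.  TPIP/TPOP are the row sums (macroscopic in/out
    degree); globally Σ TPIP = Σ TPOP.

    Returns one row per region with columns ``region, TPIP, TPOP`` plus
    ``pip`` / ``pop`` dict columns keyed by partner region.
    """
    region_of = dict(zip(c.nodes["neuron_id"], c.nodes["region"]))
    regions = sorted(set(c.nodes["region"]), key=str)
    pip: dict[object, dict[object, int]] = {r: {} for r in regions}
    pop: dict[object, dict[object, int]] = {r: {} for r in regions}
    if len(c.edges):
        for pre, post, w in c.edges[EDGE_COLUMNS].itertuples(index=False, name=None):
            r_pre, r_post = region_of[pre], region_of[post]
            if r_pre == r_post:
                continue
            amount = int(w) if count_synapses else 1
            pop[r_pre][r_post] = pop[r_pre].get(r_post, 0) + amount
            pip[r_post][r_pre] = pip[r_post].get(r_pre, 0) + amount
    return pd.DataFrame(
        {
            "region": regions,
            "TPIP": [sum(pip[r].values()) for r in regions],
            "TPOP": [sum(pop[r].values()) for r in regions],
            "pip": [pip[r] for r in regions],
            "pop": [pop[r] for r in regions],
        }
    )
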