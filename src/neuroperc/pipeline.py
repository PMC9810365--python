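"""λ-sweep orchestration: coactivation → functional sampling → percolation
→ metrics, with deterministic seed plumbing and tidy CSV outputs.

For each λ on the grid, E/I labels and static strengths are drawn once and
a single coactivation graph is computed; the l replicates differ only in
the Bernoulli sampling of functional graphs.  Every number downstream is a
pure function of (connectome, config, master seed).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from neuroperc.coactivation import (
    LIFConfig,
    assign_ei_labels,
    coactivation_graph,
    draw_static_strengths,
)
from neuroperc.connectome import Connectome, load_connectome
from neuroperc.metrics import metric_report
from neuroperc.percolation import (
    dilution_threshold,
    empirical_joint_degree,
    gscc_summary,
    phi_upper_bound,
    sample_functional_graph,
    solve_percolation,
)

DEFAULT_GRID = tuple(round(0.05 * k, 2) for k in range(1, 20))  # 0.05 .. 0.95

ALL_STAGES = frozenset({"static", "coactivate", "percolate", "metrics"})


@dataclass
class SweepConfig:
    lambda_grid: tuple[float, ...] = DEFAULT_GRID
    replicates: int = 5
    master_seed: int = 0
    lif: LIFConfig = field(default_factory=LIFConfig)
    nodes_table: str | None = None
    edges_table: str | None = None
    out_dir: str | None = None
    stages: frozenset[str] = ALL_STAGES
    ei_tol: float = 1e-3
    rentian_m_cubes: int = 300

    def __post_init__(self) -> None:
        grid = tuple(self.lambda_grid)
        if any(not 0.0 < lam < 1.0 for lam in grid):
            raise ValueError("lambda values must lie in (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("lambda grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.lambda_grid = grid
        self.stages = frozenset(self.stages)
        if not self.stages <= ALL_STAGES:
            raise ValueError(f"unknown stages: {self.stages - ALL_STAGES}")


@dataclass
class SweepResult:
    rows: pd.DataFrame           # one row per (lambda, replicate)
    phi_static: float            # upper bound from static connectivity
    config: SweepConfig
    errors: list[dict] = field(default_factory=list)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.rows.to_csv(os.path.join(out_dir, "sweep.csv"), index=False)
        prov = {
            "phi_static": self.phi_static,
            "master_seed": self.config.master_seed,
            "lambda_grid": list(self.config.lambda_grid),
            "replicates": self.config.replicates,
            "lif": asdict(self.config.lif),
        }
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(prov, fh, indent=2)
        if self.errors:
            with open(os.path.join(out_dir, "errors.json"), "w") as fh:
                json.dump(self.errors, fh, indent=2)


@dataclass(frozen=True)
class TransitionReport:
    lambda_threshold: float | None     # last subcritical grid point
    lambda_saturation: float | None
    no_transition: bool


def _lambda_seeds(master_seed: int, li: int) -> tuple[int, int, int, int]:
    state = np.random.SeedSequence((master_seed, li)).generate_state(4)
    return tuple(int(x) for x in state)


def run_sweep(cfg: SweepConfig, connectome: Connectome | None = None) -> SweepResult:
    """Execute the full sweep; returns one row per (λ, replicate)."""
    if connectome is None:
        if cfg.nodes_table is None or cfg.edges_table is None:
            raise ValueError("pass a connectome or node/edge table paths")
        connectome = load_connectome(cfg.nodes_table, cfg.edges_table)
    c = connectome
    coords = c.positions()
    node_index = {int(v): k for k, v in enumerate(c.neuron_ids())}
    phi_static = phi_upper_bound(c) if "static" in cfg.stages else float("nan")

    records: list[dict] = []
    errors: list[dict] = []
    for li, lam in enumerate(cfg.lambda_grid):
        ei_seed, strength_seed, coact_seed, sample_seed = _lambda_seeds(
            cfg.master_seed, li
        )
        try:
            assignment = assign_ei_labels(c, lam, seed=ei_seed, tol=cfg.ei_tol)
            strengths = draw_static_strengths(c, assignment, seed=strength_seed)
            cg = coactivation_graph(c, strengths, cfg.lif, seed=coact_seed, lam=lam)
        except Exception as exc:  # noqa: BLE001 - manifest, then continue
            errors.append({"lambda": lam, "replicate": None, "stage": "coactivate",
                           "error": str(exc)})
            continue
        for rep in range(1, cfg.replicates + 1):
            row: dict = {
                "lambda": lam,
                "replicate": rep,
                "lambda_achieved": assignment.lambda_achieved,
                "mean_p_coact": cg.mean_probability(),
            }
            try:
                fg = sample_functional_graph(cg, seed=sample_seed, replicate=rep,
                                             parent=c)
                g = fg.to_digraph()
                row["n_functional_edges"] = len(fg.edges)
                if "percolate" in cfg.stages:
                    d = empirical_joint_degree(g)
                    sol = solve_percolation(d)
                    row.update(
                        p_in=sol.p_in_hat, p_out=sol.p_out_hat, phi=sol.phi,
                        phi_experimental=gscc_summary(g)[3],
                    )
                    if d.uv_moment > 0:
                        dil = dilution_threshold(d)
                        row.update(rho_c=dil.rho_c, meaningful=dil.meaningful,
                                   tolerable_attack=dil.tolerable_attack)
                    else:
                        row.update(rho_c=float("nan"), meaningful=False,
                                   tolerable_attack=float("nan"))
                if "metrics" in cfg.stages:
                    rep_metrics = metric_report(g)
                    row.update(
                        characteristic_path_length=rep_metrics.characteristic_path_length,
                        global_efficiency=rep_metrics.global_efficiency,
                        assortativity=rep_metrics.assortativity,
                        rich_club_max=rep_metrics.rich_club_max,
                        mean_clustering=rep_metrics.mean_clustering,
                        transitivity=rep_metrics.transitivity,
                        scc_wcc_count_ratio=rep_metrics.scc_wcc_count_ratio,
                        scc_wcc_mean_size_ratio=rep_metrics.scc_wcc_mean_size_ratio,
                        gscc_gwcc_size_ratio=rep_metrics.gscc_gwcc_size_ratio,
                    )
                    try:
                        from neuroperc.metrics import rentian_fit

                        pos = np.array(
                            [coords[node_index[v]] for v in g.nodes()]
                        )
                        rent = rentian_fit(g, pos, m_cubes=cfg.rentian_m_cubes)
                        row.update(rentian_exponent=rent.exponent,
                                   rentian_r2=rent.r_squared)
                    except Exception:
                        row.update(rentian_exponent=float("nan"),
                                   rentian_r2=float("nan"))
                records.append(row)
            except Exception as exc:  # noqa: BLE001
                errors.append({"lambda": lam, "replicate": rep,
                               "stage": "percolate/metrics", "error": str(exc)})
    rows = pd.DataFrame(records)
    result = SweepResult(rows=rows, phi_static=phi_static, config=cfg, errors=errors)
    if cfg.out_dir:
        result.write(cfg.out_dir)
    return result


def report_transition(
    res: SweepResult, saturation_fraction: float = 0.05
) -> TransitionReport:
    """Grid-resolution percolation threshold and saturation point.

    The threshold is the largest grid λ whose predicted φ is 0 in every
    replicate (the last subcritical point).  The saturation point is the
    smallest grid λ from which every backward increment of the per-λ mean
    φ stays below ``saturation_fraction`` of its final value.
    """
    if len(res.rows) == 0 or "phi" not in res.rows:
        raise ValueError("sweep has no percolation rows")
    grid = sorted(res.rows["lambda"].unique())
    if len(grid) < 4:
        raise ValueError("sweep must cover at least 4 grid points")
    by_lam = res.rows.groupby("lambda")["phi"]
    all_zero = by_lam.max() == 0.0
    mean_phi = by_lam.mean().reindex(grid).to_numpy()
    if mean_phi.max() == 0.0:
        return TransitionReport(None, None, no_transition=True)
    threshold = None
    for lam in grid:
        if all_zero.loc[lam]:
            threshold = float(lam)
        else:
            break
    final = mean_phi[-1]
    increments = np.diff(mean_phi)  # increment arriving at grid[i + 1]
    saturation = None
    for i in range(1, len(grid)):
        if np.all(increments[i - 1 :] < saturation_fraction * final):
            saturation = float(grid[i])
            break
    return TransitionReport(threshold, saturation, no_transition=False)
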