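"""E/I assignment, static strengths and LIF coactivation estimation."""

import numpy as np
import pytest

from neuroperc import (
    LIFConfig,
    assign_ei_labels,
    coactivation_graph,
    draw_static_strengths,
    estimate_coactivation,
    run_lif_trial,
)
from neuroperc.coactivation import (
    EIAssignment,
    _LocalNetwork,
    _driven_masks,
    _edge_rng,
    _out_adjacency,
    _simulate_batch,
)

from conftest import connectome_from_edges


def _assignment(c, labels):
    total = c.total_synapses
    excit = sum(
        int(w) for a, b, w in c.edges.itertuples(index=False) if labels[int(a)] == 1
    )
    return EIAssignment(
        labels=labels, lambda_target=0.5, lambda_achieved=excit / total,
        iterations=0, converged=True,
    )


def _forced_strengths(c, labels, magnitudes):
    """Strengths object with hand-set S values (bypassing random draws)."""
    s = draw_static_strengths(c, _assignment(c, labels), seed=0)
    for k, (pre, post) in enumerate(zip(s.pre, s.post)):
        s.strengths[k] = magnitudes[(int(pre), int(post))]
    return s


class TestEIAssignment:
    def test_two_neuron_balance_forced_by_counts(self):
        c = connectome_from_edges([(0, 1, 5), (1, 0, 5)])
        a = assign_ei_labels(c, 0.5, seed=0)
        assert a.lambda_achieved == pytest.approx(0.5)
        assert sorted(a.labels.values()) == [0, 1]

    def test_recount_oracle_on_synthetic(self, medium_synthetic):
        a = assign_ei_labels(medium_synthetic, 0.95, seed=1)
        labels = a.labels
        excit = sum(
            int(w)
            for pre, _, w in medium_synthetic.edges.itertuples(index=False)
            if labels[int(pre)] == 1
        )
        recount = excit / medium_synthetic.total_synapses
        assert recount == pytest.approx(a.lambda_achieved)
        assert abs(recount - 0.95) <= 1e-3

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.1])
    def test_degenerate_lambda_rejected(self, medium_synthetic, lam):
        with pytest.raises(ValueError):
            assign_ei_labels(medium_synthetic, lam, seed=0)

    def test_deterministic_under_seed(self, small_synthetic):
        a1 = assign_ei_labels(small_synthetic, 0.4, seed=5)
        a2 = assign_ei_labels(small_synthetic, 0.4, seed=5)
        assert a1.labels == a2.labels


class TestStaticStrengths:
    def test_equal_alpha_gives_unit_prefactor(self):
        c = connectome_from_edges([(0, 1, 3), (1, 2, 3), (2, 0, 3)])
        labels = {0: 1, 1: 1, 2: 0}
        s = draw_static_strengths(c, _assignment(c, labels), seed=2)
        for k, pre in enumerate(s.pre):
            if labels[int(pre)] == 1:
                assert s.strengths[k] == pytest.approx(s.excit_draws[k])
            else:
                assert s.strengths[k] == pytest.approx(s.inhib_draws[k])

    def test_inhibitory_neuron_outputs_nonpositive(self, small_synthetic):
        a = assign_ei_labels(small_synthetic, 0.3, seed=3)
        s = draw_static_strengths(small_synthetic, a, seed=4)
        for k, pre in enumerate(s.pre):
            if a.labels[int(pre)] == 0:
                assert s.strengths[k] <= 0
            else:
                assert s.strengths[k] > 0

    def test_formula_exact(self, small_synthetic):
        a = assign_ei_labels(small_synthetic, 0.6, seed=5)
        s = draw_static_strengths(small_synthetic, a, seed=6)
        alpha_mean = small_synthetic.edges["synapse_count"].mean()
        assert s.normalizer == pytest.approx(alpha_mean)
        x = np.array([a.labels[int(p)] for p in s.pre], float)
        expect = (s.alpha / alpha_mean) * (x * s.excit_draws + (1 - x) * s.inhib_draws)
        np.testing.assert_allclose(s.strengths, expect)

    def test_excitatory_draw_mean(self, medium_synthetic):
        # Y ~ U(0,1]: mean of S <alpha>/alpha over excitatory edges ~ 0.5
        a = assign_ei_labels(medium_synthetic, 0.5, seed=7)
        s = draw_static_strengths(medium_synthetic, a, seed=8)
        x = np.array([a.labels[int(p)] for p in s.pre], bool)
        vals = (s.strengths * s.normalizer / s.alpha)[x]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * se

    def test_empty_edge_set_raises(self):
        import pandas as pd
        from neuroperc.connectome import build_connectome

        nodes = pd.DataFrame(
            {"neuron_id": [0], "region": [0], "x_nm": [0.0], "y_nm": [0.0], "z_nm": [0.0]}
        )
        c = build_connectome(
            nodes, pd.DataFrame(columns=["pre_id", "post_id", "synapse_count"])
        )
        a = EIAssignment({0: 1}, 0.5, 0.5, 0, True)
        with pytest.raises(ValueError):
            draw_static_strengths(c, a, seed=0)


class TestLIFTrial:
    def test_pure_inhibition_never_fires(self):
        c = connectome_from_edges([(0, 2, 1), (1, 2, 1)])
        s = _forced_strengths(c, {0: 0, 1: 0, 2: 1},
                              {(0, 2): -0.8, (1, 2): -0.5})
        assert run_lif_trial(c, s, 2, {0, 1}, LIFConfig(), seed=0) == 0

    def test_single_suprathreshold_impulse_fires(self):
        # one impulse S (V_thresh - V_rest) >= threshold gap  <=>  S >= 1
        c = connectome_from_edges([(0, 1, 1)])
        s = _forced_strengths(c, {0: 1, 1: 1}, {(0, 1): 1.05})
        assert run_lif_trial(c, s, 1, {0}, LIFConfig(), seed=0) == 1
        s2 = _forced_strengths(c, {0: 1, 1: 1}, {(0, 1): 0.95})
        assert run_lif_trial(c, s2, 1, {0}, LIFConfig(), seed=0) == 0

    def test_simultaneous_subunit_impulses_sum(self):
        # two drivers of strength 0.6 overshoot together (1.2 > 1)
        c = connectome_from_edges([(0, 2, 1), (1, 2, 1)])
        s = _forced_strengths(c, {0: 1, 1: 1, 2: 1},
                              {(0, 2): 0.6, (1, 2): 0.6})
        assert run_lif_trial(c, s, 2, {0, 1}, LIFConfig(), seed=0) == 1
        assert run_lif_trial(c, s, 2, {0}, LIFConfig(), seed=0) == 0

    def test_matches_independent_scalar_recursion(self):
        # chain h -> j: oracle recursion of the same Euler scheme
        c = connectome_from_edges([(0, 1, 1)])
        for strength in (0.3, 0.9, 1.0, 1.1):
            s = _forced_strengths(c, {0: 1, 1: 1}, {(0, 1): strength})
            cfg = LIFConfig()
            v = cfg.v_rest
            fired = 0
            for _ in range(cfg.n_steps):
                v = v * (1 - cfg.dt / cfg.tau_m) + cfg.leak_reversal * (
                    cfg.dt / cfg.tau_m
                )
                v = v + strength * (cfg.v_threshold - v)
                if v >= cfg.v_threshold:
                    fired = 1
                    break
            assert run_lif_trial(c, s, 1, {0}, cfg, seed=0) == fired

    def test_target_cannot_be_driven(self):
        c = connectome_from_edges([(0, 1, 1)])
        s = _forced_strengths(c, {0: 1, 1: 1}, {(0, 1): 0.5})
        with pytest.raises(ValueError):
            run_lif_trial(c, s, 1, {0, 1}, LIFConfig(), seed=0)

    def test_kernel_agrees_with_reference_trial(self, small_synthetic):
        """The vectorized kernel and the scalar reference implement the
        same dynamics for arbitrary driven sets."""
        c = small_synthetic
        a = assign_ei_labels(c, 0.6, seed=9)
        s = draw_static_strengths(c, a, seed=10)
        adj = _out_adjacency(s)
        rng = np.random.default_rng(0)
        targets = rng.choice(c.edges["post_id"].unique(), size=12, replace=False)
        for j in targets:
            preds = sorted(int(p) for p in c.edges.loc[c.edges["post_id"] == j, "pre_id"])
            net = _LocalNetwork(preds, int(j), adj)
            for _ in range(4):
                k = int(rng.integers(1, len(preds) + 1))
                driven = set(rng.choice(preds, size=k, replace=False).tolist())
                mask = np.zeros((1, net.n_local), dtype=bool)
                for h in driven:
                    mask[0, net.index[h]] = True
                ref = run_lif_trial(c, s, int(j), driven, LIFConfig(), seed=0)
                vec = int(_simulate_batch(net, mask, LIFConfig())[0])
                assert ref == vec


class TestCoactivationEstimation:
    def test_deterministic_and_quantized(self, small_synthetic):
        c = small_synthetic
        a = assign_ei_labels(c, 0.7, seed=11)
        s = draw_static_strengths(c, a, seed=12)
        cfg = LIFConfig()
        edge = tuple(c.edges.iloc[0][["pre_id", "post_id"]].astype(int))
        p1 = estimate_coactivation(c, s, edge, cfg, seed=13)
        p2 = estimate_coactivation(c, s, edge, cfg, seed=13)
        assert p1 == p2
        assert round(p1 * cfg.trials) == pytest.approx(p1 * cfg.trials)

    def test_nonedge_rejected(self, small_synthetic):
        c = small_synthetic
        a = assign_ei_labels(c, 0.7, seed=1)
        s = draw_static_strengths(c, a, seed=2)
        post = int(c.edges["post_id"].iloc[0])
        non_pred = next(
            int(i) for i in c.neuron_ids()
            if i not in set(c.edges.loc[c.edges["post_id"] == post, "pre_id"])
            and i != post
        )
        with pytest.raises(ValueError):
            estimate_coactivation(c, s, (non_pred, post), LIFConfig(), seed=0)

    def test_graph_covers_every_static_edge(self, small_synthetic):
        c = small_synthetic
        a = assign_ei_labels(c, 0.5, seed=3)
        s = draw_static_strengths(c, a, seed=4)
        cg = coactivation_graph(c, s, LIFConfig(trials=10), seed=5, lam=0.5)
        static = {
            (int(x), int(y))
            for x, y in zip(c.edges["pre_id"], c.edges["post_id"])
        }
        assert set(cg.probabilities) == static
        assert all(0.0 <= p <= 1.0 for p in cg.probabilities.values())

    def test_whole_graph_matches_per_edge_estimates(self, small_synthetic):
        """Evaluation order must not matter: the pooled whole-graph run
        reproduces independent per-edge estimates exactly."""
        c = small_synthetic
        a = assign_ei_labels(c, 0.6, seed=6)
        s = draw_static_strengths(c, a, seed=7)
        cfg = LIFConfig()
        cg = coactivation_graph(c, s, cfg, seed=8, lam=0.6)
        rng = np.random.default_rng(1)
        edges = list(cg.probabilities)
        for k in rng.choice(len(edges), size=10, replace=False):
            e = edges[int(k)]
            assert cg.probabilities[e] == estimate_coactivation(c, s, e, cfg, seed=8)

    def test_mean_coactivation_increases_with_lambda(self, small_synthetic):
        c = small_synthetic
        cfg = LIFConfig(trials=40)
        means = []
        for lam in (0.1, 0.5, 0.9):
            a = assign_ei_labels(c, lam, seed=20)
            s = draw_static_strengths(c, a, seed=21)
            cg = coactivation_graph(c, s, cfg, seed=22, lam=lam)
            means.append(cg.mean_probability())
        assert means[0] < means[1] < means[2]

    def test_driven_sets_meet_indegree_floor(self, small_synthetic):
        c = small_synthetic
        a = assign_ei_labels(c, 0.5, seed=1)
        s = draw_static_strengths(c, a, seed=2)
        adj = _out_adjacency(s)
        j = int(c.edges["post_id"].mode()[0])
        preds = sorted(int(p) for p in c.edges.loc[c.edges["post_id"] == j, "pre_id"])
        net = _LocalNetwork(preds, j, adj)
        i = preds[0]
        cfg = LIFConfig()
        masks = _driven_masks(net, i, cfg, _edge_rng(0, i, j))
        import math

        floor = max(1, math.ceil(cfg.drive_fraction * len(preds)))
        counts = masks.sum(axis=1)
        assert (counts == floor).all()
        assert masks[:, net.index[i]].all()
        assert not masks[:, net.n_local - 1].any()
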