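"""MLP training correctness, probe ranking, interaction inference, hub rules."""

import numpy as np
import pytest

from gliostrat import (
    InteractionNetwork,
    MLPConfig,
    infer_pairwise_interactions,
    rank_probes_by_prediction,
    select_top_edges_and_hubs,
    train_mlp,
)
from gliostrat.ann_interactome import mlp_gradients, mlp_loss

from conftest import make_dataset


class TestMLPConfig:
    def test_split_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MLPConfig(split_fractions=(0.5, 0.2, 0.2))

    def test_hidden_nodes_positive(self):
        with pytest.raises(ValueError):
            MLPConfig(hidden_nodes=0)


class TestTrainMLP:
    def test_zero_init_zero_lr_outputs_half(self):
        cfg = MLPConfig(learning_rate=0.0, init_scale=0.0, max_epochs=5)
        X = np.random.default_rng(0).normal(size=(10, 2))
        model = train_mlp(X, np.zeros(10), cfg)
        np.testing.assert_allclose(model.predict(X), 0.5)

    def test_xor_learned_in_most_seeds(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        Xs = (X - X.mean(0)) / X.std(0)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        ok = 0
        for seed in range(10):
            cfg = MLPConfig(max_epochs=5000, seed=seed)
            model = train_mlp(Xs, y, cfg, rng=np.random.default_rng(seed))
            ok += float(np.mean((model.predict(Xs) - y) ** 2)) < 0.1
        assert ok >= 8

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4))
        y = rng.uniform(size=8)
        w1 = rng.normal(size=(4, 2))
        b1 = rng.normal(size=2)
        w2 = rng.normal(size=2)
        b2 = 0.1
        g1, gb1, g2, gb2, _ = mlp_gradients(w1, b1, w2, b2, X, y)
        eps = 1e-6

        def num(arr, grad):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                lp = mlp_loss(w1, b1, w2, b2, X, y)
                arr[i] = orig - eps
                lm = mlp_loss(w1, b1, w2, b2, X, y)
                arr[i] = orig
                assert abs((lp - lm) / (2 * eps) - grad[i]) < 1e-6

        num(w1, g1)
        num(b1, gb1)
        num(w2, g2)
        lp = mlp_loss(w1, b1, w2, b2 + eps, X, y)
        lm = mlp_loss(w1, b1, w2, b2 - eps, X, y)
        assert abs((lp - lm) / (2 * eps) - gb2) < 1e-6

    def test_targets_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.zeros((5, 1)), np.array([0.0, 0.5, 1.5, 0.2, 0.1]), MLPConfig())


def driver_dataset(seed, n=150, n_null=30):
    """Target = sigmoid of one driver probe + small noise; rest independent."""
    rng = np.random.default_rng(seed)
    driver = rng.normal(size=n)
    target = 1 / (1 + np.exp(-2 * driver)) + rng.normal(scale=0.1, size=n)
    vals = np.vstack([driver] + [rng.normal(size=n) for _ in range(n_null)] + [target])
    probes = [f"p{i}" for i in range(n_null + 1)] + ["target"]
    return make_dataset(vals, probes=probes)


class TestRankProbes:
    def test_self_prediction_ranks_first(self):
        ds = driver_dataset(1, n_null=5)
        cfg = MLPConfig(bootstraps=5, max_epochs=500, seed=0)
        ranking = rank_probes_by_prediction(ds, "target", cfg)
        assert ranking.top(1) == ["target"]
        # sigmoid sharpening toward the median step is logarithmic in epochs,
        # so "near zero" here means far below the 0.5 null baseline
        assert ranking.table.iloc[0]["mean_rmse"] < 0.3
        assert ranking.table.iloc[0]["misclassification"] < 0.15

    def test_planted_driver_ranks_first(self):
        hits = 0
        for seed in range(3):
            ds = driver_dataset(seed, n_null=20)
            cfg = MLPConfig(bootstraps=8, max_epochs=120, seed=seed)
            ranking = rank_probes_by_prediction(ds, "target", cfg, candidates=[f"p{i}" for i in range(21)])
            hits += ranking.top(1) == ["p0"]
        assert hits >= 2

    def test_pure_noise_rmse_near_half(self):
        rng = np.random.default_rng(9)
        n = 120
        vals = np.vstack([rng.normal(size=n) for _ in range(6)])
        ds = make_dataset(vals)
        cfg = MLPConfig(bootstraps=10, max_epochs=100, seed=0)
        ranking = rank_probes_by_prediction(ds, "p5", cfg, candidates=[f"p{i}" for i in range(5)])
        assert np.all(np.abs(ranking.table["mean_rmse"] - 0.5) < 0.06)

    def test_affine_rescaling_invariance(self):
        ds = driver_dataset(4, n_null=3)
        cfg = MLPConfig(bootstraps=5, max_epochs=80, seed=2)
        r1 = rank_probes_by_prediction(ds, "target", cfg, candidates=["p0", "p1"])
        rescaled = make_dataset(
            np.vstack([ds.values[0] * 50.0 - 7.0, ds.values[1], ds.values[-1]]),
            probes=["p0", "p1", "target"],
        )
        r2 = rank_probes_by_prediction(rescaled, "target", cfg, candidates=["p0", "p1"])
        np.testing.assert_allclose(
            r1.table["mean_rmse"].to_numpy(), r2.table["mean_rmse"].to_numpy(), rtol=1e-9
        )

    def test_deterministic_given_seed(self):
        ds = driver_dataset(5, n_null=4)
        cfg = MLPConfig(bootstraps=4, max_epochs=60, seed=3)
        r1 = rank_probes_by_prediction(ds, "target", cfg)
        r2 = rank_probes_by_prediction(ds, "target", cfg)
        np.testing.assert_array_equal(
            r1.table["mean_rmse"].to_numpy(), r2.table["mean_rmse"].to_numpy()
        )

    def test_empty_candidates_rejected(self):
        ds = driver_dataset(6, n_null=3)
        with pytest.raises(ValueError):
            rank_probes_by_prediction(ds, "target", MLPConfig(), candidates=[])


def hub_dataset(seed, n=200, coupling=2.0):
    rng = np.random.default_rng(seed)
    h = rng.normal(size=n)
    vals = [h] + [coupling * h + rng.normal(scale=0.5, size=n) for _ in range(3)]
    vals += [rng.normal(size=n) for _ in range(4)]
    return make_dataset(np.vstack(vals), probes=[f"q{i}" for i in range(8)])


class TestInferInteractions:
    def test_ordered_pair_count_m2(self):
        ds = hub_dataset(0)
        cfg = MLPConfig(bootstraps=2, max_epochs=20, seed=0)
        net = infer_pairwise_interactions(ds, cfg, probes=["q0", "q1"])
        assert net.n_edges == 2

    def test_all_ordered_pairs_evaluated(self):
        ds = hub_dataset(1)
        cfg = MLPConfig(bootstraps=2, max_epochs=20, seed=0)
        net = infer_pairwise_interactions(ds, cfg)
        assert net.n_edges == 8 * 7

    def test_planted_hub_sign_and_magnitude(self):
        ds = hub_dataset(2)
        cfg = MLPConfig(bootstraps=8, max_epochs=120, seed=2)
        net = infer_pairwise_interactions(ds, cfg)
        w = {(s, t): wt for s, t, wt in net.edges}
        for j in (1, 2, 3):
            assert w[("q0", f"q{j}")] > 0
            assert abs(w[("q0", f"q{j}")]) > abs(w[("q0", "q5")])

    def test_deterministic_given_seed(self):
        ds = hub_dataset(3)
        cfg = MLPConfig(bootstraps=3, max_epochs=40, seed=1)
        n1 = infer_pairwise_interactions(ds, cfg, probes=["q0", "q1", "q2"])
        n2 = infer_pairwise_interactions(ds, cfg, probes=["q0", "q1", "q2"])
        assert n1.edges == n2.edges

    def test_single_probe_rejected(self):
        ds = hub_dataset(4)
        with pytest.raises(ValueError):
            infer_pairwise_interactions(ds, MLPConfig(), probes=["q0"])


class TestSelectTopEdgesAndHubs:
    def _star(self, n_leaves=6, weight=1.0):
        edges = tuple((f"leaf{i}", "center", weight + i * 0.01) for i in range(n_leaves))
        nodes = ("center",) + tuple(f"leaf{i}" for i in range(n_leaves))
        return InteractionNetwork(edges=edges, nodes=nodes)

    def test_star_center_is_single_hub(self):
        pruned, hubs = select_top_edges_and_hubs(self._star(6), top_k=10)
        assert list(hubs["node"]) == ["center"]
        assert pruned.n_edges == 6

    def test_four_incident_edges_is_not_a_hub(self):
        _, hubs = select_top_edges_and_hubs(self._star(4), top_k=10)
        assert len(hubs) == 0

    def test_hub_ranking_matches_brute_force_strength(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(8)]
        edges = tuple(
            (nodes[i], nodes[j], float(rng.normal()))
            for i in range(8)
            for j in range(8)
            if i != j
        )
        net = InteractionNetwork(edges=edges, nodes=tuple(nodes))
        pruned, hubs = select_top_edges_and_hubs(net, top_k=30, hub_degree=5)
        strength = {}
        for s, t, w in pruned.edges:
            for node in (s, t):
                strength[node] = strength.get(node, 0.0) + abs(w)
        expected = sorted(
            (n for n in strength if sum(1 for s, t, _ in pruned.edges if n in (s, t)) >= 5),
            key=lambda n: -strength[n],
        )
        assert list(hubs["node"]) == expected

    def test_edge_count_bounded_by_top_k(self):
        net = self._star(6)
        pruned, _ = select_top_edges_and_hubs(net, top_k=3)
        assert pruned.n_edges == 3

    def test_hub_set_shrinks_as_degree_threshold_grows(self):
        net = self._star(6)
        _, hubs5 = select_top_edges_and_hubs(net, top_k=10, hub_degree=5)
        _, hubs7 = select_top_edges_and_hubs(net, top_k=10, hub_degree=7)
        assert set(hubs7["node"]).issubset(set(hubs5["node"]))

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            InteractionNetwork(edges=(("a", "a", 1.0),), nodes=("a",))
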