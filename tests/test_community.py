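import itertools

import numpy as np
import pytest

from tmfc.community import (
    ModularityParams,
    genlouvain_optimize,
    layer_null_model,
    multilayer_modularity,
    repeat_optimization,
    supra_modularity_matrix,
)
from tmfc.measures import node_flexibility
from tmfc.networks import LayerMatrix, TemporalMultilayerNetwork

from conftest import random_multilayer


def naive_modularity(labels, net, gamma):
    """Literal quadruple-loop evaluation of the multilayer quality function."""
    n, L = net.n_nodes, net.n_layers
    stack = net.layer_stack()
    nulls = [layer_null_model(net.layers[s]) for s in range(L)]
    two_mu = sum(stack[s].sum() for s in range(L))
    two_mu += 2.0 * net.omega * n * (L - 1)
    if two_mu == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            for s in range(L):
                for r in range(L):
                    if labels[i, s] != labels[j, r]:
                        continue
                    if s == r:
                        total += stack[s][i, j] - gamma * nulls[s][i, j]
                    elif i == j and abs(s - r) == 1:
                        total += net.omega
    return total / two_mu


class TestNullModel:
    def test_single_edge_pair(self):
        lay = LayerMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), 0)
        np.testing.assert_allclose(layer_null_model(lay), np.full((2, 2), 0.5))

    def test_unit_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(layer_null_model(LayerMatrix(w, 0)),
                                   np.full((3, 3), 4.0 / 6.0))

    def test_empty_layer_returns_zeros(self):
        lay = LayerMatrix(np.zeros((4, 4)), 0)
        np.testing.assert_array_equal(layer_null_model(lay), np.zeros((4, 4)))


class TestModularityValue:
    def test_single_layer_one_community_is_zero(self, two_clique_single):
        labels = np.ones((6, 1), dtype=int)
        assert multilayer_modularity(labels, two_clique_single) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_single_layer(self, two_clique_single):
        labels = np.array([[1], [1], [1], [2], [2], [2]])
        assert multilayer_modularity(labels, two_clique_single) == pytest.approx(0.5)

    def test_two_cliques_two_layers_with_coupling(self, two_clique_duplex):
        labels = np.array([[1], [1], [1], [2], [2], [2]]).repeat(2, axis=1)
        assert multilayer_modularity(labels, two_clique_duplex) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_quadruple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 5)), int(rng.integers(2, 4))
        net = random_multilayer(rng, n, L, omega=float(rng.random()))
        labels = rng.integers(1, 4, size=(n, L))
        gamma = float(rng.uniform(0.5, 1.5))
        fast = multilayer_modularity(labels, net, ModularityParams(gamma=gamma))
        assert fast == pytest.approx(naive_modularity(labels, net, gamma), abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(11)
        net = random_multilayer(rng, 5, 3, omega=0.4)
        labels = rng.integers(1, 4, size=(5, 3))
        relabeled = np.array([10, 30, 20, 40])[labels - 1]
        assert multilayer_modularity(labels, net) == pytest.approx(
            multilayer_modularity(relabeled, net), abs=1e-12
        )


class TestOptimizer:
    def test_recovers_planted_two_blocks(self):
        rng = np.random.default_rng(0)
        w = np.zeros((8, 8))
        blocks = [range(4), range(4, 8)]
        for blk in blocks:
            for i in blk:
                for j in blk:
                    if i != j:
                        w[i, j] = 0.9 + 0.1 * rng.random()
        w = (w + w.T) / 2
        layers = [LayerMatrix(w, 0), LayerMatrix(w, 1)]
        net = TemporalMultilayerNetwork(layers=layers, omega=0.5)
        a = genlouvain_optimize(net, ModularityParams(), rep_seed=3)
        for s in range(2):
            col = a.labels[:, s]
            assert len(set(col[:4])) == 1
            assert len(set(col[4:])) == 1
            assert col[0] != col[4]

    def test_large_omega_freezes_communities_across_layers(self):
        rng = np.random.default_rng(1)
        net = random_multilayer(rng, 6, 4, omega=100.0)
        a = genlouvain_optimize(net, ModularityParams(omega=100.0), rep_seed=0)
        assert np.all(node_flexibility(a.labels) == 0.0)

    def test_q_value_consistent_with_evaluator(self, two_clique_duplex):
        a = genlouvain_optimize(two_clique_duplex, ModularityParams(), rep_seed=5)
        assert a.q_value == pytest.approx(
            multilayer_modularity(a.labels, two_clique_duplex), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_trivial_baselines(self, seed):
        rng = np.random.default_rng(seed)
        net = random_multilayer(rng, 6, 3, omega=0.5)
        a = genlouvain_optimize(net, ModularityParams(), rep_seed=seed)
        singletons = np.arange(1, 19).reshape(3, 6).T
        all_in_one = np.ones((6, 3), dtype=int)
        assert a.q_value >= multilayer_modularity(singletons, net) - 1e-12
        assert a.q_value >= multilayer_modularity(all_in_one, net) - 1e-12

    def test_q_trace_is_monotone(self):
        rng = np.random.default_rng(9)
        net = random_multilayer(rng, 8, 4, omega=0.3)
        a = genlouvain_optimize(net, ModularityParams(), rep_seed=2)
        assert all(b >= a_ - 1e-12 for a_, b in zip(a.q_trace, a.q_trace[1:]))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        net = random_multilayer(rng, 7, 3, omega=0.5)
        a1 = genlouvain_optimize(net, ModularityParams(), rep_seed=17)
        a2 = genlouvain_optimize(net, ModularityParams(), rep_seed=17)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        assert a1.q_value == a2.q_value


def exhaustive_best_q(net, gamma=1.0):
    """Maximum Q over every partition of the node-layer slots (oracle)."""
    B, two_mu = supra_modularity_matrix(net, gamma=gamma)
    B = B.toarray()
    n_slots = B.shape[0]
    best = -np.inf
    for labels in itertools.product(*[range(k + 1) for k in range(n_slots)]):
        # restricted growth strings enumerate set partitions exactly once
        lab = np.asarray(labels)
        if any(lab[k] > (lab[:k].max(initial=-1) + 1) for k in range(n_slots)):
            continue
        same = lab[:, None] == lab[None, :]
        best = max(best, B[same].sum())
    return best / two_mu


class TestGlobalOptimality:
    @pytest.mark.parametrize("n,L,omega,seed", [
        (2, 2, 0.5, 0), (2, 3, 0.5, 1), (3, 2, 0.3, 2), (4, 2, 1.0, 3),
    ])
    def test_best_of_restarts_attains_exhaustive_maximum(self, n, L, omega, seed):
        rng = np.random.default_rng(seed)
        net = random_multilayer(rng, n, L, omega=omega)
        target = exhaustive_best_q(net)
        best = max(
            genlouvain_optimize(net, ModularityParams(), rep_seed=r).q_value
            for r in range(20)
        )
        assert best == pytest.approx(target, abs=1e-10)


class TestEnsemble:
    def test_csv_round_trip(self, two_clique_duplex, tmp_path):
        from tmfc.community import read_ensemble, write_ensemble

        ens = repeat_optimization(two_clique_duplex,
                                  ModularityParams(n_repetitions=3, seed=1))
        write_ensemble(ens, tmp_path / "ensemble.csv")
        back = read_ensemble(tmp_path / "ensemble.csv")
        np.testing.assert_array_equal(back.label_array(), ens.label_array())

    def test_repetition_count_and_determinism(self, two_clique_duplex):
        params = ModularityParams(n_repetitions=10, seed=123)
        e1 = repeat_optimization(two_clique_duplex, params)
        e2 = repeat_optimization(two_clique_duplex, params)
        assert len(e1.assignments) == 10
        np.testing.assert_array_equal(e1.label_array(), e2.label_array())

    def test_unique_optimum_reached_by_all_repetitions(self, two_clique_duplex):
        ens = repeat_optimization(two_clique_duplex,
                                  ModularityParams(n_repetitions=8, seed=0))
        for a in ens.assignments:
            assert a.q_value == pytest.approx(0.6)
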