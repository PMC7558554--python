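import networkx as nx
import numpy as np
import pytest

from conftest import make_network
from emopinion import (
    DWParams,
    dw_update,
    inciting_force,
    interact_round,
    perceive,
    summarize_neighborhood,
    type_change_probability,
)
from reference import brute_force_round

DW = DWParams(d1=0.5, theta1=0.5)


class TestScalarOps:
    def test_inciting_force_scales_arousal(self):
        assert inciting_force(1.0, a=1.0) == 1.0
        assert inciting_force(0.8, a=0.0) == 0.0

    def test_inciting_force_preserves_arousal_ordering(self):
        """sadness < joy = anger < fear for any positive adjustment."""
        eps = {k: inciting_force(v, a=0.7) for k, v in [(3, 0.6), (1, 0.8), (2, 0.8), (4, 1.0)]}
        assert eps[3] < eps[1] == eps[2] < eps[4]

    def test_perceive_hand_value_and_linearity(self):
        assert perceive(-0.8, 1.0, 0.5, 0.5) == pytest.approx(-0.2)
        assert perceive(0.0, 1.0, 0.5, 0.5) == 0.0
        assert perceive(0.4, 1.0, 0.5, 1.0) == pytest.approx(2 * perceive(0.4, 1.0, 0.5, 0.5))

    def test_type_change_probability(self):
        assert type_change_probability(0.3, 0.3, 0.9) == 0.0
        assert type_change_probability(0.7, 0.2, 0.5) == pytest.approx(0.25)
        assert type_change_probability(0.9, 0.1, 0.0) == 0.0

    def test_probability_never_exceeds_one(self, rng):
        for _ in range(200):
            p = type_change_probability(rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 1))
            assert 0 <= p <= 1


class TestDWUpdate:
    def test_no_update_outside_threshold(self):
        assert dw_update(0.4, 0.95, DW) == 0.4

    def test_positive_branch_strengthens(self):
        assert dw_update(0.4, 0.8, DW) == pytest.approx(0.6)

    def test_negative_branch_strengthens(self):
        assert dw_update(-0.4, -0.8, DW) == pytest.approx(-0.6)

    def test_consensus_is_a_fixed_point(self):
        for y in (-0.7, 0.2, 0.9):
            assert dw_update(y, y, DW) == y

    def test_result_clamped(self):
        assert dw_update(0.9, 1.3, DWParams(d1=0.5, theta1=1.0)) == 1.0

    def test_magnitude_never_shrinks_within_threshold(self, rng):
        """Assimilation is polarizing: |y'| >= |y| whenever an update fires."""
        for _ in range(300):
            y = rng.uniform(-1, 1)
            avg = rng.uniform(-1, 1)
            if y == 0:
                continue
            y2 = dw_update(y, avg, DW)
            assert abs(y2) >= abs(y) - 1e-12


class TestNeighborhoodSummary:
    def test_hand_counted_star(self):
        """Neighbors hold types {1, 1, 2, 0}; self holds 2."""
        net = make_network([(0, 1), (0, 2), (0, 3), (0, 4)])
        att_type = np.array([2, 1, 1, 2, 0])
        att_value = np.array([0.5, 0.4, 0.6, -0.3, 0.0])
        arousal = np.array([0.8, 0.8, 0.8, 0.8, 0.6])
        s = summarize_neighborhood(0, att_type, att_value, arousal, net, gamma_i=0.5, lam_i=1.0)
        assert s.mainstream_type == 1
        assert s.pn_iu == pytest.approx(0.5)
        assert s.pn_i == pytest.approx(0.25)
        assert s.n_iu == 2 and s.n_i == 1
        assert s.t_iu == pytest.approx(0.125)

    def test_same_type_weighted_average(self):
        """One same-type neighbor, y=0.6, eps=1, lam=1, S=0.8 -> avg 0.6."""
        net = make_network([(0, 1)], strengths=[0.8])
        att_type = np.array([4, 4])
        att_value = np.array([0.2, 0.6])
        arousal = np.array([1.0, 1.0])
        s = summarize_neighborhood(0, att_type, att_value, arousal, net, 0.5, 1.0)
        assert s.same_type_avg == pytest.approx(0.6)

    def test_unanimous_neighborhood_has_zero_pressure(self, star_network):
        att_type = np.array([3, 3, 3, 3])
        att_value = np.array([-0.5, -0.4, -0.6, -0.3])
        arousal = np.full(4, 0.6)
        s = summarize_neighborhood(0, att_type, att_value, arousal, star_network, 0.9, 0.5)
        assert s.mainstream_type == 3
        assert s.t_iu == 0.0

    def test_silent_agent_rejected(self, star_network):
        att_type = np.array([0, 1, 1, 1])
        with pytest.raises(ValueError):
            summarize_neighborhood(
                0, att_type, np.zeros(4), np.full(4, 0.8), star_network, 0.5, 0.5
            )

    def test_no_expressing_neighbors_is_inert(self, star_network):
        att_type = np.array([1, 0, 0, 0])
        s = summarize_neighborhood(
            0, att_type, np.zeros(4), np.full(4, 0.8), star_network, 0.5, 0.5
        )
        assert s.inert


def random_case(seed):
    """Random small network state for oracle comparison."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    g = nx.gnp_random_graph(n, 0.7, seed=int(rng.integers(1 << 30)))
    for u, v in g.edges:
        g[u][v]["strength"] = float(rng.uniform(0.05, 1.0))
    from emopinion import SocialNetwork

    net = SocialNetwork(g)
    att_type = rng.integers(0, 5, n)
    att_value = np.where(att_type > 0, rng.uniform(-1, 1, n), 0.0)
    emo_arousal = rng.choice([0.6, 0.8, 1.0], n)
    gamma = rng.uniform(0, 1, n)
    lam = rng.uniform(0, 1, n)
    return net, att_type, att_value, emo_arousal, gamma, lam


class TestInteractRound:
    @pytest.mark.parametrize("seed", range(40))
    @pytest.mark.parametrize("bernoulli", [False, True])
    def test_matches_brute_force_oracle(self, seed, bernoulli):
        """Vectorized round equals a straight-line per-agent transcription."""
        net, att_type, att_value, arousal, gamma, lam = random_case(seed)
        draws = np.random.default_rng(seed + 1).random(len(att_type))
        got_t, got_v, _ = interact_round(
            att_type, att_value, arousal, net, gamma, lam, DW,
            np.random.default_rng(seed + 1), a=1.0, bernoulli_switch=bernoulli,
        )
        exp_t, exp_v = brute_force_round(
            net.graph, att_type, att_value, arousal, gamma, lam,
            DW.d1, DW.theta1, 1.0, draws=draws if bernoulli else None,
        )
        np.testing.assert_array_equal(got_t, exp_t)
        np.testing.assert_allclose(got_v, exp_v, atol=1e-12)

    def test_consensus_is_a_fixed_point(self, rng):
        net, *_ = random_case(3)
        n = net.n_nodes
        att_type = np.full(n, 2)
        att_value = np.full(n, -0.6)
        got_t, got_v, switched = interact_round(
            att_type, att_value, np.full(n, 0.8), net,
            np.full(n, 0.5), np.full(n, 1.0), DWParams(d1=0.5, theta1=0.5), rng,
        )
        # same value everywhere: perceived averages differ (eps, lam < 1 damp
        # them), but types cannot change and no new types appear
        np.testing.assert_array_equal(got_t, att_type)
        assert not switched.any()

    def test_identical_value_and_full_perception_is_inert(self, rng):
        """With eps = lam = S = 1 a unanimous group is an exact fixed point."""
        net = make_network([(0, 1), (1, 2), (0, 2)])
        att_type = np.full(3, 4)
        att_value = np.full(3, 0.7)
        got_t, got_v, _ = interact_round(
            att_type, att_value, np.full(3, 1.0), net,
            np.full(3, 0.5), np.full(3, 1.0), DW, rng,
        )
        np.testing.assert_array_equal(got_t, att_type)
        np.testing.assert_allclose(got_v, att_value)

    def test_silent_agents_never_update(self, rng):
        net, att_type, att_value, arousal, gamma, lam = random_case(11)
        got_t, got_v, _ = interact_round(att_type, att_value, arousal, net, gamma, lam, DW, rng)
        silent = att_type == 0
        assert np.all(got_t[silent] == 0)
        assert np.all(got_v[silent] == 0.0)

    def test_no_new_types_appear(self):
        for seed in range(10):
            net, att_type, att_value, arousal, gamma, lam = random_case(seed + 100)
            got_t, _, _ = interact_round(
                att_type, att_value, arousal, net, gamma, lam, DW, np.random.default_rng(seed)
            )
            before = set(att_type.tolist())
            assert set(got_t.tolist()) <= before | {0}

    def test_outcome_invariant_to_node_relabeling(self):
        """Synchronous update: permuting agent labels permutes the outcome."""
        net, att_type, att_value, arousal, gamma, lam = random_case(21)
        n = net.n_nodes
        perm = np.random.default_rng(0).permutation(n)
        inv = np.argsort(perm)
        g2 = nx.relabel_nodes(net.graph, {i: int(perm[i]) for i in range(n)})
        from emopinion import SocialNetwork

        net2 = SocialNetwork(g2)
        t1, v1, _ = interact_round(
            att_type, att_value, arousal, net, gamma, lam, DW, np.random.default_rng(5)
        )
        t2, v2, _ = interact_round(
            att_type[inv], att_value[inv], arousal[inv], net2, gamma[inv], lam[inv],
            DW, np.random.default_rng(5),
        )
        np.testing.assert_array_equal(t2[perm], t1)
        np.testing.assert_allclose(v2[perm], v1, atol=1e-12)

    def test_deterministic_under_fixed_seed(self):
        net, att_type, att_value, arousal, gamma, lam = random_case(33)
        out1 = interact_round(
            att_type, att_value, arousal, net, gamma, lam, DW,
            np.random.default_rng(9), bernoulli_switch=True,
        )
        out2 = interact_round(
            att_type, att_value, arousal, net, gamma, lam, DW,
            np.random.default_rng(9), bernoulli_switch=True,
        )
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)
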