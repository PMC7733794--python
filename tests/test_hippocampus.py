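"""Successor representation: tabular and feature-based forms."""

import numpy as np
import pytest

from dualsys.environments import build_task_graph
from dualsys.hippocampus import (
    SuccessorFeatures,
    TabularSR,
    devalue,
    feature_reward_update,
    identity_sr,
    random_walk_sr,
    reward_update,
    sf_estimate,
    sf_td_update,
    sr_td_update,
    v_hpc,
)


class TestClosedForms:
    def test_two_state_swap_chain(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        M = random_walk_sr(T, 0.5)
        assert np.allclose(M, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]])

    def test_gamma_zero_gives_identity(self, rng):
        T = rng.dirichlet(np.ones(4), size=4)
        assert np.allclose(random_walk_sr(T, 0.0), np.eye(4))

    def test_row_sums_are_geometric_series(self, rng):
        T = rng.dirichlet(np.ones(6), size=6)
        M = random_walk_sr(T, 0.9)
        assert np.allclose(M.sum(axis=1), 1 / (1 - 0.9))

    def test_matches_inversion_oracle(self, rng):
        T = rng.dirichlet(np.ones(5), size=5)
        gamma = 0.8
        oracle = np.linalg.solve(np.eye(5) - gamma * T, np.eye(5))
        assert np.allclose(random_walk_sr(T, gamma), oracle)

    def test_identity_sr(self):
        M = identity_sr(3)
        assert np.array_equal(M, np.eye(3))
        with pytest.raises(ValueError):
            identity_sr(0)


class TestTabularTD:
    def test_single_step_arithmetic(self):
        M = identity_sr(3)
        delta = sr_td_update(M, 0, 1, False, alpha_m=0.1, gamma=0.9)
        assert delta[0] == pytest.approx(0.0)
        assert delta[1] == pytest.approx(0.9)
        assert M[0, 1] == pytest.approx(0.09)
        assert M[0, 0] == pytest.approx(1.0)

    def test_true_sr_is_fixed_point(self):
        # deterministic 3-cycle; M = (I - gamma T)^-1 gives zero SPE
        T = np.roll(np.eye(3), 1, axis=1)
        gamma = 0.9
        M = random_walk_sr(T, gamma)
        for s in range(3):
            delta = sr_td_update(M.copy(), s, (s + 1) % 3, False, 0.1, gamma)
            assert np.allclose(delta, 0, atol=1e-12)

    def test_converges_to_policy_sr_on_cycle(self):
        T = np.roll(np.eye(5), 1, axis=1)
        gamma = 0.9
        M = identity_sr(5)
        s = 0
        for _ in range(20_000):
            sr_td_update(M, s, (s + 1) % 5, False, 0.05, gamma)
            s = (s + 1) % 5
        target = random_walk_sr(T, gamma)
        assert np.linalg.norm(M - target) < 1e-2

    def test_terminal_transition_counts_terminal_once(self):
        M = identity_sr(2)
        for _ in range(500):
            sr_td_update(M, 0, 1, True, 0.2, 0.9)
        assert M[0, 1] == pytest.approx(0.9, abs=1e-6)
        assert M[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_row_sums_bounded(self, rng):
        gamma = 0.95
        M = identity_sr(6)
        for _ in range(2000):
            s, sn = rng.integers(6), rng.integers(6)
            sr_td_update(M, int(s), int(sn), False, 0.1, gamma)
            assert np.all(M.sum(axis=1) <= 1 / (1 - gamma) + 1e-9)


class TestRewardAndValue:
    def test_delta_rule_arithmetic(self):
        R = np.zeros(3)
        reward_update(R, 0, 1.0, 0.1)
        assert R[0] == pytest.approx(0.1)
        before = R.copy()
        reward_update(R, 0, before[0], 0.1)  # zero error
        assert np.allclose(R, before)

    def test_unlearning_decays_reward(self):
        R = np.array([0.8, 0.0])
        for _ in range(10):
            reward_update(R, 0, 0.0, 0.3)
        assert R[0] < 0.03

    def test_identity_sr_gives_value_equal_reward(self, rng):
        R = rng.random(4)
        assert np.allclose(v_hpc(np.eye(4), R), R)

    def test_value_matches_dot_product_oracle(self, rng):
        M, R = rng.random((5, 5)), rng.random(5)
        oracle = np.array([sum(M[s, t] * R[t] for t in range(5)) for s in range(5)])
        assert np.allclose(v_hpc(M, R), oracle)

    def test_reward_edit_revalues_predecessors_without_touching_sr(self):
        T = np.roll(np.eye(4), 1, axis=1)
        M = random_walk_sr(T, 0.9)
        M_before = M.copy()
        R = np.zeros(4)
        v0 = v_hpc(M, R)
        R[2] = 1.0
        v1 = v_hpc(M, R)
        assert np.all(v1 > v0)  # every state predicts s2 eventually
        assert np.array_equal(M, M_before)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            v_hpc(np.eye(3), np.zeros(4))


class TestLookaheadQ:
    def test_zero_values_give_reward_only(self):
        sr = TabularSR(3)
        sr.R[:] = 0.7
        model = np.array([[1, 2], [2, 0], [0, 1]])
        q = sr.action_values(0, model)
        sr.M[:] = 0  # V = 0 everywhere
        q0 = sr.action_values(0, model)
        assert np.allclose(q0, 0.7)
        assert q.shape == (2,)

    def test_probabilistic_model_matches_enumeration(self):
        graph = build_task_graph("daw_two_step", rng=np.random.default_rng(5))
        sr = TabularSR(graph.n_states, gamma=0.9)
        rng = np.random.default_rng(0)
        sr.M = rng.random((7, 7))
        sr.R = rng.random(7)
        V = sr.M @ sr.R
        q = sr.action_values(0, graph.P)
        oracle = [
            sr.R[0] + 0.9 * sum(graph.P[0, a, sp] * V[sp] for sp in range(7))
            for a in range(2)
        ]
        assert np.allclose(q, oracle)


class TestSuccessorFeatures:
    def test_identity_weights_return_features(self, rng):
        f = rng.random(5)
        assert np.allclose(sf_estimate(np.eye(5), f), f)

    def test_zero_features_zero_psi_and_no_update(self):
        W = np.eye(3) * 2
        before = W.copy()
        sf_td_update(W, np.zeros(3), np.ones(3), False, 0.1, 0.9)
        assert np.allclose(sf_estimate(before, np.zeros(3)), 0)
        assert np.array_equal(W, before)  # nothing eligible, no weight change

    def test_random_case_matches_brute_force(self, rng):
        W, f = rng.random((4, 4)), rng.random(4)
        oracle = np.array([sum(W[i, j] * f[i] for i in range(4)) for j in range(4)])
        assert np.allclose(sf_estimate(W, f), oracle)

    def test_one_hot_features_reduce_to_tabular_sr(self, rng):
        """The SF rule with one-hot features is exactly the tabular rule."""
        n, gamma, alpha = 5, 0.9, 0.1
        M = identity_sr(n)
        W = identity_sr(n)
        for _ in range(200):
            s, sn = int(rng.integers(n)), int(rng.integers(n))
            terminal = bool(rng.random() < 0.2)
            d_tab = sr_td_update(M, s, sn, terminal, alpha, gamma)
            f, fn = np.eye(n)[s], np.eye(n)[sn]
            d_sf = sf_td_update(W, f, fn, terminal, alpha, gamma)
            assert np.allclose(d_tab, d_sf, atol=1e-12)
        assert np.allclose(M, W.T @ np.eye(n) @ np.eye(n), atol=1e-12) or np.allclose(
            M, W, atol=1e-12
        )

    def test_feature_reward_one_hot_reduces_to_delta_rule(self):
        u = np.zeros(3)
        feature_reward_update(u, np.eye(3)[1], 1.0, 0.1)
        R = np.zeros(3)
        reward_update(R, 1, 1.0, 0.1)
        assert np.allclose(u, R)

    def test_value_zero_with_zero_u(self, rng):
        sf = SuccessorFeatures(4)
        assert sf.value(rng.random(4)) == 0.0

    def test_compound_training_transfers_value_without_blocking(self):
        """A cell co-active with a reward-predicting cell comes to predict
        it, so value survives removal of the first cell's driving input,
        even though the reward vector itself never changes."""
        gamma = 0.95
        sf = SuccessorFeatures(3, alpha_m=0.1, alpha_r=0.3, gamma=gamma, lam=0.9)
        fA1 = np.array([1.0, 0.0, 0.0])  # en-route cell driven by cue 1
        fA2 = np.array([0.0, 1.0, 0.0])  # goal cell (rewarded)
        fB = np.array([0.0, 0.0, 1.0])  # cue-2 cell, joins during compound
        for _ in range(8):  # initial learning: A1 alone precedes reward
            sf.reset_trace()
            sf.td_update(fA1, fA2, True)
            sf.learn_reward(fA2, 1.0)
        v_initial = sf.value(fA1)
        for _ in range(60):  # compound: B co-active with A1
            sf.reset_trace()
            sf.td_update(fA1 + fB, fA2, True)
            sf.learn_reward(fA2, 1.0)
        # no reward-prediction error, so the reward vector is unchanged ...
        assert sf.u[2] < 0.05 * sf.u[1]
        # ... yet B has come to predict the goal cell, preserving value
        assert sf.W[2, 1] > 0
        assert sf.value(fB) > 0.3 * v_initial


class TestDevaluation:
    def test_factor_one_is_identity(self, rng):
        R = rng.random(4)
        before = R.copy()
        devalue(R, 1.0)
        assert np.allclose(R, before)

    def test_full_devaluation_zeroes_value(self, rng):
        M = random_walk_sr(rng.dirichlet(np.ones(4), size=4), 0.9)
        R = rng.random(4)
        devalue(R, 0.0)
        assert np.allclose(v_hpc(M, R), 0)

    def test_factor_out_of_range(self):
        with pytest.raises(ValueError):
            devalue(np.ones(3), 1.5)
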