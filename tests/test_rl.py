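"""Reward table, action dynamics, replay/target mechanics, DQN vs oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytorl.rl import (DQNAgent, QNetwork, ReplayBuffer, RewardConfig,
                       RLConfig, TabularMDP, Transition, WeightVector,
                       apply_action, batch_reward, bellman_target,
                       compute_reward, dqn_update, n_actions, select_action,
                       solve_mdp_exact, train_dqn_on_mdp)

CFG = RewardConfig(minority_classes=frozenset({1}), n_classes=2)


class TestReward:
    @pytest.mark.parametrize("pred,true,expected", [
        (1, 1, 1.0),    # minority correct
        (0, 1, -1.0),   # minority missed
        (0, 0, 0.1),    # majority correct (delta)
        (1, 0, 0.0),    # majority missed
    ])
    def test_reward_table_exhaustive(self, pred, true, expected):
        assert compute_reward(pred, true, CFG) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            compute_reward(0, 5, CFG)

    def test_reward_ordering_enforced(self):
        with pytest.raises(ValueError, match="rewards must satisfy"):
            RewardConfig(frozenset({0}), 2, r_majority_correct=2.0)

    def test_minority_set_from_frequencies(self):
        cfg = RewardConfig.from_frequencies({0: 90, 1: 10})
        assert cfg.minority_classes == frozenset({1})

    @pytest.mark.parametrize("preds,labels,expected", [
        ([1, 1], [1, 1], 1.0),
        ([1, 0], [1, 1], 0.0),
        ([1, 0], [1, 0], 0.55),
    ])
    def test_batch_reward_means(self, preds, labels, expected):
        assert batch_reward(preds, labels, CFG) == pytest.approx(expected)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            batch_reward([], [], CFG)


class _FixedQNet:
    def __init__(self, row):
        self.row = np.asarray(row, float)

    def q_values(self, state):
        return self.row


class TestActionSelection:
    def test_greedy_argmax(self):
        rng = np.random.default_rng(0)
        assert select_action(_FixedQNet([0.1, 0.9, 0.2]), np.zeros(2), 0.0,
                             rng) == 1

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert select_action(_FixedQNet([0.5, 0.5]), np.zeros(2), 0.0, rng) == 0

    def test_full_exploration_is_uniform(self):
        rng = np.random.default_rng(42)
        n, draws = 4, 10_000
        counts = np.bincount([
            select_action(_FixedQNet([0, 0, 0, 1]), np.zeros(2), 1.0, rng,
                          n_act=n)
            for _ in range(draws)
        ], minlength=n)
        p = 1 / n
        sigma = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) < 3 * sigma)


class TestWeightActions:
    def test_noop_leaves_weights_unchanged(self):
        w = WeightVector.uniform(3)
        assert apply_action(w, 0).values == w.values

    def test_raise_action_arithmetic(self):
        """(1,1,1), raise class 2 by beta=1.5 -> (0.857, 0.857, 1.286)."""
        w = apply_action(WeightVector.uniform(3), action=1 + 2 * 2, beta=1.5)
        assert np.allclose(w.as_array(), [6 / 7, 6 / 7, 9 / 7], atol=1e-3)

    def test_repeated_raising_saturates_at_w_max(self):
        w = WeightVector.uniform(8)
        for _ in range(80):
            w = apply_action(w, 1, beta=1.2)
        assert w.values[0] == pytest.approx(w.w_max)

    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=1,
                    max_size=300),
           st.integers(min_value=2, max_value=5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariants_hold_after_any_action_stream(self, actions, c):
        w = WeightVector.uniform(c)
        for a in actions:
            w = apply_action(w, a % n_actions(c), beta=1.3)
            v = w.as_array()
            assert abs(v.mean() - 1.0) < 1e-9
            assert v.min() >= w.w_min - 1e-9
            assert v.max() <= w.w_max + 1e-9

    def test_out_of_range_action_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            apply_action(WeightVector.uniform(2), 5)


class TestReplayBuffer:
    def _t(self, i):
        return Transition(np.array([float(i)]), 0, 0.0, np.array([0.0]))

    def test_fifo_eviction_at_capacity(self):
        buf = ReplayBuffer(3)
        for i in range(5):
            buf.push(self._t(i))
        stored = [t.state[0] for t in buf]
        assert stored == [2.0, 3.0, 4.0]

    def test_samples_come_from_stored_transitions(self):
        buf = ReplayBuffer(10)
        for i in range(10):
            buf.push(self._t(i))
        rng = np.random.default_rng(0)
        batch = buf.sample(32, rng)
        assert all(0 <= t.state[0] < 10 for t in batch)


class TestBellmanAndUpdate:
    def test_gamma_zero_target_is_reward(self):
        net = QNetwork(2, 2, seed=0)
        assert bellman_target(0.3, np.zeros(2), net, 0.0) == pytest.approx(0.3)

    def test_terminal_target_is_reward(self):
        net = QNetwork(2, 2, seed=0)
        assert bellman_target(0.3, np.zeros(2), net, 0.9, terminal=True) \
            == pytest.approx(0.3)

    def test_target_arithmetic(self):
        class MaxTwo:
            def q_values(self, s):
                return np.array([2.0, 1.0])
        assert bellman_target(1.0, np.zeros(2), MaxTwo(), 0.9) \
            == pytest.approx(2.8)

    def test_zero_loss_fixed_point_leaves_parameters_unchanged(self):
        qnet = QNetwork(2, 2, seed=1)
        target = qnet.clone()
        s = np.array([0.3, -0.2])
        # gamma=0 and rewards equal to current Q -> targets == predictions
        batch = [Transition(s, a, float(qnet.q_values(s)[a]), s, terminal=True)
                 for a in (0, 1)]
        before = {k: v.copy() for k, v in qnet.state_dict().items()}
        loss = dqn_update(qnet, target, batch, gamma=0.0, lr=0.1)
        assert loss == pytest.approx(0.0, abs=1e-20)
        for k, v in qnet.state_dict().items():
            assert np.allclose(v, before[k])

    def test_loss_nonnegative(self):
        qnet = QNetwork(2, 2, seed=1)
        batch = [Transition(np.zeros(2), 0, 1.0, np.ones(2))]
        assert dqn_update(qnet, qnet.clone(), batch, 0.9, 1e-3) >= 0.0

    def test_target_network_changes_only_at_sync_steps(self):
        cfg = RLConfig(batch_size=4, replay_capacity=64, target_sync_period=10)
        agent = DQNAgent(state_dim=6, n_classes=2, cfg=cfg, seed=0)
        snapshots = []
        for step in range(1, 21):
            t = Transition(np.random.default_rng(step).normal(size=6), 0,
                           0.1, np.zeros(6))
            before = agent.target.state_dict()
            agent.observe(t)
            after = agent.target.state_dict()
            changed = any(not np.array_equal(before[k], after[k])
                          for k in before)
            snapshots.append((step, changed))
        for step, changed in snapshots:
            assert changed == (step % 10 == 0)


class TestValueIterationOracle:
    def test_single_state_gamma_zero(self):
        mdp = TabularMDP(((0, 0),), ((1.0, 0.0),))
        assert np.allclose(solve_mdp_exact(mdp, 0.0), [[1.0, 0.0]])

    def test_self_loop_geometric_series(self):
        mdp = TabularMDP(((0,),), ((1.0,),))
        assert solve_mdp_exact(mdp, 0.5).max() == pytest.approx(2.0, abs=1e-9)

    def test_bellman_residual_vanishes_on_random_mdp(self):
        rng = np.random.default_rng(0)
        t = tuple(tuple(rng.integers(0, 3, 2)) for _ in range(3))
        r = tuple(tuple(rng.normal(size=2)) for _ in range(3))
        mdp = TabularMDP(t, r)
        q = solve_mdp_exact(mdp, 0.9)
        resid = np.asarray(r) + 0.9 * q.max(1)[np.asarray(t)] - q
        assert np.abs(resid).max() <= 1e-9

    def test_gamma_one_rejected(self):
        with pytest.raises(ValueError):
            solve_mdp_exact(TabularMDP(((0,),), ((1.0,),)), 1.0)


class TestDQNAgainstOracle:
    def test_greedy_policy_matches_value_iteration(self):
        mdp = TabularMDP(((1, 0), (1, 1)), ((0.0, 0.5), (1.0, 0.0)))
        qstar = solve_mdp_exact(mdp, 0.9)
        qnet = train_dqn_on_mdp(mdp, 0.9, seed=1, steps=3000)
        eye = np.eye(mdp.n_states)
        qdqn = np.stack([qnet.q_values(eye[s]) for s in range(mdp.n_states)])
        assert np.array_equal(qdqn.argmax(1), qstar.argmax(1))

    def test_q_error_shrinks_with_training(self):
        mdp = TabularMDP(((0, 1), (0, 1)), ((0.2, 0.0), (0.0, 1.0)))
        qstar = solve_mdp_exact(mdp, 0.9)
        eye = np.eye(2)

        def err(steps):
            qnet = train_dqn_on_mdp(mdp, 0.9, seed=2, steps=steps)
            qdqn = np.stack([qnet.q_values(eye[s]) for s in range(2)])
            return np.abs(qdqn - qstar).max()

        assert err(3000) < err(300)
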