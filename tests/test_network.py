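import numpy as np
import pytest

from dpsepsis.network import QNetwork, double_q_target, huber, td_errors


def _toy_head():
    """Linear dueling head on a 1-dim input with hand-set V = 2, A = [1, -1]."""
    net = QNetwork(input_dim=1, n_actions=2, hidden_sizes=(), seed=0)
    net.theta[:] = 0.0
    w = net.weights()
    w["bv"][:] = 2.0
    w["ba"][:] = [1.0, -1.0]
    return net


class TestDuelingAggregation:
    def test_hand_set_streams(self):
        net = _toy_head()
        q = net.q_values(np.array([[0.0]]))
        np.testing.assert_allclose(q, [[3.0, 1.0]])

    def test_constant_advantage_collapses_to_value(self):
        net = _toy_head()
        net.weights()["ba"][:] = [4.0, 4.0]
        q = net.q_values(np.array([[0.0]]))
        np.testing.assert_allclose(q, [[2.0, 2.0]])

    def test_mean_q_equals_value_for_random_parameters(self):
        net = QNetwork(input_dim=6, n_actions=9, hidden_sizes=(12, 8), seed=3)
        X = np.random.default_rng(0).normal(size=(20, 6))
        q = net.q_values(X)
        v, _ = net.value_and_advantage(X)
        np.testing.assert_allclose(q.mean(axis=1), v, atol=1e-12)

    def test_mean_centering_invariance(self):
        """Adding a constant to every advantage leaves Q unchanged."""
        net = QNetwork(input_dim=4, n_actions=5, hidden_sizes=(7,), seed=1)
        X = np.random.default_rng(1).normal(size=(10, 4))
        q0 = net.q_values(X)
        net.weights()["ba"][:] += 13.7
        np.testing.assert_allclose(net.q_values(X), q0, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        net = QNetwork(input_dim=4, n_actions=3, hidden_sizes=())
        with pytest.raises(ValueError):
            net.q_values(np.zeros((2, 5)))


class TestPerExampleGrads:
    def test_against_finite_differences(self):
        net = QNetwork(input_dim=5, n_actions=4, hidden_sizes=(8, 6), seed=1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 5))
        acts = np.array([0, 2, 3])
        dL = rng.normal(size=3)
        G, _ = net.per_example_grads(X, acts, dL)
        eps = 1e-6
        num = np.zeros_like(G)
        for p in range(net.n_params):
            net.theta[p] += eps
            qp = net.q_values(X)[np.arange(3), acts]
            net.theta[p] -= 2 * eps
            qm = net.q_values(X)[np.arange(3), acts]
            net.theta[p] += eps
            num[:, p] = dL * (qp - qm) / (2 * eps)
        np.testing.assert_allclose(G, num, atol=1e-7)

    def test_fused_clipped_sum_matches_explicit_path(self):
        from dpsepsis.dp import clip_by_l2

        net = QNetwork(input_dim=7, n_actions=5, hidden_sizes=(9, 6), seed=2)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(11, 7))
        acts = rng.integers(0, 5, 11)
        dL = rng.normal(size=11) * 3
        G, _ = net.per_example_grads(X, acts, dL)
        slow = clip_by_l2(G, 0.7).sum(axis=0)
        fast = net.clipped_grad_sum(X, acts, dL, 0.7)
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestDoubleQTarget:
    def test_terminal_returns_bare_reward(self):
        t = double_q_target(np.array([-15.0]), np.array([True]),
                            np.zeros((1, 2)), np.zeros((1, 2)), 0.99)
        assert t[0] == -15.0

    def test_decoupled_selection_and_evaluation(self):
        q_online = np.array([[1.0, 3.0]])   # selects action 1
        q_target = np.array([[10.0, 2.0]])  # evaluates it at 2
        t = double_q_target(np.array([0.0]), np.array([False]), q_online, q_target, 0.99)
        assert t[0] == pytest.approx(1.98)

    def test_gamma_zero_is_myopic(self):
        r = np.array([1.0, -2.0])
        t = double_q_target(r, np.array([False, False]),
                            np.ones((2, 3)), np.ones((2, 3)) * 9, 0.0)
        np.testing.assert_array_equal(t, r)

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            double_q_target(np.zeros(1), np.zeros(1, bool), np.zeros((1, 2)),
                            np.zeros((1, 2)), 1.5)

    def test_ties_break_to_lowest_index(self):
        q_online = np.array([[5.0, 5.0, 5.0]])
        q_target = np.array([[7.0, 1.0, 3.0]])
        t = double_q_target(np.array([0.0]), np.array([False]), q_online, q_target, 1.0)
        assert t[0] == 7.0


class TestTdErrors:
    def test_fixed_point_and_sign_flip(self):
        net = QNetwork(input_dim=3, n_actions=2, hidden_sizes=(), seed=0)
        target = net.copy()
        X = np.eye(3)[:2]
        acts = np.array([0, 1])
        nxt = np.eye(3)[1:3]
        term = np.array([False, True])
        d_pos, tgt, q_sa, _ = td_errors(net, target, X, acts, np.array([0.0, 1.0]),
                                        nxt, term, 0.9)
        np.testing.assert_allclose(d_pos, tgt - q_sa)
        d_neg, _, _, _ = td_errors(net, target, X, acts, np.array([0.0, -1.0]),
                                   nxt, term, 0.9)
        assert d_neg[1] == pytest.approx(d_pos[1] - 2.0)  # linear in reward

    def test_huber_derivative_saturates(self):
        loss, grad = huber(np.array([0.5, 3.0, -3.0]))
        assert loss[0] == pytest.approx(0.125)
        np.testing.assert_array_equal(grad, [0.5, 1.0, -1.0])


class TestSyncAndSerialization:
    def test_sync_is_idempotent_copy(self):
        a = QNetwork(4, 3, (5,), seed=0)
        b = QNetwork(4, 3, (5,), seed=9)
        b.sync_from(a)
        np.testing.assert_array_equal(a.theta, b.theta)
        b.sync_from(a)
        np.testing.assert_array_equal(a.theta, b.theta)
        # after sync, double target equals the single-network target
        X = np.random.default_rng(0).normal(size=(4, 4))
        qa, qb = a.q_values(X), b.q_values(X)
        t_double = double_q_target(np.zeros(4), np.zeros(4, bool), qa, qb, 0.9)
        t_single = 0.9 * qa.max(axis=1)
        np.testing.assert_allclose(t_double, t_single)

    def test_checkpoint_round_trip(self, tmp_path):
        net = QNetwork(6, 4, (8,), seed=5)
        path = tmp_path / "model.npz"
        net.save(path)
        back = QNetwork.load(path)
        assert back.hidden_sizes == net.hidden_sizes
        X = np.random.default_rng(1).normal(size=(3, 6))
        np.testing.assert_array_equal(back.q_values(X), net.q_values(X))


class TestOverestimation:
    def test_double_target_below_single_max_target_on_noisy_values(self):
        """With independent noisy Q-tables, decoupled selection/evaluation
        is less optimistic on average than the single-table max."""
        rng = np.random.default_rng(0)
        single, double = [], []
        for _ in range(200):
            qa = rng.normal(0.0, 1.0, (1, 5))  # true values all zero
            qb = rng.normal(0.0, 1.0, (1, 5))
            r = np.zeros(1)
            live = np.array([False])  # terminal=False
            live = np.array([False])
            t_double = double_q_target(r, np.array([False]), qa, qb, 1.0)[0]
            t_single = qa.max()
            double.append(t_double)
            single.append(t_single)
        assert np.mean(double) < np.mean(single)
        assert np.mean(single) > 0.5   # max of 5 N(0,1) is strongly biased up
        assert abs(np.mean(double)) < 0.25  # decoupling removes most of it
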