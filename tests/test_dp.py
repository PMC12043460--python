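import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dpsepsis.accountant import PrivacyLedger
from dpsepsis.dp import (
    Adam,
    DPConfig,
    DPContractError,
    clip_by_l2,
    dp_step,
    noisy_lot_gradient,
)
from dpsepsis.network import QNetwork


class TestClipByL2:
    def test_below_threshold_unchanged(self):
        g = np.array([0.3, 0.4])  # norm 0.5
        np.testing.assert_array_equal(clip_by_l2(g, 1.0), g)

    def test_above_threshold_scaled_to_c(self):
        out = clip_by_l2(np.array([3.0, 4.0]), 1.0)
        np.testing.assert_allclose(out, [0.6, 0.8])
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_zero_vector(self):
        np.testing.assert_array_equal(clip_by_l2(np.zeros(5), 2.0), np.zeros(5))

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            clip_by_l2(np.array([1.0, np.inf]), 1.0)

    @given(
        g=arrays(np.float64, st.integers(1, 20),
                 elements=st.floats(-1e6, 1e6, allow_nan=False)),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=1000, deadline=None)
    def test_norm_bounded_and_direction_preserved(self, g, c):
        out = clip_by_l2(g, c)
        norm_in = np.linalg.norm(g)
        norm_out = np.linalg.norm(out)
        assert norm_out <= c * (1 + 1e-9)
        assert norm_out == pytest.approx(min(norm_in, c), rel=1e-9, abs=1e-12)
        if norm_in > 0:
            np.testing.assert_allclose(out / max(norm_out, 1e-300) * norm_in, g, rtol=1e-6, atol=1e-9)


class TestNoisyLotGradient:
    def _config(self, sigma, L=4, C=1.0):
        return DPConfig(clip_C=C, sigma=sigma, lot_size=L, q=0.1, delta=1e-6, total_steps=10)

    def test_sigma_zero_is_exact_mean(self):
        G = clip_by_l2(np.random.default_rng(0).normal(size=(4, 6)), 1.0)
        out = noisy_lot_gradient(G, self._config(0.0), np.random.default_rng(1))
        np.testing.assert_allclose(out, G.sum(axis=0) / 4)

    def test_unclipped_input_rejected(self):
        G = np.ones((2, 8))  # norms sqrt(8) > 1
        with pytest.raises(DPContractError):
            noisy_lot_gradient(G, self._config(1.0), np.random.default_rng(0))

    def test_seeded_determinism(self):
        G = clip_by_l2(np.random.default_rng(0).normal(size=(4, 6)), 1.0)
        cfg = self._config(2.0)
        a = noisy_lot_gradient(G, cfg, np.random.default_rng(7))
        b = noisy_lot_gradient(G, cfg, np.random.default_rng(7))
        c = noisy_lot_gradient(G, cfg, np.random.default_rng(8))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_noise_moments(self):
        """Monte-Carlo: mean within 4 SE, per-coordinate variance within 1%
        of sigma^2 C^2 / L^2 (noise on the sum, then averaged)."""
        sigma, C, L, dim = 2.0, 1.5, 8, 5
        G = clip_by_l2(np.random.default_rng(0).normal(size=(L, dim)), C)
        cfg = DPConfig(clip_C=C, sigma=sigma, lot_size=L, q=0.1, delta=1e-6, total_steps=10)
        rng = np.random.default_rng(42)
        draws = np.array([noisy_lot_gradient(G, cfg, rng) for _ in range(100_000)])
        expected_mean = G.sum(axis=0) / L
        expected_var = sigma**2 * C**2 / L**2
        se_mean = np.sqrt(expected_var / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - expected_mean) < 4 * se_mean)
        np.testing.assert_allclose(draws.var(axis=0), expected_var, rtol=0.01)


class TestDPStep:
    def _setup(self, sigma=0.0, n=6, with_ledger=False):
        net = QNetwork(input_dim=3, n_actions=2, hidden_sizes=(), seed=0)
        target = net.copy()
        rng = np.random.default_rng(1)
        states = rng.normal(size=(n, 3))
        cfg = DPConfig(clip_C=1.0, sigma=sigma, lot_size=n, q=0.5, delta=1e-6, total_steps=100)
        ledger = PrivacyLedger(q=0.5, sigma=sigma, delta=1e-6) if with_ledger else None
        batch = dict(
            states=states,
            actions=rng.integers(0, 2, n),
            rewards=rng.normal(size=n),
            next_states=rng.normal(size=(n, 3)),
            terminal=np.zeros(n, bool),
        )
        return net, target, cfg, ledger, batch

    def test_sigma_zero_reduces_to_plain_averaged_step(self):
        net, target, cfg, _, batch = self._setup(sigma=0.0)
        theta0 = net.theta.copy()
        opt = Adam(net.n_params, lr=0.1)
        dp_step(net, target, gamma=0.9, config=cfg, optimizer=opt,
                rng=np.random.default_rng(0), **batch)
        # replicate by hand: per-example grads, clip, average, Adam
        from dpsepsis.network import double_q_target, huber

        net2 = QNetwork(input_dim=3, n_actions=2, hidden_sizes=(), seed=0)
        net2.theta[:] = theta0
        tgt = double_q_target(batch["rewards"], batch["terminal"],
                              net2.q_values(batch["next_states"]),
                              target.q_values(batch["next_states"]), 0.9)
        q_sa = net2.q_values(batch["states"])[np.arange(6), batch["actions"]]
        _, dh = huber(tgt - q_sa)
        G, _ = net2.per_example_grads(batch["states"], batch["actions"], -dh)
        G = clip_by_l2(G, 1.0)
        opt2 = Adam(net2.n_params, lr=0.1)
        opt2.update(net2.theta, G.sum(axis=0) / 6)
        np.testing.assert_allclose(net.theta, net2.theta, atol=1e-12)

    def test_ledger_increments_exactly_once_per_call(self):
        net, target, cfg, ledger, batch = self._setup(sigma=1.0, with_ledger=True)
        opt = Adam(net.n_params)
        for k in range(3):
            dp_step(net, target, gamma=0.9, config=cfg, optimizer=opt,
                    rng=np.random.default_rng(k), ledger=ledger, **batch)
        assert ledger.steps == 3

    def test_ledger_mismatch_rejected(self):
        net, target, cfg, _, batch = self._setup(sigma=1.0)
        bad = PrivacyLedger(q=0.5, sigma=1.0, delta=1e-5)  # wrong delta
        with pytest.raises(DPContractError):
            dp_step(net, target, gamma=0.9, config=cfg,
                    optimizer=Adam(net.n_params), rng=np.random.default_rng(0),
                    ledger=bad, **batch)

    def test_empty_lot_still_consumes_privacy(self):
        net, target, cfg, ledger, _ = self._setup(sigma=1.0, with_ledger=True)
        out = dp_step(net, target, states=np.empty((0, 3)), actions=np.empty(0, int),
                      rewards=np.empty(0), next_states=np.empty((0, 3)),
                      terminal=np.empty(0, bool), gamma=0.9, config=cfg,
                      optimizer=Adam(net.n_params), rng=np.random.default_rng(0),
                      ledger=ledger)
        assert out.size == 0 and ledger.steps == 1


def test_noisy_descent_on_quadratic():
    """Averaged over seeds, small-noise DP steps still decrease a quadratic
    objective: sum_i 0.5 (theta - x_i)^2 via its per-example gradients."""
    rng_data = np.random.default_rng(0)
    X = rng_data.normal(1.0, 0.2, (32, 4))
    cfg = DPConfig(clip_C=1.0, sigma=0.5, lot_size=32, q=1.0, delta=1e-6, total_steps=200)
    final_losses = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        theta = np.zeros(4)
        opt = Adam(4, lr=0.05)
        for _ in range(200):
            G = clip_by_l2(theta[None, :] - X, cfg.clip_C)
            opt.update(theta, noisy_lot_gradient(G, cfg, rng))
        final_losses.append(0.5 * ((theta - X) ** 2).sum(axis=1).mean())
    initial = 0.5 * (X**2).sum(axis=1).mean()
    assert np.mean(final_losses) < 0.2 * initial
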