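"""Dueling double-DQN function approximator.

A small fully connected network with leaky-ReLU hidden layers and two output
streams: a scalar state value V(s) and per-action advantages A(s, a). The two
are combined with mean-centering,

    Q(s, a) = V(s) + A(s, a) - mean_a' A(s, a'),

which fixes the V/A decomposition ambiguity. Parameters live in one flat
vector so the differentially private optimizer can clip and perturb the full
per-example gradient with a single global L2 norm.

All gradient code is written by hand because the private training step needs
*per-example* gradients (one flattened gradient row per transition in the
lot), which autodiff frameworks do not expose cheaply.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


class QNetwork:
    """MLP with a dueling head over a flat parameter vector.

    ``hidden_sizes=()`` gives linear value/advantage streams directly on the
    input — with one-hot states this is an exactly tabular Q-function, used
    by the small-MDP convergence tests.
    """

    def __init__(
        self,
        input_dim: int,
        n_actions: int = 25,
        hidden_sizes: tuple[int, ...] = (128, 128),
        leak: float = 0.01,
        seed: int | None = None,
        init_scale: float | None = None,
    ) -> None:
        self.input_dim = input_dim
        self.n_actions = n_actions
        self.hidden_sizes = tuple(hidden_sizes)
        self.leak = leak

        # flat parameter layout: hidden (W, b) pairs, then value head, then
        # advantage head, all reading the last hidden layer (or the input)
        dims = [input_dim, *self.hidden_sizes]
        self._slices: list[tuple[slice, tuple[int, ...]]] = []
        offset = 0

        def alloc(shape):
            nonlocal offset
            size = int(np.prod(shape))
            sl = slice(offset, offset + size)
            offset += size
            self._slices.append((sl, shape))
            return sl

        self._w_slices = []
        self._b_slices = []
        for i in range(len(self.hidden_sizes)):
            self._w_slices.append(alloc((dims[i], dims[i + 1])))
            self._b_slices.append(alloc((dims[i + 1],)))
        last = dims[-1]
        self._wv = alloc((last, 1))
        self._bv = alloc((1,))
        self._wa = alloc((last, n_actions))
        self._ba = alloc((n_actions,))
        self.n_params = offset

        rng = np.random.default_rng(seed)
        self.theta = np.zeros(self.n_params)
        for i, sl in enumerate(self._w_slices):
            fan_in = dims[i]
            s = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
            self.theta[sl] = rng.normal(0.0, s, sl.stop - sl.start)
        for sl in (self._wv, self._wa):
            fan_in = last
            s = init_scale if init_scale is not None else np.sqrt(1.0 / fan_in)
            self.theta[sl] = rng.normal(0.0, s, sl.stop - sl.start)

    # -- parameter views -----------------------------------------------------
    def _get(self, sl: slice, shape) -> np.ndarray:
        return self.theta[sl].reshape(shape)

    def weights(self) -> dict:
        dims = [self.input_dim, *self.hidden_sizes]
        out = {}
        for i, (wsl, bsl) in enumerate(zip(self._w_slices, self._b_slices)):
            out[f"W{i}"] = self._get(wsl, (dims[i], dims[i + 1]))
            out[f"b{i}"] = self._get(bsl, (dims[i + 1],))
        last = dims[-1]
        out["Wv"] = self._get(self._wv, (last, 1))
        out["bv"] = self._get(self._bv, (1,))
        out["Wa"] = self._get(self._wa, (last, self.n_actions))
        out["ba"] = self._get(self._ba, (self.n_actions,))
        return out

    # -- forward -------------------------------------------------------------
    def _forward(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected states with {self.input_dim} features, got {X.shape[1]}")
        w = self.weights()
        h = X
        pre_acts = []
        acts = [h]
        for i in range(len(self.hidden_sizes)):
            z = h @ w[f"W{i}"] + w[f"b{i}"]
            pre_acts.append(z)
            h = np.where(z > 0, z, self.leak * z)
            acts.append(h)
        V = h @ w["Wv"] + w["bv"]          # (n, 1)
        A = h @ w["Wa"] + w["ba"]          # (n, k)
        Q = V + A - A.mean(axis=1, keepdims=True)
        return Q, V, A, acts, pre_acts

    def q_values(self, X: np.ndarray) -> np.ndarray:
        """Q(s, a) for every action; shape (n_states, n_actions)."""
        return self._forward(X)[0]

    def value_and_advantage(self, X: np.ndarray):
        _, V, A, _, _ = self._forward(X)
        return V[:, 0], A

    # -- per-example gradients ----------------------------------------------
    def per_example_grads(
        self, X: np.ndarray, actions: np.ndarray, dL_dQa: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Gradient of sum_i L_i w.r.t. theta, one flattened row per example.

        ``dL_dQa[i]`` is dL_i/dQ(s_i, a_i) for the selected action a_i.
        Returns (G, q_sa) with G of shape (n, n_params).
        """
        X = np.asarray(X, dtype=float)
        actions = np.asarray(actions, dtype=np.int64)
        dL_dQa = np.asarray(dL_dQa, dtype=float)
        n = X.shape[0]
        Q, V, A, acts, pre_acts = self._forward(X)
        q_sa = Q[np.arange(n), actions]

        w = self.weights()
        k = self.n_actions
        G = np.zeros((n, self.n_params))

        # dQ_a/dV = 1 ; dQ_a/dA_j = 1[j = a] - 1/k
        dV = dL_dQa[:, None]                       # (n, 1)
        dA = np.full((n, k), -1.0 / k) * dL_dQa[:, None]
        dA[np.arange(n), actions] += dL_dQa

        h = acts[-1]
        G[:, self._wv] = (h * dV).reshape(n, -1)   # outer product h_i * dV_i
        G[:, self._bv] = dV
        G[:, self._wa] = np.einsum("ni,nj->nij", h, dA).reshape(n, -1)
        G[:, self._ba] = dA

        dh = dV @ w["Wv"].T + dA @ w["Wa"].T
        for i in reversed(range(len(self.hidden_sizes))):
            z = pre_acts[i]
            dz = dh * np.where(z > 0, 1.0, self.leak)
            a_prev = acts[i]
            G[:, self._w_slices[i]] = np.einsum("ni,nj->nij", a_prev, dz).reshape(n, -1)
            G[:, self._b_slices[i]] = dz
            dh = dz @ w[f"W{i}"].T
        return G, q_sa

    def clipped_grad_sum(
        self, X: np.ndarray, actions: np.ndarray, dL_dQa: np.ndarray, clip_C: float
    ) -> np.ndarray:
        """Sum of per-example gradients after L2 clipping at ``clip_C``.

        Mathematically identical to clipping the rows of
        :meth:`per_example_grads` and summing, but never materializes the
        (n, n_params) matrix: per-example norms factor over layers as
        ||a_prev||^2 * ||dz||^2 for weights plus ||dz||^2 for biases, and the
        clipped sum is then a weighted matrix product.
        """
        X = np.asarray(X, dtype=float)
        actions = np.asarray(actions, dtype=np.int64)
        dL_dQa = np.asarray(dL_dQa, dtype=float)
        n = X.shape[0]
        _, _, _, acts, pre_acts = self._forward(X)
        w = self.weights()
        k = self.n_actions

        dV = dL_dQa[:, None]
        dA = np.full((n, k), -1.0 / k) * dL_dQa[:, None]
        dA[np.arange(n), actions] += dL_dQa

        # backward pass collecting (a_prev, dz) factor pairs per layer
        factors: list[tuple[np.ndarray, np.ndarray, slice, slice]] = [
            (acts[-1], dV, self._wv, self._bv),
            (acts[-1], dA, self._wa, self._ba),
        ]
        dh = dV @ w["Wv"].T + dA @ w["Wa"].T
        for i in reversed(range(len(self.hidden_sizes))):
            z = pre_acts[i]
            dz = dh * np.where(z > 0, 1.0, self.leak)
            factors.append((acts[i], dz, self._w_slices[i], self._b_slices[i]))
            dh = dz @ w[f"W{i}"].T

        sq_norms = np.zeros(n)
        for a_prev, dz, _, _ in factors:
            dz_sq = np.einsum("nj,nj->n", dz, dz)
            a_sq = np.einsum("ni,ni->n", a_prev, a_prev)
            sq_norms += dz_sq * (a_sq + 1.0)  # weight block + bias block
        scale = 1.0 / np.maximum(1.0, np.sqrt(sq_norms) / clip_C)

        out = np.zeros(self.n_params)
        for a_prev, dz, wsl, bsl in factors:
            dz_s = dz * scale[:, None]
            out[wsl] = (a_prev.T @ dz_s).reshape(-1)
            out[bsl] = dz_s.sum(axis=0)
        return out

    # -- target-network plumbing ----------------------------------------------
    def copy(self) -> "QNetwork":
        clone = QNetwork(
            self.input_dim, self.n_actions, self.hidden_sizes, leak=self.leak, seed=0
        )
        clone.theta = self.theta.copy()
        return clone

    def sync_from(self, other: "QNetwork") -> None:
        """Hard target sync: copy the online parameters. Idempotent."""
        self.theta[:] = other.theta

    # -- serialization ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        spec = {
            "input_dim": self.input_dim,
            "n_actions": self.n_actions,
            "hidden_sizes": list(self.hidden_sizes),
            "leak": self.leak,
        }
        np.savez(path, theta=self.theta, spec=json.dumps(spec))

    @classmethod
    def load(cls, path: str | Path) -> "QNetwork":
        with np.load(path, allow_pickle=False) as data:
            spec = json.loads(str(data["spec"]))
            net = cls(
                spec["input_dim"],
                spec["n_actions"],
                tuple(spec["hidden_sizes"]),
                leak=spec["leak"],
                seed=0,
            )
            net.theta = data["theta"].copy()
        return net


def double_q_target(
    rewards: np.ndarray,
    terminal: np.ndarray,
    q_next_online: np.ndarray,
    q_next_target: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Double-DQN bootstrap target.

    The bootstrap action is selected by the online network and evaluated by
    the target network: r + gamma * Q_target(s', argmax_a Q_online(s', a)).
    Terminal transitions return the bare reward. Argmax ties break toward the
    lowest action index.
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    rewards = np.asarray(rewards, dtype=float)
    terminal = np.asarray(terminal, dtype=bool)
    targets = rewards.copy()
    live = ~terminal
    if np.any(live):
        a_star = np.argmax(q_next_online[live], axis=1)  # lowest index on ties
        targets[live] += gamma * q_next_target[live, a_star]
    return targets


def huber(delta: np.ndarray, kappa: float = 1.0):
    """Huber loss and its derivative w.r.t. delta."""
    delta = np.asarray(delta, dtype=float)
    a = np.abs(delta)
    loss = np.where(a <= kappa, 0.5 * delta**2, kappa * (a - 0.5 * kappa))
    grad = np.clip(delta, -kappa, kappa)
    return loss, grad


def td_errors(
    online: QNetwork,
    target: QNetwork,
    states: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    next_states: np.ndarray,
    terminal: np.ndarray,
    gamma: float,
):
    """Per-transition TD errors delta_i = target_i - Q_online(s_i, a_i).

    Returns (delta, targets, q_sa, per-example Huber losses).
    """
    q_next_online = online.q_values(next_states)
    q_next_target = target.q_values(next_states)
    targets = double_q_target(rewards, terminal, q_next_online, q_next_target, gamma)
    q = online.q_values(states)
    q_sa = q[np.arange(len(actions)), np.asarray(actions, dtype=np.int64)]
    delta = targets - q_sa
    loss, _ = huber(delta)
    return delta, targets, q_sa, loss
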