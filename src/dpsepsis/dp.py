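"""Differentially private gradient step.

One private update processes a lot of transitions: per-example gradients of
the (importance-weighted) Huber TD loss are clipped to L2 norm C, summed,
perturbed with independent Gaussian noise N(0, sigma^2 C^2 I), averaged over
the expected lot size L, and applied through Adam. Under add/remove-one
adjacency the clipped sum has L2 sensitivity C, matching the subsampled
Gaussian analysis of the accountant; Adam and the target network only ever
see the noisy gradient, so everything downstream is post-processing.

Importance weights are capped at 1 *before* clipping so prioritized replay
cannot inflate the sensitivity bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accountant import PrivacyLedger
from .network import QNetwork, double_q_target, huber


class DPContractError(RuntimeError):
    """A privacy-relevant precondition was violated."""


@dataclass
class DPConfig:
    """Parameters of the private optimizer.

    sigma = 0 disables noise (and accounting): the step reduces exactly to a
    clipped, averaged non-private gradient step.
    """

    clip_C: float = 1.0
    sigma: float = 0.0
    lot_size: int = 64
    q: float = 0.01          # Poisson sampling rate, lot_size / N
    delta: float = 1e-6
    total_steps: int = 3000

    def __post_init__(self) -> None:
        if self.clip_C <= 0:
            raise ValueError("clip_C must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.lot_size < 1 or self.total_steps < 1:
            raise ValueError("lot_size and total_steps must be positive")


def clip_by_l2(gradients: np.ndarray, clip_C: float) -> np.ndarray:
    """Scale gradient vectors to L2 norm at most ``clip_C``: g / max(1, |g|/C).

    Accepts a single vector or a (n, p) stack of per-example gradients;
    direction is preserved, vectors already inside the ball are unchanged.
    """
    g = np.asarray(gradients, dtype=float)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient entries")
    if clip_C <= 0:
        raise ValueError("clip_C must be positive")
    if g.ndim == 1:
        norm = np.linalg.norm(g)
        return g / max(1.0, norm / clip_C)
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    return g / np.maximum(1.0, norms / clip_C)


def noisy_lot_gradient(
    per_example_grads: np.ndarray,
    config: DPConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(sum_i g_i + N(0, sigma^2 C^2 I)) / L for already-clipped gradients.

    Raises :class:`DPContractError` if any input row exceeds the clipping
    threshold — noise calibrated to sensitivity C is meaningless otherwise.
    """
    G = np.asarray(per_example_grads, dtype=float)
    if G.ndim != 2:
        raise ValueError("per_example_grads must be (n_examples, n_params)")
    norms = np.linalg.norm(G, axis=1)
    if np.any(norms > config.clip_C * (1 + 1e-9) + 1e-12):
        raise DPContractError("per-example gradient exceeds the clipping threshold")
    summed = G.sum(axis=0)
    if config.sigma > 0:
        summed = summed + rng.normal(0.0, config.sigma * config.clip_C, G.shape[1])
    return summed / config.lot_size


class Adam:
    """Adam over a flat parameter vector (operates on the noisy gradient only)."""

    def __init__(self, n_params: int, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def update(self, theta: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        theta -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def dp_step(
    network: QNetwork,
    target: QNetwork,
    states: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    next_states: np.ndarray,
    terminal: np.ndarray,
    gamma: float,
    config: DPConfig,
    optimizer: Adam,
    rng: np.random.Generator,
    ledger: PrivacyLedger | None = None,
    weights: np.ndarray | None = None,
    weight_decay: float = 0.0,
    target_clip: float | None = None,
) -> np.ndarray:
    """One (possibly private) optimizer update on a lot of transitions.

    Returns the per-transition TD errors (for priority updates). If a ledger
    is supplied its step count advances by exactly one; this function is the
    only writer of the ledger, so privacy consumption is confined here.
    """
    if ledger is not None:
        if abs(ledger.delta - config.delta) > 1e-15:
            raise DPContractError("ledger delta does not match DPConfig delta")
        if abs(ledger.sigma - config.sigma) > 1e-12 or abs(ledger.q - config.q) > 1e-12:
            raise DPContractError("ledger (q, sigma) does not match DPConfig")

    n = len(states)
    if n == 0:
        # Empty Poisson lot: the mechanism still releases (pure noise) and
        # the step still consumes privacy.
        grad = np.zeros(network.n_params)
        if config.sigma > 0:
            grad = rng.normal(0.0, config.sigma * config.clip_C, network.n_params) / config.lot_size
        if weight_decay:
            grad = grad + weight_decay * network.theta
        optimizer.update(network.theta, grad)
        if ledger is not None:
            ledger.record_step()
        return np.empty(0)

    q_next_online = network.q_values(next_states)
    q_next_target = target.q_values(next_states)
    targets = double_q_target(rewards, terminal, q_next_online, q_next_target, gamma)
    if target_clip is not None:
        # sparse +-R terminal rewards bound every return by R, so bootstrap
        # targets outside [-R, R] are necessarily overestimation artifacts
        targets = np.clip(targets, -target_clip, target_clip)

    if weights is None:
        w = np.ones(n)
    else:
        w = np.minimum(np.asarray(weights, dtype=float), 1.0)  # cap: sensitivity stays C

    # dL_i/dQ(s_i, a_i) for weighted Huber loss w_i * huber(target_i - q_i)
    q_sa_pre = network.q_values(states)[np.arange(n), np.asarray(actions, np.int64)]
    delta = targets - q_sa_pre
    _, dhuber = huber(delta)
    dL_dQa = -w * dhuber

    # fused clip-and-sum (identical to clipping per_example_grads rows);
    # noise is then added to the sum and the result averaged over L
    summed = network.clipped_grad_sum(states, actions, dL_dQa, config.clip_C)
    if config.sigma > 0:
        summed = summed + rng.normal(0.0, config.sigma * config.clip_C, summed.size)
    grad = summed / config.lot_size
    if weight_decay:
        # L2 shrinkage on the (already released) parameters: post-processing
        grad = grad + weight_decay * network.theta
    optimizer.update(network.theta, grad)
    if ledger is not None:
        ledger.record_step()
    return delta
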