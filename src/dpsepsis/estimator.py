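"""Offline DP-DQN trainer as a scikit-learn style estimator.

``DPDQNPolicy.fit(transitions)`` trains a dueling double-DQN on an offline
transition set by sampled lots; ``predict(states)`` returns greedy flat
actions in 0..24. With ``sigma > 0`` every gradient step is privatized
(per-example clipping at C, Gaussian noise sigma*C on the summed gradient)
and a moments-accountant ledger tracks the spent (epsilon, delta); with
``sigma = 0`` training is plain (non-private) dueling double-DQN and the
reported budget is epsilon = inf.

Replay modes
------------
* Non-private: classic proportional prioritized replay (sum-tree sampling
  with importance weights, beta annealed to 1), or uniform replay when
  ``use_per=False``.
* Private: lots are Poisson-subsampled at rate q = lot_size / N, which is
  what the accountant's amplification analysis assumes. Prioritization, if
  enabled, is applied as per-example loss weights (normalized priority^alpha,
  capped at 1) inside the Poisson lot, so the sensitivity bound C survives.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from .accountant import PrivacyLedger
from .dataset import TransitionSet
from .dp import Adam, DPConfig, DPContractError, dp_step
from .evaluation import LearningCurve, estimated_mortality
from .network import QNetwork
from .replay import PriorityBuffer


class DPDQNPolicy(BaseEstimator):
    """Dueling double deep Q-network trained by (optionally private) SGD.

    Parameters
    ----------
    hidden_sizes : widths of the shared hidden layers; ``()`` is linear/tabular.
    gamma : MDP discount factor.
    learning_rate : Adam step size on the (noisy) averaged gradient.
    n_steps : number of gradient steps (lots) to train for.
    lot_size : examples per lot; under DP this is the *expected* Poisson lot.
    target_sync_period : hard target-network sync interval in steps.
    clip_C : per-example L2 gradient clipping threshold.
    sigma : DP noise multiplier; 0 disables privacy.
    delta : DP delta target for the ledger.
    epsilon_budget : optional cap; training stops early once the accountant
        epsilon would exceed it.
    use_per : prioritized replay (see module docstring for the DP variant).
    per_alpha, per_beta0, per_eps : standard PER constants; beta anneals
        linearly from per_beta0 to 1 over training.
    eval_period : gradient steps between held-out evaluations (one
        evaluation = one "episode" of the learning curve).
    weight_decay : L2 shrinkage on all parameters, applied to the released
        (noisy) gradient. Shrinking the advantage stream toward zero is the
        main stabilizer against overestimation drift in this offline
        setting: with sparse terminal rewards the bootstrap max otherwise
        inflates poorly supported actions until the greedy policy collapses
        onto them.
    target_clip : clamp bootstrap targets to [-target_clip, +target_clip];
        with +-15 terminal-only rewards every true return lies in [-15, 15],
        so clipped mass is pure overestimation. None disables.
    tail_average_frac : fraction of scheduled steps over which the final
        parameters are averaged (iterate averaging; the greedy argmax is
        sensitive to iterate noise).
    lr_decay, lr_decay_at : learning-rate multiplier applied at the given
        fraction of training.
    random_state : seed for all randomness (init, sampling, noise).

    Attributes
    ----------
    network_, target_network_ : fitted online and target Q-networks.
    ledger_ : PrivacyLedger (None when sigma = 0).
    epsilon_ : certified epsilon at the end of training (inf when sigma = 0).
    learning_curve_ : held-out survival-rate curve (empty without eval data).
    n_steps_run_ : gradient steps actually taken (early stop may truncate).
    """

    def __init__(
        self,
        n_actions: int = 25,
        hidden_sizes: tuple[int, ...] = (128, 128),
        gamma: float = 0.99,
        learning_rate: float = 1e-3,
        n_steps: int = 3000,
        lot_size: int = 64,
        target_sync_period: int = 1000,
        clip_C: float = 1.0,
        sigma: float = 0.0,
        delta: float = 1e-6,
        epsilon_budget: float | None = None,
        use_per: bool = True,
        per_alpha: float = 0.6,
        per_beta0: float = 0.4,
        per_eps: float = 0.01,
        eval_period: int = 500,
        weight_decay: float = 1e-3,
        target_clip: float | None = 15.0,
        tail_average_frac: float = 0.25,
        lr_decay: float = 0.2,
        lr_decay_at: float = 0.6,
        random_state: int | None = None,
    ) -> None:
        self.n_actions = n_actions
        self.hidden_sizes = hidden_sizes
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.n_steps = n_steps
        self.lot_size = lot_size
        self.target_sync_period = target_sync_period
        self.clip_C = clip_C
        self.sigma = sigma
        self.delta = delta
        self.epsilon_budget = epsilon_budget
        self.use_per = use_per
        self.per_alpha = per_alpha
        self.per_beta0 = per_beta0
        self.per_eps = per_eps
        self.eval_period = eval_period
        self.weight_decay = weight_decay
        self.target_clip = target_clip
        self.tail_average_frac = tail_average_frac
        self.lr_decay = lr_decay
        self.lr_decay_at = lr_decay_at
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, transitions: TransitionSet, eval_transitions: TransitionSet | None = None):
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")
        n = len(transitions)
        if n < self.lot_size:
            raise ValueError("fewer transitions than lot_size")
        rng = np.random.default_rng(self.random_state)
        d = transitions.n_features
        private = self.sigma > 0
        q = self.lot_size / n

        self.network_ = QNetwork(
            d, n_actions=self.n_actions, hidden_sizes=tuple(self.hidden_sizes),
            seed=int(rng.integers(2**31)),
        )
        self.target_network_ = self.network_.copy()
        optimizer = Adam(self.network_.n_params, lr=self.learning_rate)

        dp_config = DPConfig(
            clip_C=self.clip_C, sigma=self.sigma, lot_size=self.lot_size,
            q=q, delta=self.delta, total_steps=self.n_steps,
        )
        self.ledger_ = PrivacyLedger(q=q, sigma=self.sigma, delta=self.delta) if private else None

        if private and self.epsilon_budget is not None:
            probe = PrivacyLedger(q=q, sigma=self.sigma, delta=self.delta)
            probe.record_step()
            if probe.epsilon() > self.epsilon_budget:
                raise DPContractError(
                    "sigma too small: a single step already exceeds the epsilon budget"
                )

        # Priorities over the whole offline set, indexed 0..n-1.
        buffer = PriorityBuffer(
            capacity=n, alpha=self.per_alpha, beta=self.per_beta0,
            epsilon_priority=self.per_eps, uniform=not self.use_per,
        )
        for i in range(n):
            buffer.add(i)

        episodes: list[int] = []
        survival: list[float] = []
        steps_run = 0
        # Iterate averaging over the training tail: the averaged parameters
        # are far less noisy than the last iterate, which matters because
        # greedy argmax is sensitive to small Q perturbations. Averaging
        # noisy iterates is post-processing and consumes no extra privacy.
        avg_start = int(self.n_steps * (1.0 - self.tail_average_frac)) + 1
        theta_avg = np.zeros_like(self.network_.theta)
        n_avg = 0
        decay_step = int(self.n_steps * self.lr_decay_at)
        for step in range(1, self.n_steps + 1):
            if step == decay_step:
                optimizer.lr = self.learning_rate * self.lr_decay
            buffer.beta = self.per_beta0 + (1.0 - self.per_beta0) * step / self.n_steps

            if private:
                idx = np.flatnonzero(rng.random(n) < q)
                slots = idx  # buffer slot i holds transition i
                if self.use_per and idx.size:
                    prios = np.array([buffer.tree.get(int(s)) for s in slots])
                    weights = prios / prios.max() if prios.max() > 0 else np.ones(idx.size)
                else:
                    weights = None
            else:
                items, slots, weights = buffer.sample(self.lot_size, rng)
                idx = np.asarray(items, dtype=np.int64)

            delta_td = dp_step(
                self.network_, self.target_network_,
                transitions.states[idx], transitions.actions[idx],
                transitions.rewards[idx], transitions.next_states[idx],
                transitions.terminal[idx], self.gamma,
                dp_config, optimizer, rng,
                ledger=self.ledger_, weights=weights,
                weight_decay=self.weight_decay, target_clip=self.target_clip,
            )
            for s, e in zip(np.atleast_1d(slots), np.atleast_1d(delta_td)):
                buffer.update_priority(int(s), float(e))
            steps_run = step

            if step >= avg_start:
                theta_avg += self.network_.theta
                n_avg += 1

            if step % self.target_sync_period == 0:
                self.target_network_.sync_from(self.network_)

            if eval_transitions is not None and step % self.eval_period == 0:
                episodes.append(len(episodes) + 1)
                survival.append(self._survival_rate(eval_transitions))

            if (
                private
                and self.epsilon_budget is not None
                and step % 25 == 0
                and self.ledger_.epsilon() >= self.epsilon_budget
            ):
                break

        if n_avg > 0:
            self.network_.theta = theta_avg / n_avg
            self.target_network_.sync_from(self.network_)
        self.n_steps_run_ = steps_run
        self.epsilon_ = self.ledger_.epsilon() if private else math.inf
        self.learning_curve_ = LearningCurve(np.array(episodes), np.array(survival))
        self.n_features_in_ = d
        return self

    def _survival_rate(self, ts: TransitionSet) -> float:
        report = estimated_mortality(self.predict(ts.states), ts)
        if not report.overall.defined:
            # no agreement anywhere: count it as zero observed survival
            return 0.0
        return 1.0 - report.overall.mortality

    # ------------------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Greedy flat actions (0..24); argmax ties break to the lowest index."""
        self._check_fitted()
        return np.argmax(self.network_.q_values(X), axis=1)

    def predict_q(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self.network_.q_values(X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("DPDQNPolicy is not fitted; call fit first")
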