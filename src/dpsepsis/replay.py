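"""Prioritized experience replay over the offline transition set.

Priorities are (|TD error| + eps)^alpha stored in a sum-tree; sampling is
proportional to priority with (N * P(i))^-beta importance weights normalized
by the lot maximum. A uniform mode (``uniform=True``) disables
prioritization entirely, since low-privacy-budget training runs are
configured without it.
"""

from __future__ import annotations

import numpy as np


class SumTree:
    """Binary sum-tree over ``capacity`` leaves; internal nodes hold child sums."""

    def __init__(self, capacity: int) -> None:
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self.nodes = np.zeros(2 * capacity - 1)

    @property
    def total(self) -> float:
        return float(self.nodes[0])

    def set(self, leaf: int, value: float) -> None:
        if not 0 <= leaf < self.capacity:
            raise IndexError("leaf out of range")
        i = leaf + self.capacity - 1
        delta = value - self.nodes[i]
        while True:
            self.nodes[i] += delta
            if i == 0:
                break
            i = (i - 1) // 2

    def get(self, leaf: int) -> float:
        return float(self.nodes[leaf + self.capacity - 1])

    def find(self, value: float) -> int:
        """Leaf whose cumulative-priority interval contains ``value``."""
        i = 0
        while i < self.capacity - 1:
            left = 2 * i + 1
            if value <= self.nodes[left]:
                i = left
            else:
                value -= self.nodes[left]
                i = left + 1
        return i - (self.capacity - 1)

    def consistent(self, atol: float = 1e-8) -> bool:
        """Every internal node equals the sum of its children."""
        for i in range(self.capacity - 1):
            left = 2 * i + 1
            right = left + 1
            s = self.nodes[left] + (self.nodes[right] if right < self.nodes.size else 0.0)
            if not np.isclose(self.nodes[i], s, atol=atol, rtol=1e-9):
                return False
        return True


class PriorityBuffer:
    """Replay buffer with proportional prioritization.

    Stores opaque items (here: indices into a TransitionSet). New items enter
    with the current maximum priority so every transition is sampled at least
    once before its priority is informed by a TD error.
    """

    def __init__(
        self,
        capacity: int,
        alpha: float = 0.6,
        beta: float = 0.4,
        epsilon_priority: float = 0.01,
        uniform: bool = False,
    ) -> None:
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if epsilon_priority <= 0:
            raise ValueError("epsilon_priority must be > 0")
        self.capacity = capacity
        self.alpha = alpha
        self.beta = beta
        self.epsilon_priority = epsilon_priority
        self.uniform = uniform
        self.tree = SumTree(capacity)
        self.items: list = [None] * capacity
        self.size = 0
        self._next = 0  # ring position; oldest evicted when full
        self._max_priority = 1.0

    def __len__(self) -> int:
        return self.size

    def _priority_from_td(self, td_error: float) -> float:
        if not np.isfinite(td_error):
            raise ValueError("td_error must be finite")
        return float((abs(td_error) + self.epsilon_priority) ** self.alpha)

    def add(self, item, priority: float | None = None) -> int:
        """Insert an item; returns its slot. Oldest item is evicted when full."""
        if priority is None:
            priority = self._max_priority
        if priority <= 0 or not np.isfinite(priority):
            raise ValueError("priority must be positive and finite")
        slot = self._next
        self.items[slot] = item
        self.tree.set(slot, priority)
        self._max_priority = max(self._max_priority, priority)
        self._next = (self._next + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)
        return slot

    def update_priority(self, slot: int, td_error: float) -> None:
        p = self._priority_from_td(td_error)
        self.tree.set(slot, p)
        self._max_priority = max(self._max_priority, p)

    def priorities(self) -> np.ndarray:
        return np.array([self.tree.get(i) for i in range(self.size)])

    def sample(self, lot_size: int, rng: np.random.Generator):
        """Sample ``lot_size`` items with replacement.

        Returns (items, slots, importance_weights); weights are
        (N * P(i))^-beta normalized by the lot maximum (all ones in uniform
        mode or at beta = 0).
        """
        if self.size == 0:
            raise ValueError("cannot sample from an empty buffer")
        if lot_size > self.size:
            raise ValueError("lot_size exceeds buffer size")
        if self.uniform:
            slots = rng.integers(0, self.size, lot_size)
            weights = np.ones(lot_size)
        else:
            total = self.tree.total
            # stratified proportional sampling: one draw per equal segment
            bounds = total * (np.arange(lot_size) + rng.random(lot_size)) / lot_size
            slots = np.array([self.tree.find(v) for v in bounds])
            probs = np.array([self.tree.get(s) for s in slots]) / total
            weights = (self.size * np.maximum(probs, 1e-12)) ** (-self.beta)
            weights = weights / weights.max()
        items = [self.items[s] for s in slots]
        return items, slots, weights
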