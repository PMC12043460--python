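import numpy as np
import pytest

from dpsepsis.cohort import CohortConfig, generate_cohort, sepsis_filter
from dpsepsis.dataset import (
    StateNormalizer,
    build_transitions,
    fit_action_grid,
    split_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """250 synthetic patients, Sepsis-3 filtered."""
    cfg = CohortConfig(n_patients=250, seed=7)
    return sepsis_filter(generate_cohort(cfg), 2), cfg


@pytest.fixture(scope="session")
def small_mdp(small_cohort):
    """Train/test transition sets built from the small cohort."""
    cohort, cfg = small_cohort
    train, test = split_cohort(cohort, 0.8, seed=1)
    grid = fit_action_grid(train)
    normalizer = StateNormalizer().fit(train)
    return {
        "train_records": train,
        "test_records": test,
        "grid": grid,
        "normalizer": normalizer,
        "train": build_transitions(train, grid, normalizer),
        "test": build_transitions(test, grid, normalizer),
        "config": cfg,
    }


def chain_mdp_transitions(reps: int = 50):
    """Tiny deterministic 3-state chain MDP as a TransitionSet.

    States one-hot in R^3; two actions: 0 = stay (reward -0.1),
    1 = advance; reaching state 2 ends the episode with reward +1.
    """
    from dpsepsis.dataset import TransitionSet

    eye = np.eye(3)
    data = [
        (0, 0, -0.1, 0, False),
        (0, 1, 0.0, 1, False),
        (1, 0, -0.1, 1, False),
        (1, 1, 1.0, 2, True),
    ]
    n = len(data) * reps
    return TransitionSet(
        states=np.vstack([eye[s] for s, _, _, _, _ in data] * reps),
        actions=np.array([a for _, a, _, _, _ in data] * reps),
        iv_bins=np.array([a for _, a, _, _, _ in data] * reps),
        vp_bins=np.zeros(n, dtype=np.int64),
        rewards=np.array([r for _, _, r, _, _ in data] * reps, dtype=float),
        next_states=np.vstack([eye[sp] for _, _, _, sp, _ in data] * reps),
        terminal=np.array([t for _, _, _, _, t in data] * reps),
        patient_ids=np.array([f"x{i}" for i in range(n)], dtype=object),
        strata=np.array(["medium"] * n, dtype=object),
        survived=np.ones(n, dtype=bool),
    )


def chain_mdp_qstar(gamma: float = 0.9) -> np.ndarray:
    """Value-iteration oracle for the chain MDP above."""
    Q = np.zeros((2, 2))
    for _ in range(500):
        V = Q.max(axis=1)
        Qn = np.empty_like(Q)
        Qn[0, 0] = -0.1 + gamma * V[0]
        Qn[0, 1] = 0.0 + gamma * V[1]
        Qn[1, 0] = -0.1 + gamma * V[1]
        Qn[1, 1] = 1.0
        Q = Qn
    return Q
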