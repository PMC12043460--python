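"""Offline MDP construction from a cohort.

Turns patient records into transition tuples: per-drug dose discretization
into 5 bins (zero dose plus empirical quartiles of the nonzero doses, fitted
on the training split only), sparse terminal rewards (+15 survive / -15 die),
patient-level train/test splitting, SOFA stratification, and z-normalized
state vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .cohort import N_BINS, PatientRecord, STRATA

TERMINAL_REWARD = 15.0

_STRATUM_NAMES = np.array(STRATA)


class DegenerateGridError(ValueError):
    """Raised when a drug's nonzero doses have no spread to take quartiles of."""


class SplitError(ValueError):
    """Raised when a cohort cannot be split as requested."""


@dataclass
class ActionGrid:
    """Per-drug quartile cut points over *nonzero* training doses.

    Bin 0 is "no drug"; bins 1..4 are the quartiles of the nonzero-dose
    distribution, with intervals closed on the left of the upper bin (a dose
    exactly on a cut point falls in the lower bin).
    """

    iv_quartiles: np.ndarray  # 3 strictly increasing cut points
    vp_quartiles: np.ndarray

    def __post_init__(self) -> None:
        self.iv_quartiles = np.asarray(self.iv_quartiles, dtype=float)
        self.vp_quartiles = np.asarray(self.vp_quartiles, dtype=float)
        for cuts in (self.iv_quartiles, self.vp_quartiles):
            if cuts.shape != (3,) or not np.all(np.diff(cuts) > 0):
                raise DegenerateGridError("quartile cut points must be 3 strictly increasing values")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"iv_quartiles": self.iv_quartiles.tolist(),
                        "vp_quartiles": self.vp_quartiles.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ActionGrid":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["iv_quartiles"]), np.array(d["vp_quartiles"]))


def fit_action_grid(training_records: list[PatientRecord]) -> ActionGrid:
    """Empirical quartiles of the nonzero doses per drug, training split only."""
    cuts = []
    for attr in ("iv_dose", "vp_dose"):
        doses = np.concatenate([getattr(r, attr) for r in training_records])
        nonzero = doses[doses > 0]
        if nonzero.size == 0:
            raise DegenerateGridError(f"all {attr} values are zero")
        if np.unique(nonzero).size < 4:
            raise DegenerateGridError(f"need at least 4 distinct nonzero {attr} values")
        cuts.append(np.quantile(nonzero, [0.25, 0.5, 0.75]))
    return ActionGrid(iv_quartiles=cuts[0], vp_quartiles=cuts[1])


def _discretize_one(dose: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("doses must be >= 0")
    # nonzero bins 1..4; a dose equal to a cut point goes to the lower bin
    bins = 1 + np.searchsorted(cuts, dose, side="left")
    return np.where(dose == 0, 0, bins).astype(np.int64)


def discretize_action(iv_dose, vp_dose, grid: ActionGrid):
    """Map continuous (IV, VP) doses to the 5x5 bin grid.

    Zero dose is bin 0 ("no treatment"); nonzero doses land in quartile bins
    1..4, so (4, 4) is the highest quartile of both drugs. Accepts scalars or
    arrays; returns a pair of ints or int arrays.
    """
    iv_bin = _discretize_one(iv_dose, grid.iv_quartiles)
    vp_bin = _discretize_one(vp_dose, grid.vp_quartiles)
    if np.isscalar(iv_dose) and np.isscalar(vp_dose):
        return int(iv_bin), int(vp_bin)
    return iv_bin, vp_bin


def flatten_action(iv_bin, vp_bin):
    """(iv_bin, vp_bin) -> flat index in 0..24."""
    return N_BINS * np.asarray(iv_bin) + np.asarray(vp_bin)


def unflatten_action(index):
    index = np.asarray(index)
    return index // N_BINS, index % N_BINS


def assign_rewards(record: PatientRecord) -> np.ndarray:
    """Sparse terminal reward: 0 everywhere except +-15 at the last window."""
    if record.n_windows < 1:
        raise ValueError("record must have at least one window")
    rewards = np.zeros(record.n_windows)
    rewards[-1] = TERMINAL_REWARD if record.survived else -TERMINAL_REWARD
    return rewards


def split_cohort(cohort: list[PatientRecord], train_frac: float, seed: int):
    """Patient-level split: no patient contributes to both partitions."""
    if not 0 < train_frac < 1:
        raise SplitError("train_frac must be in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise SplitError("need at least 2 patients to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = set(order[:n_train].tolist())
    train = [cohort[i] for i in range(n) if i in train_idx]
    test = [cohort[i] for i in range(n) if i not in train_idx]
    return train, test


def stratify_sofa(sofa: int) -> str:
    """SOFA severity stratum: < 5 low, 5..15 medium, > 15 high.

    The boundary scores 5 and 15 are assigned to the medium stratum so the
    three strata are exhaustive.
    """
    if sofa < 0:
        raise ValueError("SOFA must be >= 0")
    if sofa < 5:
        return "low"
    if sofa <= 15:
        return "medium"
    return "high"


class StateNormalizer:
    """Per-feature z-scoring with statistics from the training split only."""

    def __init__(self) -> None:
        self._scaler = StandardScaler()

    def fit(self, training_records: list[PatientRecord]) -> "StateNormalizer":
        X = np.vstack([r.features for r in training_records])
        self._scaler.fit(X)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        check_is_fitted(self._scaler)
        return self._scaler.transform(features)

    @property
    def mean_(self) -> np.ndarray:
        return self._scaler.mean_

    @property
    def scale_(self) -> np.ndarray:
        return self._scaler.scale_

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self._scaler)
        Path(path).write_text(
            json.dumps({"mean": self.mean_.tolist(), "scale": self.scale_.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StateNormalizer":
        d = json.loads(Path(path).read_text())
        norm = cls()
        mean = np.array(d["mean"])
        scale = np.array(d["scale"])
        norm._scaler.mean_ = mean
        norm._scaler.scale_ = scale
        norm._scaler.var_ = scale**2
        norm._scaler.n_features_in_ = mean.size
        norm._scaler.n_samples_seen_ = 1
        return norm


@dataclass
class Transition:
    """One offline MDP tuple with patient and stratum metadata."""

    state: np.ndarray
    action: int                  # flat index, 5*iv_bin + vp_bin
    iv_bin: int
    vp_bin: int
    reward: float
    next_state: np.ndarray | None
    terminal: bool
    patient_id: str
    sofa_stratum: str
    survived: bool


@dataclass
class TransitionSet:
    """Columnar container of transitions (one row per patient-window)."""

    states: np.ndarray        # (n, d) z-normalized
    actions: np.ndarray       # (n,) flat indices 0..24
    iv_bins: np.ndarray
    vp_bins: np.ndarray
    rewards: np.ndarray       # (n,) in {-15, 0, +15}
    next_states: np.ndarray   # (n, d); rows of terminal transitions are zero
    terminal: np.ndarray      # (n,) bool
    patient_ids: np.ndarray   # (n,) object
    strata: np.ndarray        # (n,) 'low'|'medium'|'high'
    survived: np.ndarray      # (n,) bool, patient-level outcome replicated
    sofa: np.ndarray = field(default=None)  # (n,) raw SOFA at the window

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def n_features(self) -> int:
        return self.states.shape[1]

    def __getitem__(self, i: int) -> Transition:
        return Transition(
            state=self.states[i],
            action=int(self.actions[i]),
            iv_bin=int(self.iv_bins[i]),
            vp_bin=int(self.vp_bins[i]),
            reward=float(self.rewards[i]),
            next_state=None if self.terminal[i] else self.next_states[i],
            terminal=bool(self.terminal[i]),
            patient_id=str(self.patient_ids[i]),
            sofa_stratum=str(self.strata[i]),
            survived=bool(self.survived[i]),
        )

    def subset(self, mask: np.ndarray) -> "TransitionSet":
        mask = np.asarray(mask)
        return TransitionSet(
            states=self.states[mask],
            actions=self.actions[mask],
            iv_bins=self.iv_bins[mask],
            vp_bins=self.vp_bins[mask],
            rewards=self.rewards[mask],
            next_states=self.next_states[mask],
            terminal=self.terminal[mask],
            patient_ids=self.patient_ids[mask],
            strata=self.strata[mask],
            survived=self.survived[mask],
            sofa=None if self.sofa is None else self.sofa[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        d = self.states.shape[1]
        df = pd.DataFrame(self.states, columns=[f"s{j}" for j in range(d)])
        for j in range(d):
            df[f"ns{j}"] = self.next_states[:, j]
        df["action"] = self.actions
        df["iv_bin"] = self.iv_bins
        df["vp_bin"] = self.vp_bins
        df["reward"] = self.rewards
        df["terminal"] = self.terminal.astype(int)
        df["patient_id"] = self.patient_ids
        df["sofa_stratum"] = self.strata
        df["survived"] = self.survived.astype(int)
        if self.sofa is not None:
            df["sofa"] = self.sofa
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionSet":
        d = sum(1 for c in df.columns if c.startswith("s") and c[1:].isdigit())
        return cls(
            states=df[[f"s{j}" for j in range(d)]].to_numpy(float),
            actions=df["action"].to_numpy(np.int64),
            iv_bins=df["iv_bin"].to_numpy(np.int64),
            vp_bins=df["vp_bin"].to_numpy(np.int64),
            rewards=df["reward"].to_numpy(float),
            next_states=df[[f"ns{j}" for j in range(d)]].to_numpy(float),
            terminal=df["terminal"].to_numpy(bool),
            patient_ids=df["patient_id"].to_numpy(object),
            strata=df["sofa_stratum"].to_numpy(object),
            survived=df["survived"].to_numpy(bool),
            sofa=df["sofa"].to_numpy(np.int64) if "sofa" in df.columns else None,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionSet":
        return cls.from_frame(pd.read_csv(path))


def build_transitions(
    records: list[PatientRecord],
    grid: ActionGrid,
    normalizer: StateNormalizer,
) -> TransitionSet:
    """Assemble one Transition per patient-window.

    The last window of each patient is terminal (no next state) and carries
    the +-15 outcome reward; all other rewards are 0. States are z-normalized
    with the supplied normalizer, which must have been fit on the training
    split (an unfit normalizer raises sklearn's NotFittedError).
    """
    if not records:
        raise ValueError("no records given")
    check_is_fitted(normalizer._scaler)  # fail fast before any work

    states, next_states, actions_iv, actions_vp = [], [], [], []
    rewards, terminal, pids, strata, survived, sofa_col = [], [], [], [], [], []
    for r in records:
        X = normalizer.transform(r.features)
        T = r.n_windows
        iv_b, vp_b = discretize_action(r.iv_dose, r.vp_dose, grid)
        rew = assign_rewards(r)
        nxt = np.zeros_like(X)
        nxt[:-1] = X[1:]
        states.append(X)
        next_states.append(nxt)
        actions_iv.append(iv_b)
        actions_vp.append(vp_b)
        rewards.append(rew)
        term = np.zeros(T, dtype=bool)
        term[-1] = True
        terminal.append(term)
        pids.extend([r.patient_id] * T)
        strata.extend(stratify_sofa(int(s)) for s in r.sofa)
        survived.extend([r.survived] * T)
        sofa_col.append(r.sofa)

    iv_bins = np.concatenate(actions_iv)
    vp_bins = np.concatenate(actions_vp)
    return TransitionSet(
        states=np.vstack(states),
        actions=flatten_action(iv_bins, vp_bins),
        iv_bins=iv_bins,
        vp_bins=vp_bins,
        rewards=np.concatenate(rewards),
        next_states=np.vstack(next_states),
        terminal=np.concatenate(terminal),
        patient_ids=np.array(pids, dtype=object),
        strata=np.array(strata, dtype=object),
        survived=np.array(survived, dtype=bool),
        sofa=np.concatenate(sofa_col),
    )
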