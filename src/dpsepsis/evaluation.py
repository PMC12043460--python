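"""Policy evaluation: learning efficiency, estimated mortality, action maps.

Three readouts mirror how offline sepsis policies are conventionally judged:

* FAE (first-achieve episode): the first periodic training evaluation at
  which the held-out survival rate reaches a target phi — a learning-
  efficiency metric. "Episode" here means one evaluation pass, performed
  every K gradient steps during offline training.
* Estimated mortality: among held-out transitions where the clinician's
  discretized action agrees with the policy's greedy action, the death
  fraction of the *patients* contributing those matched transitions. The
  behavior policy itself scores exactly the cohort mortality under this
  estimator. The agreement rule is exact 5x5-bin equality by default, or
  "within one bin per drug" for sensitivity analysis.
* 5x5 action histograms: counts of (IV bin, VP bin) choices, overall and per
  SOFA stratum, for the learned policy and the clinician side by side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import N_BINS, STRATA
from .dataset import TransitionSet, unflatten_action

NOT_ACHIEVED = math.inf


@dataclass
class LearningCurve:
    """Held-out survival rate at each periodic evaluation (1-based episodes)."""

    episodes: np.ndarray
    survival_rates: np.ndarray

    def __post_init__(self) -> None:
        self.episodes = np.asarray(self.episodes, dtype=np.int64)
        self.survival_rates = np.asarray(self.survival_rates, dtype=float)
        if self.episodes.size != self.survival_rates.size:
            raise ValueError("episodes and survival_rates must have equal length")
        if self.episodes.size and np.any(np.diff(self.episodes) <= 0):
            raise ValueError("episode indices must be strictly increasing")
        finite = self.survival_rates[np.isfinite(self.survival_rates)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("survival rates must lie in [0, 1]")


def fae(curve: LearningCurve, phi: float) -> float:
    """First episode whose survival rate reaches phi; inf if never achieved."""
    if not 0 <= phi <= 1:
        raise ValueError("phi must be in [0, 1]")
    if curve.episodes.size == 0:
        raise ValueError("empty learning curve")
    hit = np.where(curve.survival_rates >= phi)[0]
    if hit.size == 0:
        return NOT_ACHIEVED
    return float(curve.episodes[hit[0]])


def _match_mask(policy_actions: np.ndarray, ts: TransitionSet, match_rule: str) -> np.ndarray:
    policy_actions = np.asarray(policy_actions, dtype=np.int64)
    if policy_actions.shape != (len(ts),):
        raise ValueError("need one policy action per transition")
    if match_rule == "exact":
        return policy_actions == ts.actions
    if match_rule == "within1":
        piv, pvp = unflatten_action(policy_actions)
        return (np.abs(piv - ts.iv_bins) <= 1) & (np.abs(pvp - ts.vp_bins) <= 1)
    raise ValueError(f"unknown match rule {match_rule!r}")


def _patient_mortality(pids: np.ndarray, survived: np.ndarray) -> tuple[float, int]:
    if pids.size == 0:
        return math.nan, 0
    _, first = np.unique(pids.astype(str), return_index=True)
    died = ~survived[first]
    return float(died.mean()), int(first.size)


@dataclass
class MortalityEstimate:
    mortality: float          # nan when no transitions matched
    n_patients: int
    n_matched_transitions: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mortality)


@dataclass
class MortalityReport:
    overall: MortalityEstimate
    by_stratum: dict[str, MortalityEstimate]


def estimated_mortality(
    policy_actions: np.ndarray,
    transitions: TransitionSet,
    match_rule: str = "exact",
) -> MortalityReport:
    """Action-matched patient-level mortality, overall and per SOFA stratum.

    ``policy_actions`` are the policy's greedy flat actions for each
    transition's state (compute via ``policy.predict(ts.states)``). A stratum
    with zero matched transitions gets a NaN estimate flagged via
    ``defined`` — undefined, not an error.
    """
    matched = _match_mask(policy_actions, transitions, match_rule)
    m_overall, n_pat = _patient_mortality(
        transitions.patient_ids[matched], transitions.survived[matched]
    )
    report = MortalityReport(
        overall=MortalityEstimate(m_overall, n_pat, int(matched.sum())),
        by_stratum={},
    )
    for s in STRATA:
        sel = matched & (transitions.strata == s)
        m, n = _patient_mortality(transitions.patient_ids[sel], transitions.survived[sel])
        report.by_stratum[s] = MortalityEstimate(m, n, int(sel.sum()))
    return report


def action_histogram(
    actions: np.ndarray,
    stratum_labels: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """5x5 (IV bin, VP bin) count grids, overall and per stratum.

    ``actions`` may be flat indices (n,) or bin pairs (n, 2). Stratum grids
    sum cell-wise to the overall grid.
    """
    actions = np.asarray(actions)
    if actions.ndim == 1:
        iv, vp = unflatten_action(actions.astype(np.int64))
    elif actions.ndim == 2 and actions.shape[1] == 2:
        iv, vp = actions[:, 0].astype(np.int64), actions[:, 1].astype(np.int64)
    else:
        raise ValueError("actions must be flat indices or (n, 2) bin pairs")
    if iv.size and (iv.min() < 0 or iv.max() >= N_BINS or vp.min() < 0 or vp.max() >= N_BINS):
        raise ValueError("action bins out of range 0..4")

    def grid(mask=None):
        ii = iv if mask is None else iv[mask]
        vv = vp if mask is None else vp[mask]
        g = np.zeros((N_BINS, N_BINS), dtype=np.int64)
        np.add.at(g, (ii, vv), 1)
        return g

    out = {"overall": grid()}
    if stratum_labels is not None:
        stratum_labels = np.asarray(stratum_labels)
        if stratum_labels.shape[0] != iv.shape[0]:
            raise ValueError("stratum labels must align with actions")
        for s in STRATA:
            out[s] = grid(stratum_labels == s)
    return out


@dataclass
class EvaluationReport:
    """One trained policy's full evaluation bundle."""

    fae: dict[float, float] = field(default_factory=dict)   # phi -> episode or inf
    mortality: MortalityReport | None = None
    policy_histogram: dict[str, np.ndarray] | None = None
    clinician_histogram: dict[str, np.ndarray] | None = None
    curve: LearningCurve | None = None
    epsilon: float = math.inf     # certified budget; inf = non-private
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def est(e: MortalityEstimate):
            return {
                "mortality": None if not e.defined else e.mortality,
                "n_patients": e.n_patients,
                "n_matched_transitions": e.n_matched_transitions,
            }

        d: dict = {
            "epsilon": None if math.isinf(self.epsilon) else self.epsilon,
            "fae": {str(k): (None if math.isinf(v) else v) for k, v in self.fae.items()},
            "extras": self.extras,
        }
        if self.mortality is not None:
            d["mortality"] = {
                "overall": est(self.mortality.overall),
                **{s: est(e) for s, e in self.mortality.by_stratum.items()},
            }
        if self.policy_histogram is not None:
            d["policy_histogram"] = {k: v.tolist() for k, v in self.policy_histogram.items()}
        if self.clinician_histogram is not None:
            d["clinician_histogram"] = {k: v.tolist() for k, v in self.clinician_histogram.items()}
        if self.curve is not None:
            d["curve"] = {
                "episodes": self.curve.episodes.tolist(),
                "survival_rates": self.curve.survival_rates.tolist(),
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def histograms_to_csv(self, path: str | Path, which: str = "policy") -> None:
        """Emit the 5x5 grids as CSV (one block per stratum key)."""
        hists = self.policy_histogram if which == "policy" else self.clinician_histogram
        if hists is None:
            raise ValueError(f"no {which} histogram recorded")
        lines = []
        for key, g in hists.items():
            lines.append(key)
            lines.extend(",".join(str(int(x)) for x in row) for row in g)
        Path(path).write_text("\n".join(lines) + "\n")
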