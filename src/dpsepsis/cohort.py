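"""Synthetic septic-patient cohort generator.

Emulates the structure of a Sepsis-3 ICU cohort: per-patient time series of
4-hour windows spanning 24 h before to 48 h after sepsis onset (18 windows by
default), a 47-dimensional physiological state per window in which the SOFA
organ-failure score is one coordinate, continuous IV-fluid and vasopressor
doses chosen by a severity-dependent simulated clinician, and a binary
survival outcome.

The generative model plants a recoverable optimal treatment: each SOFA
stratum (low / medium / high) has a designated optimal (IV bin, VP bin) dose
pair, deviating from it both worsens the SOFA trajectory and directly raises
the terminal death probability. A policy learner run on the generated data
can therefore be scored against a known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

SOFA_MAX = 24
N_BINS = 5  # per-drug dose bins: 0 = no drug, 1..4 = nonzero quartiles

STRATA = ("low", "medium", "high")


def _default_severity_drift() -> dict:
    return {
        "latent_mean": 7.0,   # mean latent severity of the admitted cohort
        "latent_sd": 4.0,
        "init_sd": 2.0,       # sd of SOFA at the first window around latent
        "pull": 0.3,          # mean-reversion rate toward latent severity
        "action_push": 0.7,   # SOFA points per unit of action mismatch
        "push_center": 2.3,   # mismatch level that leaves the drift neutral
        "walk_sd": 1.0,       # innovation sd of the SOFA random walk
    }


def _default_behavior_dose_params() -> dict:
    # Mean dose *bin* chosen by the simulated clinician, as a nondecreasing
    # step function of SOFA (one mean pair per stratum). Conditioning the
    # clinician on the stratum rather than the raw score keeps the action
    # choice independent of severity within a stratum, so conditional
    # death rates by action identify the planted optimum. The means and
    # dispersion are chosen so that the pooled occupancy of the four nonzero
    # bins is close to uniform, which makes the empirical dose quartiles
    # fitted downstream land on the generative bin edges.
    # Dosing style varies *between* patients (style_sd) as well as from
    # window to window (bin_sd): the same clinician treats the same patient
    # consistently. Within-patient consistency is what gives the
    # action-matched mortality estimator its selection power — with a purely
    # independent per-window clinician, matched patient subsets are
    # essentially random and every policy scores the cohort mortality.
    return {
        "mean_bins": {"low": (1.2, 0.5), "medium": (2.6, 2.3), "high": (3.4, 3.2)},
        "bin_sd": 1.0,        # per-window dispersion around the patient's mean
        "style_sd": 1.0,      # per-patient (per-drug) dosing-style offset
        "explore": 0.2,       # probability of a uniformly random bin (practice variability)
        "iv_scale": 500.0,    # mL per 4 h; exponential reference scale
        "vp_scale": 0.5,      # ug/kg/min; exponential reference scale
    }


def _default_outcome_params() -> dict:
    return {
        "intercept": -5.4,
        "sofa_coef": 0.25,      # logit per terminal SOFA point
        "mismatch_coef": 0.06,  # logit per unit of summed L1 action mismatch
    }


def _default_planted_optimum() -> dict:
    return {"low": (1, 0), "medium": (2, 1), "high": (3, 3)}


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``n_windows`` defaults to 18: the 72-hour span around sepsis onset
    (24 h before to 48 h after) divided into 4-hour windows.
    """

    n_patients: int = 1000
    n_windows: int = 18
    window_hours: float = 4.0
    n_features: int = 47
    severity_drift: dict = field(default_factory=_default_severity_drift)
    behavior_dose_params: dict = field(default_factory=_default_behavior_dose_params)
    outcome_params: dict = field(default_factory=_default_outcome_params)
    planted_optimum: dict = field(default_factory=_default_planted_optimum)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise CohortConfigError("n_patients must be positive")
        if self.n_windows < 2:
            raise CohortConfigError("n_windows must be at least 2")
        if self.window_hours <= 0:
            raise CohortConfigError("window_hours must be positive")
        if self.n_features < 2:
            raise CohortConfigError("n_features must be >= 2 (SOFA plus at least one)")
        for stratum in STRATA:
            if stratum not in self.planted_optimum:
                raise CohortConfigError(f"planted_optimum missing stratum {stratum!r}")
            iv, vp = self.planted_optimum[stratum]
            if not (0 <= iv < N_BINS and 0 <= vp < N_BINS):
                raise CohortConfigError("planted optimum bins must lie in 0..4")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_optimum"] = {k: list(v) for k, v in self.planted_optimum.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "planted_optimum" in d:
            d["planted_optimum"] = {k: tuple(v) for k, v in d["planted_optimum"].items()}
        return cls(**d)


@dataclass
class PatientRecord:
    """One synthetic patient: windowed features, doses, SOFA trace, outcome.

    ``iv_bin`` / ``vp_bin`` record the generative dose bins the simulated
    clinician actually chose; downstream discretization re-derives bins from
    the continuous doses and need not agree exactly near bin boundaries.
    """

    patient_id: str
    features: np.ndarray        # (n_windows, n_features), raw scale; column 0 is SOFA
    sofa: np.ndarray            # (n_windows,) non-negative integers
    iv_dose: np.ndarray         # (n_windows,) mL, >= 0
    vp_dose: np.ndarray         # (n_windows,) ug/kg/min, >= 0
    survived: bool
    iv_bin: np.ndarray | None = None
    vp_bin: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


def stratum_of_sofa(sofa: np.ndarray) -> np.ndarray:
    """Vectorized SOFA stratification: < 5 low, 5..15 medium, > 15 high."""
    sofa = np.asarray(sofa)
    out = np.where(sofa < 5, 0, np.where(sofa <= 15, 1, 2))
    return out


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` synthetic patients.

    Deterministic in ``config.seed``: identical configs yield bit-identical
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    T = config.n_windows
    drift = config.severity_drift
    beh = config.behavior_dose_params
    out_p = config.outcome_params

    opt = np.array([list(config.planted_optimum[s]) for s in STRATA])  # (3, 2)
    mean_bins = np.array([list(beh["mean_bins"][s]) for s in STRATA])  # (3, 2)

    latent = np.clip(rng.normal(drift["latent_mean"], drift["latent_sd"], n), 0, SOFA_MAX)
    sofa = np.zeros((n, T), dtype=np.int64)
    sofa[:, 0] = np.clip(
        np.rint(latent + rng.normal(0.0, drift["init_sd"], n)), 0, SOFA_MAX
    )

    iv_bin = np.zeros((n, T), dtype=np.int64)
    vp_bin = np.zeros((n, T), dtype=np.int64)
    mismatch = np.zeros((n, T), dtype=np.float64)

    style_sd = beh.get("style_sd", 0.0)
    style_iv = rng.normal(0.0, style_sd, n)
    style_vp = rng.normal(0.0, style_sd, n)

    for t in range(T):
        s_t = sofa[:, t]
        stratum = stratum_of_sofa(s_t)
        opt_iv = opt[stratum, 0]
        opt_vp = opt[stratum, 1]

        mean_iv = mean_bins[stratum, 0] + style_iv
        mean_vp = mean_bins[stratum, 1] + style_vp
        b_iv = np.clip(np.rint(rng.normal(mean_iv, beh["bin_sd"])), 0, N_BINS - 1)
        b_vp = np.clip(np.rint(rng.normal(mean_vp, beh["bin_sd"])), 0, N_BINS - 1)
        explore = rng.random(n) < beh["explore"]
        b_iv = np.where(explore, rng.integers(0, N_BINS, n), b_iv).astype(np.int64)
        b_vp = np.where(explore, rng.integers(0, N_BINS, n), b_vp).astype(np.int64)
        iv_bin[:, t] = b_iv
        vp_bin[:, t] = b_vp

        mis = np.abs(b_iv - opt_iv) + np.abs(b_vp - opt_vp)
        mismatch[:, t] = mis

        if t + 1 < T:
            step = (
                drift["pull"] * (latent - s_t)
                + drift["action_push"] * (mis - drift["push_center"])
                + rng.normal(0.0, drift["walk_sd"], n)
            )
            sofa[:, t + 1] = np.clip(s_t + np.rint(step), 0, SOFA_MAX)

    # Continuous doses: bin b > 0 occupies the b-th quarter of an exponential
    # reference distribution, so doses are ordered across bins and the
    # population nonzero-dose quartiles approximately recover the bin edges.
    u = rng.random((n, T, 2))
    p_iv = (iv_bin - 1 + u[:, :, 0]) / 4.0
    p_vp = (vp_bin - 1 + u[:, :, 1]) / 4.0
    iv_dose = np.where(iv_bin > 0, -np.log1p(-np.clip(p_iv, 0, None)) * beh["iv_scale"], 0.0)
    vp_dose = np.where(vp_bin > 0, -np.log1p(-np.clip(p_vp, 0, None)) * beh["vp_scale"], 0.0)

    logit = (
        out_p["intercept"]
        + out_p["sofa_coef"] * sofa[:, -1]
        + out_p["mismatch_coef"] * mismatch.sum(axis=1)
    )
    p_death = special.expit(logit)
    survived = rng.random(n) >= p_death

    # Non-SOFA features: severity-correlated "vitals" with feature-specific
    # offset/scale plus independent noise channels, on raw scale.
    k = config.n_features - 1
    loading = rng.uniform(-1.0, 1.0, k)
    noise_sd = rng.uniform(0.5, 1.5, k)
    offset = rng.uniform(-10.0, 10.0, k)
    scale = rng.uniform(0.5, 20.0, k)
    feats = np.empty((n, T, config.n_features), dtype=np.float64)
    feats[:, :, 0] = sofa
    z_sofa = (sofa - drift["latent_mean"]) / max(drift["latent_sd"], 1e-12)
    noise = rng.normal(0.0, 1.0, (n, T, k))
    feats[:, :, 1:] = offset + scale * (loading * z_sofa[:, :, None] + noise_sd * noise)

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"p{i:06d}",
                features=feats[i],
                sofa=sofa[i],
                iv_dose=iv_dose[i],
                vp_dose=vp_dose[i],
                survived=bool(survived[i]),
                iv_bin=iv_bin[i],
                vp_bin=vp_bin[i],
            )
        )
    return records


def sepsis_filter(cohort: list[PatientRecord], threshold: int = 2) -> list[PatientRecord]:
    """Keep patients whose maximum SOFA over the trajectory reaches ``threshold``.

    Mirrors Sepsis-3 screening (organ dysfunction: SOFA >= 2). Order is
    preserved; an empty cohort filters to an empty cohort.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [r for r in cohort if int(np.max(r.sofa)) >= threshold]


# ---------------------------------------------------------------------------
# CSV interchange: one row per patient-window.

def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        n_feat = r.features.shape[1]
        for t in range(r.n_windows):
            row = {
                "patient_id": r.patient_id,
                "window": t,
                "sofa": int(r.sofa[t]),
                "iv_dose": r.iv_dose[t],
                "vp_dose": r.vp_dose[t],
                "survived": int(r.survived),
            }
            for j in range(1, n_feat):
                row[f"f{j}"] = r.features[t, j]
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    feat_cols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    records = []
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("window")
        sofa = g["sofa"].to_numpy(dtype=np.int64)
        feats = np.column_stack([sofa.astype(float)] + [g[c].to_numpy(float) for c in feat_cols])
        records.append(
            PatientRecord(
                patient_id=str(pid),
                features=feats,
                sofa=sofa,
                iv_dose=g["iv_dose"].to_numpy(float),
                vp_dose=g["vp_dose"].to_numpy(float),
                survived=bool(g["survived"].iloc[0]),
            )
        )
    return records


def write_cohort(path: str | Path, cohort: list[PatientRecord], config: CohortConfig | None = None) -> None:
    """Write a cohort CSV plus, if given, a JSON sidecar with the config."""
    path = Path(path)
    cohort_to_frame(cohort).to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2))


def read_cohort(path: str | Path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path))
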