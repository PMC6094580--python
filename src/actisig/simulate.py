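"""Synthetic cohorts and epoch streams with known ground truth.

Two generators:

* ``simulate_cohort`` draws feature-level cohorts (16-bin spectra plus a
  metabolic panel) with the collinearity structure the analysis assumes:
  strong adjacent-bin correlations, negative sedentary-vs-mid-intensity
  correlations induced by wear-time closure, and an outcome signal placed on
  known bins. Fast enough for repeated statistical tests.
* ``simulate_epochs`` emits 10-s epoch streams from a semi-Markov bout
  process for end-to-end exercise of the feature-extraction chain.

Bin durations follow a logistic-normal composition: log-durations combine a
general-activity factor, a vigorous-specific factor, and AR(1)-correlated
bin noise, then renormalize to each subject's wear time (the closure step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .accel import BinScheme, EpochStream

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SimulatedCohort",
    "SubjectActivitySpec",
    "known_signature",
    "simulate_cohort",
    "simulate_epochs",
]

N_BINS = 16

#: Baseline composition, min/day per bin (sums to 795 wear minutes).
DEFAULT_BIN_MEANS = np.array(
    [490.0, 90.0, 60.0, 45.0, 22.0, 12.0, 9.0, 8.0,
     8.0, 7.5, 7.0, 6.5, 10.0, 8.0, 6.0, 6.0]
)

#: General-activity factor loadings on log-durations (sedentary loads negative).
DEFAULT_ACTIVITY_LOADINGS = np.array(
    [-0.06, 0.12, 0.15, 0.18, 0.21, 0.24, 0.26, 0.28,
     0.28, 0.26, 0.22, 0.18, 0.15, 0.12, 0.10, 0.08]
)

#: Vigorous-specific factor loadings (upper spectrum only).
DEFAULT_VIGOR_LOADINGS = np.array(
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.03, 0.06,
     0.10, 0.15, 0.22, 0.28, 0.33, 0.38, 0.42, 0.46]
)

COMPOSITE_OUTCOMES = ("sbp", "tg", "tc_hdl", "homa", "wc_height", "andersen_distance")

#: Raw-scale descriptive targets (mean, SD) mirroring a 10-year-old cohort.
_OUTCOME_SCALE = {
    "sbp": (105.2, 8.4),
    "tg": (0.78, 0.38),
    "tc_hdl": (2.91, 0.71),
    "homa": (1.71, 0.98),
    "wc_height": (0.43, 0.05),
    "andersen_distance": (898.0, 103.0),
}
_LOGNORMAL_OUTCOMES = ("tg", "tc_hdl", "homa")

#: Risk-scale (z) shifts: (delta for sex=1, slope per year of age).
_OUTCOME_EFFECTS = {
    "sbp": (0.0, 0.2),
    "tg": (-0.3, 0.0),
    "tc_hdl": (-0.24, 0.0),
    "homa": (-0.35, 0.2),
    "wc_height": (0.0, 0.0),
    "andersen_distance": (-0.5, -1.0),
}


def known_signature() -> "GroundTruth":
    """Default ground truth: effect concentrated on the 5000-6999 cpm bins."""
    beta = np.zeros(N_BINS)
    beta[12] = beta[13] = -1.0  # more time in these bins -> lower risk score
    return GroundTruth(beta=beta, true_r2=0.13, confounded_sed=True)


@dataclass(frozen=True)
class GroundTruth:
    """The generating effect vector and its headline parameters."""

    beta: np.ndarray
    true_r2: float
    confounded_sed: bool = True

    @property
    def effect_bins(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs for the feature-level cohort generator.

    ``neighbor_rho`` is the adjacent-bin correlation target used to derive
    the AR(1) bin-noise scale from the factor loadings; ``true_r2`` is the
    variance fraction of the composite outcome carried by the spectrum, and
    ``individual_r2`` the per-outcome analogue (shared metabolic noise makes
    the composite cleaner than its parts).
    """

    n_subjects: int = 841
    wear_mean: float = 795.0
    wear_sd: float = 57.0
    bin_means: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_MEANS.copy())
    activity_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_ACTIVITY_LOADINGS.copy()
    )
    vigor_loadings: np.ndarray = field(
        default_factory=lambda: DEFAULT_VIGOR_LOADINGS.copy()
    )
    neighbor_rho: float = 0.91
    ar_phi: float = 0.7
    sed_noise_sd: float = 0.10
    beta: np.ndarray | None = None
    true_r2: float = 0.13
    individual_r2: float = 0.07
    sex_activity_shift: float = 0.25
    age_mean: float = 10.2
    age_sd: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (-1.0 < self.neighbor_rho < 1.0):
            raise ValueError("neighbor_rho must be in (-1, 1)")
        if not (0.0 <= self.ar_phi < self.neighbor_rho):
            raise ValueError(
                "ar_phi must be in [0, neighbor_rho) for a feasible noise scale"
            )
        if not (0.0 < self.true_r2 < 1.0):
            raise ValueError("true_r2 must be in (0, 1)")

    def noise_sd(self) -> np.ndarray:
        """Per-bin log-noise SD hitting the adjacent-correlation target.

        For equal-loading neighbours, corr = (L^2 + c^2 L^2 phi)/(L^2 + c^2 L^2)
        with sigma = c*L, so c^2 = (1 - rho)/(rho - phi).
        """
        c = np.sqrt((1.0 - self.neighbor_rho) / (self.neighbor_rho - self.ar_phi))
        load = np.sqrt(self.activity_loadings**2 + self.vigor_loadings**2)
        sd = np.maximum(c * load, 0.04)
        sd[0] = self.sed_noise_sd
        return sd

    def noise_split(self) -> tuple[float, float]:
        """(shared, idiosyncratic) outcome-noise scales from the R^2 targets."""
        if not (0.0 < self.individual_r2 <= self.true_r2):
            raise ValueError("individual_r2 must be in (0, true_r2]")
        ce2 = 1.2 * (1.0 / self.individual_r2 - 1.0 / self.true_r2)
        cu2 = (1.0 / self.individual_r2 - 1.0) - ce2
        if cu2 < 0:
            raise ValueError(
                "infeasible R^2 targets: individual_r2 too close to true_r2 "
                "for six outcomes with shared noise"
            )
        return float(np.sqrt(cu2)), float(np.sqrt(ce2))


@dataclass
class SimulatedCohort:
    """Feature matrix, metabolic panel, and the generating ground truth."""

    features: pd.DataFrame   # n x 16 minutes/day, indexed by subject_id
    panel: pd.DataFrame      # raw metabolic panel (CSV-compatible)
    ground_truth: GroundTruth
    config: CohortConfig
    seed: int | None

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def bin_labels(self) -> list[str]:
        return list(self.features.columns)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def simulate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> SimulatedCohort:
    """Generate one cohort; deterministic for a given config and seed."""
    config = config or CohortConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    truth = (
        known_signature()
        if config.beta is None
        else GroundTruth(beta=np.asarray(config.beta, dtype=float), true_r2=config.true_r2)
    )
    if config.beta is not None:
        truth = replace(truth, true_r2=config.true_r2)

    # demographics
    sex = rng.integers(0, 2, size=n)  # 1 = boy
    age = rng.normal(config.age_mean, config.age_sd, size=n)

    # latent factors and AR(1) bin noise
    activity = rng.standard_normal(n) + config.sex_activity_shift * (sex - 0.5)
    vigor = rng.standard_normal(n)
    phi = config.ar_phi
    eps = np.empty((n, N_BINS))
    eps[:, 0] = rng.standard_normal(n)
    for j in range(1, N_BINS):
        eps[:, j] = phi * eps[:, j - 1] + np.sqrt(1 - phi**2) * rng.standard_normal(n)

    sd = config.noise_sd()
    log_d = (
        np.log(config.bin_means)[None, :]
        + np.outer(activity, config.activity_loadings)
        + np.outer(vigor, config.vigor_loadings)
        + eps * sd[None, :]
    )
    durations = np.exp(log_d)

    # closure: renormalize to each subject's wear time
    wear = np.clip(rng.normal(config.wear_mean, config.wear_sd, size=n), 480.0, None)
    X = durations * (wear / durations.sum(axis=1))[:, None]

    # outcome signal on the closed features
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    s = Xz @ truth.beta
    s = _standardize(s) if s.std(ddof=1) > 0 else np.zeros(n)  # null-effect cohorts

    c_u, c_e = config.noise_split()
    u = rng.standard_normal(n)
    panel_cols: dict = {}
    for name in COMPOSITE_OUTCOMES:
        core = _standardize(s + c_u * u + c_e * rng.standard_normal(n))
        sex_delta, age_slope = _OUTCOME_EFFECTS[name]
        core = core + sex_delta * sex + age_slope * (age - config.age_mean)
        mean, sdev = _OUTCOME_SCALE[name]
        if name == "andersen_distance":
            raw = mean - sdev * core  # fitness: higher is better
        elif name in _LOGNORMAL_OUTCOMES:
            mu, sig = _lognormal_params(mean, sdev)
            raw = np.exp(mu + sig * core)
        else:
            raw = mean + sdev * core
        panel_cols[name] = raw

    # back out raw panel fields consistent with the derived indices
    height = rng.normal(142.9, 6.7, size=n)
    mu, sig = _lognormal_params(18.0, 3.0)
    bmi = np.exp(mu + sig * rng.standard_normal(n))
    hdl_mu, hdl_sig = _lognormal_params(1.59, 0.25)
    hdl = np.exp(hdl_mu + hdl_sig * rng.standard_normal(n))
    glucose = np.clip(rng.normal(4.98, 0.32, size=n), 3.5, None)
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    panel = pd.DataFrame(
        {
            "subject_id": ids,
            "sex": sex,
            "age": age,
            "body_mass": bmi * (height / 100.0) ** 2,
            "height": height,
            "waist": panel_cols["wc_height"] * height,
            "sbp": panel_cols["sbp"],
            "dbp": rng.normal(57.7, 6.2, size=n),
            "tc": panel_cols["tc_hdl"] * hdl,
            "hdl": hdl,
            "tg": panel_cols["tg"],
            "glucose": glucose,
            "insulin": panel_cols["homa"] * 22.5 / glucose * 6.945,
            "andersen_distance": panel_cols["andersen_distance"],
        }
    )
    features = pd.DataFrame(X, index=pd.Index(ids, name="subject_id"),
                            columns=list(BinScheme.default().labels))
    return SimulatedCohort(
        features=features, panel=panel, ground_truth=truth, config=config, seed=seed
    )


# ---------------------------------------------------------------------------
# Epoch-level generator
# ---------------------------------------------------------------------------

#: state -> (target min/day, mean bout minutes, median cpm, log-sd of cpm).
#: Non-wear bouts have a 65-min floor (see NONWEAR_MIN_BOUT_MIN) so device-off
#: time stays above the 60-min detection threshold instead of leaking into
#: sedentary wear time; targets are therefore close to realized minutes.
DEFAULT_STATE_PARAMS = {
    "sedentary": (480.0, 6.0, 18.0, 0.0),
    "light": (228.0, 3.0, 600.0, 0.4),
    "moderate": (44.0, 1.5, 3000.0, 0.12),
    "vigorous": (30.0, 1.0, 5800.0, 0.15),
    "nonwear": (298.0, 115.0, 0.0, 0.0),
}

NONWEAR_MIN_BOUT_MIN = 65.0


@dataclass(frozen=True)
class SubjectActivitySpec:
    """Bout-process parameters for one simulated subject."""

    subject_id: str = "SIM"
    n_days: int = 7
    start_date: str = "2024-05-06"
    epoch_length: int = 10
    day_start_hour: int = 6
    day_end_hour: int = 24
    state_params: dict = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_STATE_PARAMS.items()}
    )
    forced_nonwear: tuple = ()  # (day_index, start_minute, duration_minutes)
    emit_full_day: bool = False  # also emit zero-count epochs outside the window


def simulate_epochs(spec: SubjectActivitySpec, seed: int | None = None) -> EpochStream:
    """Semi-Markov bout process over wear states emitting 10-s epochs.

    Bout starts are drawn with probability proportional to
    target_minutes / mean_bout_minutes, bout lengths are geometric with the
    state's mean, and within-bout cpm is lognormal (sedentary counts are
    Poisson so long all-zero runs cannot arise from wear time).
    """
    rng = np.random.default_rng(seed)
    e = spec.epoch_length
    if 60 % e != 0:
        raise ValueError("epoch_length must divide 60 s")
    per_min = 60 // e
    day_epochs = (spec.day_end_hour - spec.day_start_hour) * 60 * per_min
    states = list(spec.state_params)
    targets = np.array([spec.state_params[s][0] for s in states], dtype=float)
    mean_bouts = np.array([spec.state_params[s][1] for s in states], dtype=float)
    start_prob = targets / mean_bouts
    start_prob = start_prob / start_prob.sum()

    all_times: list[pd.DatetimeIndex] = []
    all_counts: list[np.ndarray] = []
    day0 = pd.Timestamp(spec.start_date)
    for day in range(spec.n_days):
        counts = np.zeros(day_epochs, dtype=np.int64)
        filled = 0
        while filled < day_epochs:
            k = rng.choice(len(states), p=start_prob)
            name = states[k]
            if name == "nonwear":
                floor = int(NONWEAR_MIN_BOUT_MIN * per_min)
                extra = max(mean_bouts[k] - NONWEAR_MIN_BOUT_MIN, 1.0) * per_min
                length = floor + int(rng.geometric(1.0 / extra))
            else:
                length = int(rng.geometric(1.0 / (mean_bouts[k] * per_min)))
            length = min(length, day_epochs - filled)
            _, _, med_cpm, log_sd = spec.state_params[name]
            if name == "nonwear":
                pass  # zeros already
            elif name == "sedentary":
                counts[filled : filled + length] = rng.poisson(
                    med_cpm * e / 60.0, size=length
                )
            else:
                cpm = med_cpm * np.exp(log_sd * rng.standard_normal(length))
                counts[filled : filled + length] = np.round(cpm * e / 60.0).astype(
                    np.int64
                )
            filled += length
        for day_idx, start_min, dur_min in spec.forced_nonwear:
            if day_idx == day:
                a = start_min * per_min
                b = a + dur_min * per_min
                counts[a:b] = 0
        start = day0 + pd.Timedelta(days=day, hours=spec.day_start_hour)
        times = start + pd.to_timedelta(np.arange(day_epochs) * e, unit="s")
        if spec.emit_full_day:
            pre_n = spec.day_start_hour * 60 * per_min
            pre_times = day0 + pd.Timedelta(days=day) + pd.to_timedelta(
                np.arange(pre_n) * e, unit="s"
            )
            all_times.append(pd.DatetimeIndex(pre_times))
            all_counts.append(np.zeros(pre_n, dtype=np.int64))
        all_times.append(pd.DatetimeIndex(times))
        all_counts.append(counts)
    return EpochStream(
        subject_id=spec.subject_id,
        times=pd.DatetimeIndex(np.concatenate([t.asi8 for t in all_times]).view("M8[ns]")),
        counts=np.concatenate(all_counts),
        epoch_length=e,
    )
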