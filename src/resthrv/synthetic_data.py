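"""Synthetic data with known ground truth for the HRV pipeline.

Two generators back the test suite and the power simulations:

* :func:`generate_ibi_recording` emits a beat series whose resting HRV is
  controlled analytically.  The IBI model is a respiratory-sinus-arrhythmia
  sinusoid (which places power in the HF band) plus stationary AR(1)
  Gaussian noise, mean-shifted to the target mean IBI.  For a sinusoid of
  amplitude A at frequency f sampled every T seconds, the successive-
  difference RMS is ``A * sqrt(2) * |sin(pi f T)|``; for AR(1) noise with
  variance s2 and coefficient phi it is ``sqrt(2 s2 (1 - phi))``.  The noise
  variance is solved so the two components add (in quadrature) to the target
  RMSSD, which makes the realized RMSSD predictable and testable.  Missing-
  beat gaps, split/merged spurious beats, and movement minutes reproduce the
  artifact classes the preprocessing stage must handle.

* :func:`generate_panel` emits a two-level person x day panel
  ``y_ij = mu + sqrt(icc) * b_i + sqrt(1-icc) * w_ij`` with person effects
  correlated by a between-person matrix and day effects by a within-person
  matrix, so the generating between/within correlations and ICCs are exactly
  the configured ones.  Binary person-level variables are produced by
  thresholding the latent person effect at the quantile matching the
  configured probability; age and gender act only at the between level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ibi_pipeline import BeatSeries, MS_PER_MIN


class ParameterError(ValueError):
    """Raised for infeasible or invalid generator configurations."""


# ---------------------------------------------------------------------------
# IBI recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IbiGenConfig:
    """Configuration for one synthetic IBI recording.

    Defaults describe a typical sleeping adult: mean IBI 1000 ms (60 bpm),
    RMSSD 40 ms, respiration at 0.25 Hz contributing a 20 ms peak
    modulation, mildly autocorrelated residual variability.
    """

    mean_ibi: float = 1000.0
    target_rmssd: float = 40.0
    respiratory_freq: float = 0.25
    respiratory_amplitude: float = 20.0
    ar_coefficient: float = 0.3
    duration: float = 18_000.0
    gap_fraction: float = 0.0
    spurious_rate: float = 0.0
    movement_minutes: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.mean_ibi <= 0:
            raise ParameterError("mean_ibi must be positive")
        if self.target_rmssd < 0:
            raise ParameterError("target_rmssd must be non-negative")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if not 0 <= self.gap_fraction < 1:
            raise ParameterError("gap_fraction must lie in [0, 1)")
        if not -1 < self.ar_coefficient < 1:
            raise ParameterError("ar_coefficient must lie in (-1, 1)")
        if self.spurious_rate < 0:
            raise ParameterError("spurious_rate must be non-negative")


@dataclass
class IbiRecording:
    """A generated beat series with its paired step table and truth record."""

    series: BeatSeries
    steps: pd.DataFrame
    truth: dict


def _resp_rmssd(cfg: IbiGenConfig) -> float:
    """Successive-difference RMS contributed by the respiratory sinusoid."""
    T = cfg.mean_ibi / 1000.0
    return cfg.respiratory_amplitude * np.sqrt(2.0) * abs(
        np.sin(np.pi * cfg.respiratory_freq * T)
    )


def generate_ibi_recording(config: IbiGenConfig) -> IbiRecording:
    """Generate one timestamped IBI recording with controllable HRV.

    Raises :class:`ParameterError` when the respiratory amplitude alone
    already implies an RMSSD above the target (the noise variance would have
    to be negative).
    """
    rng = np.random.default_rng(config.seed)
    n_ibis = max(2, int(round(config.duration * 1000.0 / config.mean_ibi)))

    resp_sq = _resp_rmssd(config) ** 2
    resid_sq = config.target_rmssd ** 2 - resp_sq
    if resid_sq < -1e-9:
        raise ParameterError(
            "infeasible target: respiratory amplitude alone implies RMSSD "
            f"{np.sqrt(resp_sq):.2f} ms > target {config.target_rmssd:.2f} ms"
        )
    resid_sq = max(resid_sq, 0.0)
    phi = config.ar_coefficient
    ar_var = resid_sq / (2.0 * (1.0 - phi))
    eps_sd = np.sqrt(max(ar_var, 0.0) * (1.0 - phi ** 2))

    t_nom = np.arange(n_ibis) * (config.mean_ibi / 1000.0)  # seconds
    resp = config.respiratory_amplitude * np.sin(
        2 * np.pi * config.respiratory_freq * t_nom
    )
    noise = np.zeros(n_ibis)
    if ar_var > 0:
        noise[0] = rng.normal(0.0, np.sqrt(ar_var))
        eps = rng.normal(0.0, eps_sd, size=n_ibis - 1)
        for k in range(1, n_ibis):
            noise[k] = phi * noise[k - 1] + eps[k - 1]
    ibis = config.mean_ibi + resp + noise
    if np.any(ibis <= 0):
        raise ParameterError("generated IBIs non-positive; reduce variability")
    timestamps = np.concatenate([[0.0], np.cumsum(ibis)])
    clean_rmssd = float(np.sqrt(np.mean(np.diff(ibis) ** 2)))

    # missing-beat gaps: drop contiguous runs of interior beats
    n_gap_beats = 0
    if config.gap_fraction > 0:
        quota = int(round(config.gap_fraction * timestamps.size))
        drop = np.zeros(timestamps.size, dtype=bool)
        while n_gap_beats < quota:
            run = min(int(rng.integers(5, 40)), quota - n_gap_beats)
            start = int(rng.integers(1, timestamps.size - run - 1))
            newly = ~drop[start:start + run]
            drop[start:start + run] = True
            n_gap_beats += int(newly.sum())
        timestamps = timestamps[~drop]

    # spurious beats: split a true interval in two (rate per 100 true beats)
    n_spurious = int(round(config.spurious_rate / 100.0 * timestamps.size))
    if n_spurious > 0:
        intervals = rng.choice(timestamps.size - 1, size=n_spurious, replace=False)
        frac = rng.uniform(0.3, 0.7, size=n_spurious)
        extra = timestamps[intervals] + frac * np.diff(timestamps)[intervals]
        timestamps = np.sort(np.concatenate([timestamps, extra]))

    series = BeatSeries.from_timestamps("p0", "r0", timestamps,
                                        device_context="night_watch")

    n_minutes = int(np.ceil(config.duration * 1000.0 / MS_PER_MIN))
    steps = pd.DataFrame({
        "person_id": "p0",
        "minute_start_ms": np.arange(n_minutes) * MS_PER_MIN,
        "steps": 0,
    })
    for m in config.movement_minutes:
        steps.loc[steps.index == m, "steps"] = 30

    truth = dict(asdict(config))
    truth.update(clean_rmssd=clean_rmssd, n_true_beats=n_ibis + 1,
                 n_gap_beats=n_gap_beats, n_spurious=n_spurious)
    return IbiRecording(series=series, steps=steps, truth=truth)


# ---------------------------------------------------------------------------
# Two-level panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGenConfig:
    """Configuration for a two-level (person x day) panel.

    Variables have unit total latent variance split by ``icc`` into a
    between-person and a within-person part.  ``covariate_effects`` maps a
    variable name to ``(beta_age, beta_gender)`` weights applied to the
    standardized age and centred gender at the between level (on top of the
    unit latent variance).  ``binary_specs`` maps a variable name to the
    probability of a 1; such variables are observed once per person.
    """

    n_persons: int = 100
    n_obs_per_person: int = 9
    variables: tuple = ("x", "y")
    between_corr: tuple | None = None
    within_corr: tuple | None = None
    icc: tuple = (0.5, 0.5)
    means: tuple | None = None
    binary_specs: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    age_range: tuple = (18.0, 65.0)
    seed: int = 0

    def matrix(self, which: str) -> np.ndarray:
        k = len(self.variables)
        raw = getattr(self, which)
        m = np.eye(k) if raw is None else np.asarray(raw, dtype=float)
        if m.shape != (k, k):
            raise ParameterError(f"{which} must be {k}x{k}")
        if not np.allclose(m, m.T):
            raise ParameterError(f"{which} must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ParameterError(f"{which} must have unit diagonal")
        lam = np.linalg.eigvalsh(m)
        if lam[0] < -1e-10:
            raise ParameterError(
                f"{which} is not positive semi-definite "
                f"(smallest eigenvalue {lam[0]:.3g})"
            )
        return m

    def __post_init__(self):
        if self.n_persons < 1 or self.n_obs_per_person < 1:
            raise ParameterError("n_persons and n_obs_per_person must be >= 1")
        if len(self.icc) != len(self.variables):
            raise ParameterError("need one icc per variable")
        if any(not 0 < i < 1 for i in self.icc):
            raise ParameterError("icc values must lie in (0, 1)")
        self.matrix("between_corr")
        self.matrix("within_corr")
        for name in list(self.binary_specs) + list(self.covariate_effects):
            if name not in self.variables:
                raise ParameterError(f"unknown variable {name!r}")


@dataclass
class PanelDataset:
    """Long-format person x day panel plus person-level covariates.

    ``data`` has columns person_id, day_index, variable, value; ``persons``
    has person_id, age, gender and any binary baseline variables.
    """

    data: pd.DataFrame
    persons: pd.DataFrame
    flags: list = field(default_factory=list)

    def wide(self, variable: str) -> pd.DataFrame:
        sub = self.data[self.data["variable"] == variable]
        return sub.pivot(index="person_id", columns="day_index", values="value")

    @property
    def n_persons(self) -> int:
        return int(self.data["person_id"].nunique())


@dataclass
class SyntheticTruth:
    """Exact copy of the generating parameters plus realized latent effects."""

    config: PanelGenConfig
    person_effects: np.ndarray  # latent b_i, persons x variables, unit variance
    person_means: np.ndarray    # realized between-level values incl. covariates
    age: np.ndarray
    gender: np.ndarray
    binary_thresholds: dict


def _chol_psd(m: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semi-definite matrices."""
    lam, q = np.linalg.eigh(m)
    return q @ np.diag(np.sqrt(np.clip(lam, 0.0, None)))


def generate_panel(config: PanelGenConfig):
    """Generate a two-level panel; returns ``(PanelDataset, SyntheticTruth)``."""
    rng = np.random.default_rng(config.seed)
    m, n, k = config.n_persons, config.n_obs_per_person, len(config.variables)
    icc = np.asarray(config.icc, dtype=float)
    mu = np.zeros(k) if config.means is None else np.asarray(config.means, float)

    Lb = _chol_psd(config.matrix("between_corr"))
    Lw = _chol_psd(config.matrix("within_corr"))
    b = rng.standard_normal((m, k)) @ Lb.T
    w = rng.standard_normal((m, n, k)) @ Lw.T

    age = rng.uniform(*config.age_range, size=m)
    gender = rng.integers(0, 2, size=m)
    lo, hi = config.age_range
    age_sd = (hi - lo) / np.sqrt(12.0)
    age_std = (age - (lo + hi) / 2.0) / age_sd if age_sd > 0 else np.zeros(m)
    gender_c = gender - 0.5

    person_means = mu + np.sqrt(icc) * b
    cov_var = np.zeros(k)  # extra between variance added by covariates
    for name, (b_age, b_gen) in config.covariate_effects.items():
        j = config.variables.index(name)
        person_means[:, j] += b_age * age_std + b_gen * gender_c
        cov_var[j] = b_age ** 2 + 0.25 * b_gen ** 2

    y = person_means[:, None, :] + np.sqrt(1.0 - icc) * w

    binary_thresholds = {}
    persons = pd.DataFrame({
        "person_id": [f"p{i:04d}" for i in range(m)],
        "age": age, "gender": gender,
    })
    long_frames = []
    for j, name in enumerate(config.variables):
        if name in config.binary_specs:
            p = float(config.binary_specs[name])
            if not 0 < p < 1:
                raise ParameterError(f"binary probability for {name!r} not in (0,1)")
            latent_sd = np.sqrt(icc[j] + cov_var[j])
            thr = mu[j] + latent_sd * stats.norm.ppf(1.0 - p)
            binary_thresholds[name] = thr
            persons[name] = (person_means[:, j] > thr).astype(int)
        else:
            frame = pd.DataFrame({
                "person_id": np.repeat(persons["person_id"].to_numpy(), n),
                "day_index": np.tile(np.arange(n), m),
                "variable": name,
                "value": y[:, :, j].ravel(),
            })
            long_frames.append(frame)

    data = (
        pd.concat(long_frames, ignore_index=True) if long_frames
        else pd.DataFrame(columns=["person_id", "day_index", "variable", "value"])
    )
    flags = [] if n > 1 else ["no within-person information"]
    panel = PanelDataset(data=data, persons=persons, flags=flags)
    truth = SyntheticTruth(config=config, person_effects=b,
                           person_means=person_means, age=age, gender=gender,
                           binary_thresholds=binary_thresholds)
    return panel, truth
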