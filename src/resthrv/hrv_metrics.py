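"""Time- and frequency-domain resting-HRV metrics.

RMSSD and SDNN are computed directly on the (cleaned) IBI annotations of a
segment; spectral band powers come from a Welch periodogram of the uniformly
resampled tachogram.  Band limits default to the Task Force standard
(VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz) and are overridable.
VLF is suppressed for recordings shorter than five minutes, for which the
band is not resolvable or recommended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

logger = logging.getLogger("resthrv")


class MetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


@dataclass(frozen=True)
class BandDefinition:
    """A half-open spectral band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise MetricError(f"band {self.name}: need 0 < low < high")


DEFAULT_BANDS = (
    BandDefinition("VLF", 0.0033, 0.04),
    BandDefinition("LF", 0.04, 0.15),
    BandDefinition("HF", 0.15, 0.40),
)


@dataclass
class HRVRecord:
    """Per-person-per-day resting-HRV summary."""

    person_id: str
    day_index: int
    rmssd: float
    sdnn: float
    hf: float = np.nan
    lf: float = np.nan
    vlf: float = np.nan
    lf_hf: float = np.nan
    n_valid_segments: int = 0
    context: str = "night"
    log_rmssd: float = np.nan
    extra_logs: dict = field(default_factory=dict)


def rmssd(ibis) -> float:
    """Root mean square of successive IBI differences, in ms."""
    x = np.asarray(ibis, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise MetricError("RMSSD undefined for fewer than 2 IBIs")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def sdnn(ibis) -> float:
    """Sample standard deviation (n-1 denominator) of the IBIs, in ms."""
    x = np.asarray(ibis, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise MetricError("SDNN undefined for fewer than 2 IBIs")
    return float(np.std(x, ddof=1))


def band_powers(tachogram, rate: float = 4.0,
                bands=DEFAULT_BANDS, duration_s: float | None = None) -> dict:
    """Integrate a Welch PSD of the mean-removed tachogram over each band.

    Powers are in ms^2; total power over (0, Nyquist] approximates the
    tachogram variance (Parseval).  When ``duration_s`` is below 300 s the
    VLF band is omitted with a warning.

    Uses half-overlapping Hann windows with per-window linear detrend;
    ``nperseg`` is the full signal up to 512 samples so the lowest bands
    remain resolvable for 5-minute segments.
    """
    x = np.asarray(tachogram, dtype=float)
    if x.size < 64:
        raise MetricError("tachogram too short for spectral analysis (<64 samples)")
    if duration_s is None:
        duration_s = x.size / rate
    nperseg = min(x.size, 512)
    f, psd = welch(
        x - x.mean(), fs=rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="linear",
    )
    df = f[1] - f[0]
    out = {}
    for band in bands:
        if band.name == "VLF" and duration_s < 300.0:
            logger.warning(
                "VLF omitted: recording %.0f s is below the 5-minute minimum",
                duration_s,
            )
            continue
        sel = (f >= band.low) & (f < band.high)
        out[band.name] = float(np.sum(psd[sel]) * df)
    return out


def total_power(tachogram, rate: float = 4.0) -> float:
    """Integrated PSD over (0, Nyquist]; approximates the variance."""
    x = np.asarray(tachogram, dtype=float)
    nperseg = min(x.size, 512)
    f, psd = welch(
        x - x.mean(), fs=rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="linear",
    )
    df = f[1] - f[0]
    return float(np.sum(psd[f > 0]) * df)


def lf_hf_ratio(lf: float, hf: float) -> float:
    """LF/HF power ratio; undefined when HF is zero."""
    if hf <= 0:
        raise MetricError("LF/HF ratio undefined: HF power is zero")
    return float(lf / hf)


def segment_metrics(seg, rate: float = 4.0, bands=DEFAULT_BANDS) -> dict:
    """All metrics for one clean segment (RMSSD/SDNN on beats, bands on tachogram)."""
    from .ibi_pipeline import interpolate

    ib = seg.beat_ibis[np.isfinite(seg.beat_ibis)]
    out = {"rmssd": rmssd(ib), "sdnn": sdnn(ib)}
    tach = interpolate(seg, rate)
    powers = band_powers(tach, rate, bands, duration_s=seg.duration_s)
    out["hf"] = powers.get("HF", np.nan)
    out["lf"] = powers.get("LF", np.nan)
    out["vlf"] = powers.get("VLF", np.nan)
    hf = out["hf"]
    out["lf_hf"] = lf_hf_ratio(out["lf"], hf) if hf and hf > 0 else np.nan
    return out


def aggregate_daily(seg_metrics: list[dict], person_id: str, day_index: int,
                    context: str = "night") -> HRVRecord | None:
    """Unweighted mean of each metric across a person-day's valid segments.

    Returns ``None`` (logged) when no valid segments exist for the day.
    """
    if not seg_metrics:
        logger.info("person %s day %s: no valid segments, no HRV record",
                    person_id, day_index)
        return None
    keys = ("rmssd", "sdnn", "hf", "lf", "vlf", "lf_hf")
    means = {}
    for k in keys:
        vals = np.array([m.get(k, np.nan) for m in seg_metrics], dtype=float)
        vals = vals[np.isfinite(vals)]
        means[k] = float(vals.mean()) if vals.size else np.nan
    return HRVRecord(person_id=person_id, day_index=day_index,
                     n_valid_segments=len(seg_metrics), context=context, **means)


def log_transform(record: HRVRecord, metrics=("rmssd",)) -> HRVRecord:
    """Store the natural log of the named metrics alongside the raw values.

    Non-positive values skip the transform for that record (logged); the raw
    value is always retained.
    """
    for name in metrics:
        value = getattr(record, name, np.nan)
        if not np.isfinite(value) or value <= 0:
            logger.warning("log transform skipped for %s=%r (person %s day %s)",
                           name, value, record.person_id, record.day_index)
            continue
        if name == "rmssd":
            record.log_rmssd = float(np.log(value))
        else:
            record.extra_logs[f"log_{name}"] = float(np.log(value))
    return record
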