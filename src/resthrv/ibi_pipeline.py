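"""Preprocessing of raw interbeat-interval (IBI) streams into clean 5-minute segments.

The nocturnal pipeline mirrors common consumer-wearable practice: restrict
beats to the 12am-5am clock window, tile the window with 5-minute segments,
keep only segments with at least 70% IBI coverage and no recorded steps,
remove physiologically implausible or locally deviant IBIs, and spline-resample
each surviving segment to a uniform tachogram for spectral analysis.

Timestamps are milliseconds on a local clock; ``clock_offset_ms`` on a
:class:`BeatSeries` maps recording time to clock time (0 = local midnight).
All intervals are half-open ``[start, end)``; a beat exactly on a segment
boundary belongs to the later segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger("resthrv")

MS_PER_MIN = 60_000
NIGHT_WINDOW_MS = (0, 5 * 3600 * 1000)  # [12am, 5am) on the local clock
SEGMENT_MS = 300_000  # 5 minutes

#: Absolute physiological IBI range in ms; values outside are spurious.
ABS_IBI_RANGE = (300.0, 2000.0)
#: Relative deviation from the running 5-beat median that flags a beat.
REL_DEVIATION = 0.25
MEDIAN_WINDOW = 5

# Segment validity reason codes
KEPT = "kept"
LOW_COMPLETENESS = "low_completeness"
MOVEMENT = "movement"
ARTIFACT_BURST = "artifact_burst"


class PipelineError(ValueError):
    """Raised for invalid inputs to the IBI pipeline."""


@dataclass
class BeatSeries:
    """Timestamped beats for one recording.

    ``timestamps`` are strictly increasing ms since the recording epoch;
    ``ibis`` has one entry per beat after the first and equals the timestamp
    differences (within 1 ms).
    """

    person_id: str
    recording_id: str
    timestamps: np.ndarray
    ibis: np.ndarray
    device_context: str = "night_watch"
    clock_offset_ms: float = 0.0
    day_index: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if self.timestamps.size:
            if np.any(np.diff(self.timestamps) <= 0):
                raise PipelineError("timestamps must be strictly increasing")
            if self.ibis.size != self.timestamps.size - 1:
                raise PipelineError("need one IBI per beat after the first")
            if self.ibis.size and np.any(self.ibis <= 0):
                raise PipelineError("IBIs must be positive")
            if self.ibis.size and np.max(
                np.abs(np.diff(self.timestamps) - self.ibis)
            ) > 1.0:
                raise PipelineError("IBIs inconsistent with timestamps (>1 ms)")

    @classmethod
    def from_timestamps(cls, person_id: str, recording_id: str,
                        timestamps: np.ndarray, **kw) -> "BeatSeries":
        ts = np.asarray(timestamps, dtype=float)
        return cls(person_id, recording_id, ts, np.diff(ts), **kw)

    @property
    def n_beats(self) -> int:
        return int(self.timestamps.size)

    @property
    def clock_timestamps(self) -> np.ndarray:
        return self.timestamps + self.clock_offset_ms


@dataclass
class Segment:
    """One half-open analysis window with its beats and validity state.

    ``beat_times`` are clock timestamps; ``beat_ibis`` is the IBI annotation
    of each beat (NaN for a beat whose predecessor is unknown, e.g. the first
    beat of the recording or a beat following a filtered-out one).
    """

    start: float
    end: float
    beat_times: np.ndarray
    beat_ibis: np.ndarray
    completeness: float = 0.0
    step_count: int = 0
    valid: str = KEPT

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / 1000.0

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


def window_night(series: BeatSeries, window: tuple = NIGHT_WINDOW_MS) -> BeatSeries:
    """Clip a recording to the nocturnal clock window (default [12am, 5am)).

    Beats outside the half-open window are dropped; the IBI of the first beat
    inside the window is discarded implicitly because its predecessor falls
    outside.  An empty result is returned flagged ``"no nocturnal data"``
    rather than raised.
    """
    lo, hi = window
    clock = series.clock_timestamps
    keep = (clock >= lo) & (clock < hi)
    kept = series.timestamps[keep]
    out = BeatSeries.from_timestamps(
        series.person_id, series.recording_id, kept,
        device_context=series.device_context,
        clock_offset_ms=series.clock_offset_ms,
        day_index=series.day_index, flags=list(series.flags),
    )
    if kept.size == 0:
        out.flags.append("no nocturnal data")
    return out


def segment(series: BeatSeries, seg_len: float = 300.0,
            window: tuple = NIGHT_WINDOW_MS) -> list[Segment]:
    """Tile the clock window with contiguous half-open segments.

    Every beat is assigned to exactly one segment by its clock timestamp
    (boundary beats go to the later segment).  Empty segments are returned
    with completeness 0 so that validity accounting stays exact.
    """
    if seg_len <= 0:
        raise PipelineError("seg_len must be positive")
    lo, hi = window
    seg_ms = seg_len * 1000.0
    n_seg = int(np.ceil((hi - lo) / seg_ms))
    clock = series.clock_timestamps
    ibis = np.concatenate([[np.nan], series.ibis]) if series.n_beats else np.array([])
    segments = []
    for k in range(n_seg):
        s, e = lo + k * seg_ms, min(lo + (k + 1) * seg_ms, hi)
        in_seg = (clock >= s) & (clock < e)
        seg = Segment(s, e, clock[in_seg], ibis[in_seg])
        seg.completeness = completeness(seg)
        if seg.completeness < 0.70:
            seg.valid = LOW_COMPLETENESS
        segments.append(seg)
    return segments


def completeness(seg: Segment) -> float:
    """Fraction of the segment covered by plausible IBIs, capped at 1.

    Coverage is the sum of IBI annotations of beats inside the segment.  IBIs
    above the absolute physiological bound (gap-spanning intervals from
    missing beats) do not count as coverage, and NaN annotations contribute
    nothing.
    """
    dur = seg.end - seg.start
    if dur <= 0 or seg.n_beats == 0:
        return 0.0
    ib = seg.beat_ibis
    ok = np.isfinite(ib) & (ib <= ABS_IBI_RANGE[1])
    return float(min(1.0, np.sum(ib[ok]) / dur))


def exclude_movement(segments: list[Segment], steps: pd.DataFrame,
                     missing_policy: str = "keep") -> list[Segment]:
    """Invalidate segments overlapping any minute with a positive step count.

    ``steps`` has columns ``minute_start_ms`` (clock) and ``steps``.  Minutes
    without a step record follow ``missing_policy``: ``"keep"`` (default,
    logged) or ``"drop"``.
    """
    if missing_policy not in ("keep", "drop"):
        raise PipelineError(f"unknown missing-step policy {missing_policy!r}")
    by_minute = {}
    if steps is not None and len(steps):
        by_minute = dict(
            zip(steps["minute_start_ms"].astype(float), steps["steps"].astype(float))
        )
    for seg in segments:
        if seg.valid != KEPT:
            continue
        minutes = np.arange(
            np.floor(seg.start / MS_PER_MIN) * MS_PER_MIN, seg.end, MS_PER_MIN
        )
        counts = [by_minute.get(m) for m in minutes]
        if any(c is not None and c > 0 for c in counts):
            seg.valid = MOVEMENT
            seg.step_count = int(sum(c for c in counts if c))
        elif any(c is None for c in counts):
            if missing_policy == "drop":
                seg.valid = MOVEMENT
            else:
                logger.warning(
                    "segment [%s, %s): missing step data for %d minute(s); kept",
                    seg.start, seg.end, sum(c is None for c in counts),
                )
    return segments


def filter_spurious(beat_times: np.ndarray, beat_ibis: np.ndarray,
                    abs_range: tuple = ABS_IBI_RANGE,
                    rel_threshold: float = REL_DEVIATION,
                    median_window: int = MEDIAN_WINDOW):
    """Remove spurious IBIs by an absolute range rule and a local-median rule.

    A beat is rejected when its IBI lies outside ``abs_range`` or deviates
    from the centred running median (window ``median_window`` beats) by more
    than ``rel_threshold``.  Passes are repeated until no further beat is
    rejected (removing an artifact sharpens the local median for its
    neighbours), so the filter is idempotent by construction.  Beats with
    NaN IBI annotations pass through untouched (they carry no interval
    evidence).  Returns ``(times, ibis, rejections)`` where ``rejections``
    is a list of ``(index, rule)`` records with indices into the original
    input.
    """
    times = np.asarray(beat_times, dtype=float)
    ibis = np.asarray(beat_ibis, dtype=float)
    if times.size == 0:
        return times, ibis, []
    orig_index = np.arange(times.size)
    rejections = []
    while times.size:
        ref = (
            pd.Series(ibis)
            .rolling(median_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            out_of_range = np.isfinite(ibis) & (
                (ibis < abs_range[0]) | (ibis > abs_range[1])
            )
            deviant = (
                np.isfinite(ibis)
                & np.isfinite(ref)
                & (ref > 0)
                & (np.abs(ibis - ref) / ref > rel_threshold)
            )
        reject = out_of_range | deviant
        if not reject.any():
            break
        rejections.extend(
            (int(orig_index[i]), "range" if out_of_range[i]
             else "median_deviation")
            for i in np.flatnonzero(reject)
        )
        keep = ~reject
        kept_ibis = ibis[keep].copy()
        # a surviving beat whose predecessor was rejected loses its interval
        prev_rejected = np.concatenate([[False], reject[:-1]])[keep]
        kept_ibis[prev_rejected] = np.nan
        times, ibis, orig_index = times[keep], kept_ibis, orig_index[keep]
    rejections.sort()
    return times, ibis, rejections


def filter_segment(seg: Segment, **kw) -> list:
    """Apply :func:`filter_spurious` in place; invalidate artifact bursts.

    A segment in which more than half of the beats are rejected is marked
    ``artifact_burst``.  Returns the rejection log.
    """
    n_before = seg.n_beats
    seg.beat_times, seg.beat_ibis, rejections = filter_spurious(
        seg.beat_times, seg.beat_ibis, **kw
    )
    if n_before and len(rejections) / n_before > 0.5 and seg.valid == KEPT:
        seg.valid = ARTIFACT_BURST
    return rejections


def interpolate(seg: Segment, rate: float = 4.0) -> np.ndarray:
    """Resample a segment's IBI annotations to a uniform tachogram.

    Cubic-spline interpolation of IBI (ms) versus beat time, evaluated at
    ``seg_len * rate`` uniform sample times across the segment; outside the
    span of observed beats the edge value is held.  Falls back to linear
    interpolation when fewer than four beats carry an IBI; fewer than two is
    an error.
    """
    ok = np.isfinite(seg.beat_ibis)
    t, v = seg.beat_times[ok], seg.beat_ibis[ok]
    if t.size < 2:
        raise PipelineError("uninterpolatable segment: fewer than 2 valid beats")
    n = int(round(seg.duration_s * rate))
    sample_t = seg.start + np.arange(n) * (1000.0 / rate)
    if t.size >= 4:
        out = CubicSpline(t, v)(sample_t)
    else:
        out = np.interp(sample_t, t, v)
    # hold edge values instead of extrapolating the spline
    return np.where(sample_t < t[0], v[0], np.where(sample_t > t[-1], v[-1], out))


def preprocess_recording(series: BeatSeries, steps: pd.DataFrame | None,
                         window: tuple = NIGHT_WINDOW_MS,
                         seg_len: float = 300.0,
                         missing_policy: str = "keep"):
    """Run the full nocturnal preprocessing chain for one recording.

    Returns ``(segments, rejection_log)``.  Morning chest-strap recordings
    (``device_context == "morning_strap"``) skip the night window and are
    treated as a single segment spanning the whole recording.
    """
    if series.device_context == "morning_strap":
        clock = series.clock_timestamps
        ibis = (
            np.concatenate([[np.nan], series.ibis]) if series.n_beats
            else np.array([])
        )
        start = clock[0] if clock.size else 0.0
        end = clock[-1] + 1 if clock.size else 1.0
        seg = Segment(start, end, clock, ibis)
        dur = end - start
        ok = np.isfinite(ibis) & (ibis <= ABS_IBI_RANGE[1])
        seg.completeness = float(min(1.0, np.sum(ibis[ok]) / dur)) if dur else 0.0
        segments = [seg]
    else:
        windowed = window_night(series, window)
        segments = segment(windowed, seg_len, window)
    rejection_log = []
    for i, seg in enumerate(segments):
        if seg.valid != KEPT:
            continue
        for idx, rule in filter_segment(seg):
            rejection_log.append(
                {"person_id": series.person_id, "recording_id": series.recording_id,
                 "segment": i, "beat_index": idx, "rule": rule}
            )
    if steps is not None and series.device_context != "morning_strap":
        exclude_movement(segments, steps, missing_policy)
    return segments, rejection_log


def validity_counts(segments: list[Segment]) -> dict:
    """Count segments by validity reason; the counts sum to the total."""
    counts = {KEPT: 0, LOW_COMPLETENESS: 0, MOVEMENT: 0, ARTIFACT_BURST: 0}
    for seg in segments:
        counts[seg.valid] = counts.get(seg.valid, 0) + 1
    return counts
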