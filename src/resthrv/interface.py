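"""Run configuration and CSV readers/writers for the HRV pipeline.

All tabular I/O is plain CSV with a one-line ``#``-prefixed header comment
recording the producing stage and the seed, which the readers skip.  The
formats:

* IBI CSV: ``person_id, recording_id, timestamp_ms, ibi_ms`` (one row per
  beat; ``ibi_ms`` empty for the first beat of a recording).
* Steps CSV: ``person_id, minute_start_ms, steps``.
* Panel CSV (long): ``person_id, day_index, variable, value``; person-level
  covariates and baselines live in a separate persons CSV
  (``person_id, age, gender, ...``).
* Truth sidecar: ``key = value`` text lines.

Configuration is a YAML mapping validated against :class:`RunConfig`;
unknown keys are errors, not warnings, so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import yaml

from .ibi_pipeline import BeatSeries, NIGHT_WINDOW_MS, ABS_IBI_RANGE

logger = logging.getLogger("resthrv")


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration keys/values."""


@dataclasses.dataclass
class RunConfig:
    """All tunables of a pipeline run, with their documented legal ranges."""

    ibi_csv: str | None = None
    steps_csv: str | None = None
    panel_csv: str | None = None
    persons_csv: str | None = None
    outdir: str = "."
    night_window_ms: tuple = NIGHT_WINDOW_MS
    segment_seconds: float = 300.0
    completeness_threshold: float = 0.70
    abs_ibi_range: tuple = ABS_IBI_RANGE
    rel_deviation: float = 0.25
    interp_rate_hz: float = 4.0
    aggregation: str = "segment_mean"
    lag_spec: str = "same_day"
    estimator: str = "ml_latent"
    covariates: tuple = ()
    log_transform: tuple = ()
    pairs: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.completeness_threshold <= 1:
            raise ConfigError("completeness_threshold must lie in (0, 1]")
        if self.segment_seconds <= 0:
            raise ConfigError("segment_seconds must be positive")
        if self.interp_rate_hz <= 0:
            raise ConfigError("interp_rate_hz must be positive")
        if self.rel_deviation <= 0:
            raise ConfigError("rel_deviation must be positive")
        lo, hi = self.abs_ibi_range
        if not 0 < lo < hi:
            raise ConfigError("abs_ibi_range must satisfy 0 < low < high")
        if self.aggregation not in ("segment_mean", "pooled_beats"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.estimator not in ("ml_latent", "moments_observed"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("night_window_ms", "abs_ibi_range", "covariates",
                    "log_transform", "pairs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: str, stage: str, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# resthrv {stage} seed={seed}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: str, required: tuple) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ConfigError(f"{path}: empty input file")
    missing = set(required) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


# --- IBI recordings ---------------------------------------------------------

def write_ibi_csv(series_list, path: str, seed=0) -> None:
    frames = []
    for s in series_list:
        ibi = np.concatenate([[np.nan], s.ibis]) if s.n_beats else np.array([])
        frames.append(pd.DataFrame({
            "person_id": s.person_id, "recording_id": s.recording_id,
            "timestamp_ms": s.timestamps, "ibi_ms": ibi,
        }))
    _write_csv(pd.concat(frames, ignore_index=True), path, "ibi", seed)


def read_ibi_csv(path: str) -> list:
    df = _read_csv(path, ("person_id", "recording_id", "timestamp_ms", "ibi_ms"))
    out = []
    day_counter: dict = {}
    for (pid, rid), sub in df.groupby(["person_id", "recording_id"], sort=True):
        sub = sub.sort_values("timestamp_ms")
        bad = sub["timestamp_ms"].isna()
        if bad.any():
            raise ConfigError(
                f"{path}: malformed timestamp in row(s) "
                f"{list(sub.index[bad][:3])} for recording {pid}/{rid}"
            )
        day = day_counter.get(pid, 0)  # recordings per person in id order
        day_counter[pid] = day + 1
        out.append(BeatSeries.from_timestamps(
            str(pid), str(rid), sub["timestamp_ms"].to_numpy(float),
            day_index=day))
    return out


def write_steps_csv(steps: pd.DataFrame, path: str, seed=0) -> None:
    _write_csv(steps[["person_id", "minute_start_ms", "steps"]], path,
               "steps", seed)


def read_steps_csv(path: str) -> pd.DataFrame:
    return _read_csv(path, ("person_id", "minute_start_ms", "steps"))


# --- Panels -----------------------------------------------------------------

def write_panel_csv(panel, path: str, persons_path: str | None = None,
                    seed=0) -> None:
    _write_csv(panel.data, path, "panel", seed)
    if persons_path:
        _write_csv(panel.persons, persons_path, "persons", seed)


def read_panel_csv(path: str, persons_path: str | None = None):
    from .synthetic_data import PanelDataset

    data = _read_csv(path, ("person_id", "day_index", "variable", "value"))
    if persons_path:
        persons = _read_csv(persons_path, ("person_id",))
    else:
        persons = pd.DataFrame({"person_id": data["person_id"].unique()})
    return PanelDataset(data=data, persons=persons)


# --- Truth sidecar ----------------------------------------------------------

def write_truth_sidecar(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        for key, value in truth.items():
            fh.write(f"{key} = {value!r}\n")


def read_truth_sidecar(path: str) -> dict:
    import ast

    out = {}
    with open(path) as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            try:
                out[key.strip()] = ast.literal_eval(value.strip())
            except (ValueError, SyntaxError):
                out[key.strip()] = value.strip()
    return out


# --- Result tables ----------------------------------------------------------

def write_hrv_csv(records, path: str, seed=0) -> None:
    rows = [{
        "person_id": r.person_id, "day_index": r.day_index,
        "context": r.context, "rmssd": r.rmssd, "sdnn": r.sdnn,
        "hf": r.hf, "lf": r.lf, "vlf": r.vlf, "lf_hf": r.lf_hf,
        "log_rmssd": r.log_rmssd, "n_valid_segments": r.n_valid_segments,
    } for r in records]
    _write_csv(pd.DataFrame(rows), path, "hrv", seed)


def read_hrv_csv(path: str) -> pd.DataFrame:
    return _read_csv(path, ("person_id", "day_index", "rmssd", "sdnn"))


def write_report_csv(df: pd.DataFrame, path: str, stage: str, seed=0) -> None:
    _write_csv(df, path, stage, seed)
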