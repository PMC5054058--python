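"""Threshold-based flagging and run-length episode detection.

An ambulatory epoch is flagged when its measured RMSSD lies strictly below
the expected RMSSD predicted from concurrent acceleration minus ``k`` times
the calibration SE.  Maximal runs of at least ``min_run`` consecutive
flagged epochs form episodes; invalid epochs break runs unless explicitly
bridged via ``max_gap``.  Episodes are then coded onto an hourly grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ModelStatusError, PersonModel
from .io import HOUR_SECONDS, EpochSeries, ValidationError


@dataclass(frozen=True)
class Episode:
    start_index: int
    length: int
    start_time: float


@dataclass
class EpisodeSet:
    """Maximal qualifying runs plus the per-epoch flags they came from.

    ``flags`` is a nullable boolean array: True/False for valid epochs,
    NA where the epoch was invalid.
    """

    person_id: str
    episodes: list[Episode]
    flags: pd.arrays.BooleanArray
    min_run: int
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        prev_end = -1
        for ep in self.episodes:
            if ep.length < self.min_run:
                raise ValidationError("episode shorter than min_run")
            if ep.start_index <= prev_end:
                raise ValidationError("episodes must be sorted and non-overlapping")
            prev_end = ep.start_index + ep.length - 1

    def __len__(self) -> int:
        return len(self.episodes)

    def spans(self) -> list[tuple[float, float]]:
        """Half-open time spans ``[start, end)`` of each episode."""
        return [
            (ep.start_time, ep.start_time + ep.length * self.epoch_length)
            for ep in self.episodes
        ]


def _require_ok(model: PersonModel) -> None:
    if not model.ok:
        raise ModelStatusError(
            f"person {model.person_id}: model status is {model.status.value!r}; "
            "detection requires an ok model"
        )


def expected_rmssd(model: PersonModel, acceleration) -> np.ndarray | float:
    """Predicted RMSSD at the given acceleration(s), floored before inversion."""
    _require_ok(model)
    acc = np.asarray(acceleration, dtype=float)
    if np.any(acc[~np.isnan(acc)] < 0):
        raise ValidationError("acceleration must be >= 0")
    out = model.b0 + model.b1 / np.maximum(acc, model.accel_floor)
    return float(out) if np.isscalar(acceleration) else out


def threshold(model: PersonModel, acceleration) -> np.ndarray | float:
    """Detection threshold: expected RMSSD minus ``k`` times the calibration SE."""
    return expected_rmssd(model, acceleration) - model.k * model.se


def flag_epochs(model: PersonModel, day: EpochSeries) -> pd.arrays.BooleanArray:
    """Per-epoch flags: True where RMSSD < threshold, NA for invalid epochs."""
    _require_ok(model)
    flags = pd.array([pd.NA] * len(day), dtype="boolean")
    valid = day.valid
    if valid.any():
        thr = threshold(model, day.accel[valid])
        flags[np.flatnonzero(valid)] = day.rmssd[valid] < thr
    return flags


def _normalize_flags(flags) -> tuple[np.ndarray, np.ndarray]:
    """Split an arbitrary flag sequence into (is_true, is_missing) bool arrays."""
    arr = pd.array(flags, dtype="boolean")
    missing = np.asarray(arr.isna(), dtype=bool)
    true = arr.fillna(False).to_numpy(dtype=bool)
    return true, missing


def detect_episodes(
    flags,
    min_run: int = 15,
    person_id: str = "unknown",
    start_times=None,
    epoch_length: float = 30.0,
    max_gap: int = 0,
) -> EpisodeSet:
    """Find maximal runs of >= ``min_run`` consecutive flagged epochs.

    ``flags`` may contain True, False, and missing (None/NA) entries.  A
    False always breaks a run.  Missing entries break runs by default;
    with ``max_gap > 0``, interior gaps of at most ``max_gap`` consecutive
    missing epochs are bridged and count toward the episode span.
    """
    is_true, is_missing = _normalize_flags(flags)
    n = is_true.size
    if start_times is None:
        start_times = np.arange(n, dtype=float) * epoch_length
    start_times = np.asarray(start_times, dtype=float)
    if start_times.size != n:
        raise ValidationError("start_times must align with flags")

    # maximal runs of consecutive True, broken by False or missing
    runs: list[tuple[int, int]] = []  # (start, end) inclusive
    i = 0
    while i < n:
        if is_true[i]:
            j = i
            while j + 1 < n and is_true[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    if max_gap > 0:
        merged: list[tuple[int, int]] = []
        for run in runs:
            if merged:
                gap_lo, gap_hi = merged[-1][1] + 1, run[0] - 1
                gap = gap_hi - gap_lo + 1
                if gap <= max_gap and np.all(is_missing[gap_lo : gap_hi + 1]):
                    merged[-1] = (merged[-1][0], run[1])
                    continue
            merged.append(run)
        runs = merged

    episodes = [
        Episode(start_index=a, length=b - a + 1, start_time=float(start_times[a]))
        for a, b in runs
        if b - a + 1 >= min_run
    ]
    return EpisodeSet(
        person_id=person_id,
        episodes=episodes,
        flags=pd.array(flags, dtype="boolean"),
        min_run=min_run,
        epoch_length=epoch_length,
    )


def hour_grid(t0: float, t1: float) -> np.ndarray:
    """Hour-window start times (aligned to 3600 s) covering ``[t0, t1)``."""
    first = np.floor(t0 / HOUR_SECONDS) * HOUR_SECONDS
    starts = np.arange(first, t1, HOUR_SECONDS)
    return starts.astype(float)


def code_hours(
    episodes: EpisodeSet,
    day: EpochSeries,
    hour_starts=None,
    attribution: str = "overlap",
) -> pd.DataFrame:
    """Code hours 0/1 for episode presence, with per-hour epoch summaries.

    ``attribution='overlap'`` marks every hour an episode intersects;
    ``attribution='criterion_epoch'`` marks only the hour containing the
    epoch at which the episode first reaches ``min_run`` length.
    """
    if attribution not in ("overlap", "criterion_epoch"):
        raise ValidationError(f"unknown attribution mode {attribution!r}")
    if hour_starts is None:
        if len(day) == 0:
            hour_starts = np.array([])
        else:
            hour_starts = hour_grid(float(day.start[0]), float(day.end[-1]))
    hour_starts = np.asarray(hour_starts, dtype=float)

    rows = []
    for h0 in hour_starts:
        h1 = h0 + HOUR_SECONDS
        if attribution == "overlap":
            n_eps = sum(1 for a, b in episodes.spans() if a < h1 and b > h0)
        else:
            n_eps = 0
            for ep in episodes.episodes:
                t_crit = ep.start_time + (episodes.min_run - 1) * episodes.epoch_length
                if h0 <= t_crit < h1:
                    n_eps += 1
        in_hour = day.restrict(h0, h1)
        valid = in_hour & day.valid
        rows.append(
            {
                "person_id": episodes.person_id,
                "hour_end_s": h1,
                "add_hrvr": int(n_eps >= 1),
                "n_episodes": int(n_eps),
                "mean_rmssd": float(np.mean(day.rmssd[valid])) if valid.any() else np.nan,
                "mean_accel": float(np.mean(day.accel[valid])) if valid.any() else np.nan,
                "n_valid_epochs": int(valid.sum()),
            }
        )
    columns = [
        "person_id",
        "hour_end_s",
        "add_hrvr",
        "n_episodes",
        "mean_rmssd",
        "mean_accel",
        "n_valid_epochs",
    ]
    return pd.DataFrame(rows, columns=columns)


def detect_person(
    model: PersonModel,
    day: EpochSeries,
    hour_starts=None,
    attribution: str = "overlap",
    max_gap: int = 0,
) -> tuple[EpisodeSet, pd.DataFrame]:
    """Full per-person detection: flags -> episodes -> hourly coding."""
    flags = flag_epochs(model, day)
    episodes = detect_episodes(
        flags,
        min_run=model.min_run,
        person_id=model.person_id,
        start_times=day.start,
        epoch_length=day.epoch_length,
        max_gap=max_gap,
    )
    hourly = code_hours(episodes, day, hour_starts=hour_starts, attribution=attribution)
    return episodes, hourly
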