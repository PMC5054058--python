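"""Tabular I/O and shared domain types.

All file formats are plain comma-separated text with a single header row,
decimal points, and times in seconds from recording start.  Missing values
are encoded as empty fields and surfaced as missing (NaN), never as zero.

File kinds
----------
ibi file          : ``timestamp_s, ibi_ms``
accel file        : ``timestamp_s, accel_g`` or ``timestamp_s, x_g, y_g, z_g``
epoch file        : ``start_s, rmssd_ms, accel_g, valid``
phase annotation  : ``label, start_s, end_s`` (labels: rest, standing,
                    lying, cycling, stairs)
hourly report     : ``person_id, hour_end_s, worry_count, stress_count`` plus
                    optional numeric columns (affect scales, durations, ...)
person model file : one row per person, see :func:`write_models`
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PHASE_LABELS = ("rest", "standing", "lying", "cycling", "stairs")

REPORT_REQUIRED_COLUMNS = ("person_id", "hour_end_s", "worry_count", "stress_count")

HOUR_SECONDS = 3600.0


class FormatError(ValueError):
    """A file could not be parsed (message names the offending line)."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


class MissingPhaseError(ValidationError):
    """A required calibration phase is absent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class IbiStream:
    """Ordered interbeat intervals for one person.

    ``time`` holds the timestamp (s since recording start) at which each
    interval *ends*; ``ibi`` is the interval length in ms.  ``valid`` marks
    samples retained by artifact cleaning; raw streams start all-valid.
    """

    person_id: str
    time: np.ndarray
    ibi: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ibi = np.asarray(self.ibi, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.time.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time.size == self.ibi.size == self.valid.size):
            raise ValidationError("time, ibi and valid must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            idx = int(np.argmax(np.diff(self.time) <= 0))
            raise ValidationError(
                f"timestamps must be strictly increasing (violated at sample {idx + 1})"
            )
        if np.any(self.ibi <= 0):
            raise ValidationError("all ibi values must be > 0")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) timestamp; (0, 0) for an empty stream."""
        if not len(self):
            return (0.0, 0.0)
        return (float(self.time[0]), float(self.time[-1]))


@dataclass
class AccelStream:
    """Acceleration-magnitude samples (g) for one person."""

    person_id: str
    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.size != self.value.size:
            raise ValidationError("time and value must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(self.value < 0):
            raise ValidationError("acceleration magnitude must be >= 0")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def span(self) -> tuple[float, float]:
        if not len(self):
            return (0.0, 0.0)
        return (float(self.time[0]), float(self.time[-1]))


@dataclass
class EpochSeries:
    """Aligned epochs of RMSSD (ms) and mean acceleration (g).

    Epoch windows are half-open ``[start, start + epoch_length)`` and start
    times form an arithmetic sequence with step ``epoch_length``.  Missing
    RMSSD/acceleration is NaN; an epoch with any missing field is never
    valid (the constructor enforces this by clearing the flag).
    """

    person_id: str
    start: np.ndarray
    rmssd: np.ndarray
    accel: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.rmssd = np.asarray(self.rmssd, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.epoch_length <= 0:
            raise ValidationError("epoch_length must be > 0")
        n = self.start.size
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (n == self.rmssd.size == self.accel.size == self.valid.size):
            raise ValidationError("epoch columns must have equal length")
        if n > 1:
            steps = np.diff(self.start)
            if not np.allclose(steps, self.epoch_length, rtol=0, atol=1e-6):
                bad = int(np.argmax(~np.isclose(steps, self.epoch_length, rtol=0, atol=1e-6)))
                raise ValidationError(
                    f"epoch starts must advance by epoch_length={self.epoch_length} "
                    f"(violated between epochs {bad} and {bad + 1}: step {steps[bad]})"
                )
        with np.errstate(invalid="ignore"):
            if np.any(self.rmssd < 0):
                raise ValidationError("rmssd must be >= 0 where present")
            if np.any(self.accel < 0):
                raise ValidationError("acceleration must be >= 0 where present")
        # missing fields force invalidity
        self.valid = self.valid & ~np.isnan(self.rmssd) & ~np.isnan(self.accel)

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.epoch_length

    def restrict(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of epochs whose start lies in ``[t0, t1)``."""
        return (self.start >= t0) & (self.start < t1)


@dataclass(frozen=True)
class Phase:
    """One labeled interval of the scripted calibration protocol."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValidationError(
                f"unknown phase label {self.label!r}; expected one of {PHASE_LABELS}"
            )
        if not self.end > self.start:
            raise ValidationError(f"phase {self.label!r}: end must exceed start")


def _check_phases(phases: Sequence[Phase]) -> list[Phase]:
    ordered = sorted(phases, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"phases {a.label!r} and {b.label!r} overlap "
                f"([{a.start}, {a.end}) vs [{b.start}, {b.end}))"
            )
    return ordered


@dataclass
class CalibrationSession:
    """Phase-labeled epoch data from the scripted exercise protocol."""

    person_id: str
    phases: list[Phase]
    epochs: EpochSeries

    def __post_init__(self) -> None:
        self.phases = _check_phases(self.phases)

    @property
    def has_rest(self) -> bool:
        return any(p.label == "rest" for p in self.phases)

    def phase_mask(self, label: str) -> np.ndarray:
        """Mask of epochs whose start falls in any window with ``label``."""
        mask = np.zeros(len(self.epochs), dtype=bool)
        for p in self.phases:
            if p.label == label:
                mask |= self.epochs.restrict(p.start, p.end)
        return mask


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_rows(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file, expected a header row")
    return rows


def _parse_float(cell: str, path, lineno: int, column: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"{path}, line {lineno}: cannot parse {column}={cell!r} as a number"
        ) from None


def read_ibi(path, person_id: str | None = None) -> IbiStream:
    """Read a two-column ``timestamp_s, ibi_ms`` file."""
    rows = _open_rows(path)
    pid = person_id if person_id is not None else Path(path).stem
    times: list[float] = []
    ibis: list[float] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise FormatError(f"{path}, line {lineno}: expected 2 fields, got {len(row)}")
        times.append(_parse_float(row[0], path, lineno, "timestamp_s"))
        ibis.append(_parse_float(row[1], path, lineno, "ibi_ms"))
    return IbiStream(pid, np.array(times), np.array(ibis))


def read_accel(path, person_id: str | None = None) -> AccelStream:
    """Read an acceleration file: one magnitude column or three axis columns.

    Three-axis input is collapsed to the per-sample Euclidean norm.
    """
    rows = _open_rows(path)
    pid = person_id if person_id is not None else Path(path).stem
    header = [c.strip() for c in rows[0]]
    n_axes = len(header) - 1
    if n_axes not in (1, 3):
        raise FormatError(
            f"{path}: expected 2 or 4 columns (time + magnitude, or time + x/y/z), "
            f"got {len(header)}"
        )
    times: list[float] = []
    values: list[float] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != n_axes + 1:
            raise FormatError(
                f"{path}, line {lineno}: expected {n_axes + 1} fields, got {len(row)}"
            )
        times.append(_parse_float(row[0], path, lineno, "timestamp_s"))
        axes = [_parse_float(c, path, lineno, f"axis_{i}") for i, c in enumerate(row[1:])]
        values.append(math.hypot(*axes) if n_axes == 3 else axes[0])
    return AccelStream(pid, np.array(times), np.array(values))


def read_epochs(path, person_id: str | None = None, epoch_length: float = 30.0) -> EpochSeries:
    """Read a four-column ``start_s, rmssd_ms, accel_g, valid`` epoch file."""
    rows = _open_rows(path)
    pid = person_id if person_id is not None else Path(path).stem
    starts: list[float] = []
    rmssd: list[float] = []
    accel: list[float] = []
    valid: list[bool] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 4:
            raise FormatError(f"{path}, line {lineno}: expected 4 fields, got {len(row)}")
        starts.append(_parse_float(row[0], path, lineno, "start_s"))
        rmssd.append(
            math.nan if not row[1].strip() else _parse_float(row[1], path, lineno, "rmssd_ms")
        )
        accel.append(
            math.nan if not row[2].strip() else _parse_float(row[2], path, lineno, "accel_g")
        )
        cell = row[3].strip().lower()
        if cell in ("1", "true"):
            valid.append(True)
        elif cell in ("0", "false", ""):
            valid.append(False)
        else:
            raise FormatError(f"{path}, line {lineno}: cannot parse valid={row[3]!r}")
    return EpochSeries(
        pid,
        np.array(starts),
        np.array(rmssd),
        np.array(accel),
        np.array(valid, dtype=bool),
        epoch_length=epoch_length,
    )


def write_epochs(series: EpochSeries, path) -> None:
    df = pd.DataFrame(
        {
            "start_s": series.start,
            "rmssd_ms": series.rmssd,
            "accel_g": series.accel,
            "valid": series.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, na_rep="")


def read_calibration_annotation(path) -> list[Phase]:
    """Read a ``label, start_s, end_s`` phase annotation file."""
    rows = _open_rows(path)
    phases: list[Phase] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 3:
            raise FormatError(f"{path}, line {lineno}: expected 3 fields, got {len(row)}")
        label = row[0].strip()
        start = _parse_float(row[1], path, lineno, "start_s")
        end = _parse_float(row[2], path, lineno, "end_s")
        phases.append(Phase(label, start, end))
    return _check_phases(phases)


def write_calibration_annotation(phases: Sequence[Phase], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "start_s", "end_s"])
        for p in phases:
            writer.writerow([p.label, repr(p.start), repr(p.end)])


def read_reports(path) -> pd.DataFrame:
    """Read an hourly self-report table and validate its invariants."""
    df = pd.read_csv(path)
    missing = [c for c in REPORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["person_id"] = df["person_id"].astype(str)
    return validate_reports(df)


def validate_reports(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("worry_count", "stress_count"):
        counts = df[col].dropna()
        if (counts < 0).any():
            raise ValidationError(f"{col} must be >= 0")
        if not np.allclose(counts, counts.round()):
            raise ValidationError(f"{col} must be an integer count")
    for pid, grp in df.groupby("person_id"):
        ends = np.sort(grp["hour_end_s"].to_numpy(dtype=float))
        if ends.size != np.unique(ends).size:
            raise ValidationError(f"person {pid}: duplicated report hours")
        if ends.size > 1 and np.any(np.diff(ends) < HOUR_SECONDS - 1e-6):
            raise ValidationError(
                f"person {pid}: hour windows overlap (ends closer than 3600 s)"
            )
    return df


def write_reports(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")


# person-model file -----------------------------------------------------------

MODEL_COLUMNS = (
    "person_id",
    "b0",
    "b1",
    "se",
    "r2",
    "b1_pvalue",
    "resting_rmssd",
    "status",
    "k",
    "min_run",
    "accel_floor",
    "n_valid_epochs",
)


def write_models(models, path) -> None:
    """Write person models (one row each); accepts a single model or a list."""
    from .calibration import PersonModel  # local import avoids a cycle

    if isinstance(models, PersonModel):
        models = [models]
    rows = []
    for m in models:
        rows.append(
            {
                "person_id": m.person_id,
                "b0": m.b0,
                "b1": m.b1,
                "se": m.se,
                "r2": m.r2,
                "b1_pvalue": m.b1_pvalue,
                "resting_rmssd": m.resting_rmssd,
                "status": m.status.value,
                "k": m.k,
                "min_run": m.min_run,
                "accel_floor": m.accel_floor,
                "n_valid_epochs": m.n_valid_epochs,
            }
        )
    pd.DataFrame(rows, columns=MODEL_COLUMNS).to_csv(path, index=False, na_rep="")


def read_models(path) -> dict:
    """Read a person-model file into ``{person_id: PersonModel}``."""
    from .calibration import ModelStatus, PersonModel

    df = pd.read_csv(path)
    missing = [c for c in MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = {}
    for _, row in df.iterrows():
        model = PersonModel(
            person_id=str(row["person_id"]),
            b0=float(row["b0"]),
            b1=float(row["b1"]),
            se=float(row["se"]),
            r2=float(row["r2"]),
            b1_pvalue=float(row["b1_pvalue"]),
            resting_rmssd=float(row["resting_rmssd"]),
            status=ModelStatus(row["status"]),
            k=float(row["k"]),
            min_run=int(row["min_run"]),
            accel_floor=float(row["accel_floor"]),
            n_valid_epochs=int(row["n_valid_epochs"]),
        )
        out[model.person_id] = model
    return out


# episode / hourly files ------------------------------------------------------


def write_episodes(episode_sets, path) -> None:
    """Write detected episodes: ``person_id, start_index, length_epochs, start_s``."""
    if not isinstance(episode_sets, (list, tuple)):
        episode_sets = [episode_sets]
    rows = []
    for es in episode_sets:
        for ep in es.episodes:
            rows.append(
                {
                    "person_id": es.person_id,
                    "start_index": ep.start_index,
                    "length_epochs": ep.length,
                    "start_s": ep.start_time,
                }
            )
    cols = ["person_id", "start_index", "length_epochs", "start_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_hourly(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["person_id", "hour_end_s", "add_hrvr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["person_id"] = df["person_id"].astype(str)
    return df


def write_hourly(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")
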