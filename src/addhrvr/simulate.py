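"""Seeded synthetic calibration sessions, ambulatory days, and self-reports.

Data are generated from a known inverse movement->RMSSD law with Gaussian
epoch noise, a two-state (quiet/bout) movement process, and planted
suppression windows whose depth is expressed in multiples of the person's
calibration SE.  Because suppression is applied relative to the generating
law, a plant of depth ``k`` sits exactly at the detector's threshold, which
makes detection power directly interpretable.

Everything is reproducible from ``(config, seed)``: each person and stream
draws from its own ``numpy`` generator derived from the top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ModelStatus, PersonModel, fit_inverse_model
from .detection import EpisodeSet, hour_grid
from .io import (
    HOUR_SECONDS,
    CalibrationSession,
    EpochSeries,
    Phase,
    ValidationError,
)


class ConfigError(ValueError):
    """Simulation configuration is inconsistent."""


@dataclass(frozen=True)
class PhasePlan:
    """One calibration phase: label, duration, target acceleration range."""

    label: str
    duration_s: float
    accel_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("phase duration must be > 0")
        lo, hi = self.accel_range
        if not 0 < lo <= hi:
            raise ConfigError("acceleration range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class PlantSpec:
    """A planted suppression window within the simulated day."""

    start_hour: float
    length_epochs: int
    depth: float  # multiples of the person's calibration SE

    def __post_init__(self) -> None:
        if self.length_epochs <= 0:
            raise ConfigError("plant length must be > 0")
        if self.depth <= 0:
            raise ConfigError("plant depth must be > 0")


def default_phase_plan() -> list[PhasePlan]:
    return [
        PhasePlan("rest", 180.0, (0.015, 0.035)),
        PhasePlan("standing", 180.0, (0.02, 0.05)),
        PhasePlan("lying", 180.0, (0.01, 0.03)),
        PhasePlan("cycling", 180.0, (0.08, 0.25)),
        PhasePlan("stairs", 120.0, (0.12, 0.40)),
    ]


@dataclass
class SimConfig:
    """Generator parameters; defaults sit in a realistic ambulatory regime
    (calibration RMSSD around 45 ms, mean acceleration around 0.05 g, worry
    on roughly 16 % and stress on roughly 7 % of hours)."""

    n_persons: int = 8
    true_b0: float = 21.56
    true_b1: float = 0.471
    epoch_noise_sd: float = 5.0  # calibration epoch noise (ms)
    day_noise_sd: float = 1.0  # ambulatory epoch noise (ms)
    epoch_length: float = 30.0
    phase_plan: list[PhasePlan] = field(default_factory=default_phase_plan)
    day_hours: float = 24.0
    quiet_accel: tuple[float, float] = (0.01, 0.05)
    bout_rate_per_hour: float = 3.0
    bout_length_epochs: tuple[int, int] = (2, 10)
    bout_accel: tuple[float, float] = (0.08, 0.40)
    missing_rate: float = 0.0
    plants: list[PlantSpec] = field(
        default_factory=lambda: [
            PlantSpec(start_hour=3.0, length_epochs=20, depth=4.0),
            PlantSpec(start_hour=9.5, length_epochs=30, depth=4.0),
        ]
    )
    worry_p_base: float = 0.163
    worry_p_plant: float = 0.60
    stress_p_base: float = 0.068
    stress_p_plant: float = 0.12
    affect_pa_mean: float = 4.0
    affect_na_mean: float = 1.9
    affect_plant_shift: float = 0.8
    affect_sd: float = 0.8

    def __post_init__(self) -> None:
        for p in (
            self.worry_p_base,
            self.worry_p_plant,
            self.stress_p_base,
            self.stress_p_plant,
            self.missing_rate,
        ):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.day_hours <= 0 or self.epoch_length <= 0:
            raise ConfigError("day_hours and epoch_length must be > 0")
        if self.epoch_noise_sd < 0 or self.day_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class PersonTruth:
    """Generating-law parameters for one person."""

    b0: float
    b1: float
    se: float  # SE of the realized calibration RMSSD (threshold units)


@dataclass
class SyntheticTruth:
    """Planted-episode annotations for recovery scoring."""

    person_id: str
    truth: PersonTruth
    plant_windows: list[tuple[int, int]]  # (start_index, length) in epochs
    plant_depths: list[float]
    hour_starts: np.ndarray
    hour_flags: np.ndarray  # per hour: does any plant overlap the hour?
    epoch_length: float = 30.0

    @property
    def plant_spans(self) -> list[tuple[float, float]]:
        return [
            (a * self.epoch_length, (a + ln) * self.epoch_length)
            for a, ln in self.plant_windows
        ]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _law(cfg: SimConfig, accel: np.ndarray) -> np.ndarray:
    return cfg.true_b0 + cfg.true_b1 / accel


def simulate_calibration(
    cfg: SimConfig, person_seed: int, person_id: str = "sim"
) -> CalibrationSession:
    """Generate a phase-labeled calibration session from the inverse law."""
    rng = _rng(person_seed, 1)
    starts: list[float] = []
    accel: list[float] = []
    phases: list[Phase] = []
    t = 0.0
    for plan in cfg.phase_plan:
        n = int(np.floor(plan.duration_s / cfg.epoch_length + 1e-9))
        if n < 1:
            raise ConfigError(f"phase {plan.label!r} shorter than one epoch")
        phases.append(Phase(plan.label, t, t + n * cfg.epoch_length))
        for j in range(n):
            starts.append(t + j * cfg.epoch_length)
            accel.append(rng.uniform(*plan.accel_range))
        t += n * cfg.epoch_length
    accel_arr = np.array(accel)
    noise = rng.normal(0.0, cfg.epoch_noise_sd, accel_arr.size) if cfg.epoch_noise_sd else 0.0
    rmssd = np.clip(_law(cfg, accel_arr) + noise, 0.0, None)
    epochs = EpochSeries(
        person_id,
        np.array(starts),
        rmssd,
        accel_arr,
        np.ones(accel_arr.size, dtype=bool),
        epoch_length=cfg.epoch_length,
    )
    return CalibrationSession(person_id, phases, epochs)


def truth_from_calibration(session: CalibrationSession, cfg: SimConfig) -> PersonTruth:
    """Pair the generating law with the realized calibration SE."""
    y = session.epochs.rmssd[session.epochs.valid]
    se = float(np.std(y, ddof=1) / np.sqrt(y.size))
    return PersonTruth(b0=cfg.true_b0, b1=cfg.true_b1, se=se)


def _movement(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Two-state renewal process: quiet baseline plus random activity bouts."""
    accel = rng.uniform(*cfg.quiet_accel, size=n)
    epochs_per_hour = HOUR_SECONDS / cfg.epoch_length
    p_start = min(cfg.bout_rate_per_hour / epochs_per_hour, 1.0)
    starts = np.flatnonzero(rng.random(n) < p_start)
    for s in starts:
        length = int(rng.integers(cfg.bout_length_epochs[0], cfg.bout_length_epochs[1] + 1))
        intensity = rng.uniform(*cfg.bout_accel)
        accel[s : s + length] = intensity * rng.uniform(0.9, 1.1, size=len(accel[s : s + length]))
    return accel


def simulate_day(
    cfg: SimConfig, truth: PersonTruth, person_seed: int, person_id: str = "sim"
) -> tuple[EpochSeries, SyntheticTruth]:
    """Generate an ambulatory day with planted suppression windows.

    Within a plant, RMSSD is reduced by ``depth * truth.se`` below the
    generating law, so depth equals the threshold multiplier at which the
    plant becomes detectable.
    """
    rng = _rng(person_seed, 2)
    n = int(np.floor(cfg.day_hours * HOUR_SECONDS / cfg.epoch_length + 1e-9))
    starts = np.arange(n, dtype=float) * cfg.epoch_length
    accel = _movement(cfg, n, rng)
    noise = rng.normal(0.0, cfg.day_noise_sd, n) if cfg.day_noise_sd else np.zeros(n)
    rmssd = _law(cfg, accel) + noise

    windows: list[tuple[int, int]] = []
    depths: list[float] = []
    epochs_per_hour = HOUR_SECONDS / cfg.epoch_length
    for plant in cfg.plants:
        a = int(round(plant.start_hour * epochs_per_hour))
        if a < 0 or a + plant.length_epochs > n:
            raise ConfigError("plant window falls outside the simulated day")
        windows.append((a, plant.length_epochs))
        depths.append(plant.depth)
    windows_sorted = sorted(zip(windows, depths))
    for (w1, _), (w2, _) in zip(windows_sorted, windows_sorted[1:]):
        if w2[0] < w1[0] + w1[1]:
            raise ConfigError("plant windows overlap")
    for (a, ln), depth in zip(windows, depths):
        rmssd[a : a + ln] -= depth * truth.se
    rmssd = np.clip(rmssd, 0.0, None)

    valid = np.ones(n, dtype=bool)
    if cfg.missing_rate > 0:
        valid &= rng.random(n) >= cfg.missing_rate
    rmssd_out = np.where(valid, rmssd, np.nan)
    accel_out = np.where(valid, accel, np.nan)
    day = EpochSeries(
        person_id, starts, rmssd_out, accel_out, valid, epoch_length=cfg.epoch_length
    )

    hours = hour_grid(0.0, cfg.day_hours * HOUR_SECONDS)
    flags = np.zeros(hours.size, dtype=bool)
    for (a, ln) in windows:
        t0, t1 = a * cfg.epoch_length, (a + ln) * cfg.epoch_length
        flags |= (hours < t1) & (hours + HOUR_SECONDS > t0)
    truth_out = SyntheticTruth(
        person_id=person_id,
        truth=truth,
        plant_windows=windows,
        plant_depths=depths,
        hour_starts=hours,
        hour_flags=flags,
        epoch_length=cfg.epoch_length,
    )
    return day, truth_out


def simulate_reports(
    truth: SyntheticTruth, cfg: SimConfig, person_seed: int
) -> pd.DataFrame:
    """Hourly worry/stress indicators and affect ratings coupled to plants."""
    rng = _rng(person_seed, 3)
    rows = []
    for h0, planted in zip(truth.hour_starts, truth.hour_flags):
        p_worry = cfg.worry_p_plant if planted else cfg.worry_p_base
        p_stress = cfg.stress_p_plant if planted else cfg.stress_p_base
        shift = cfg.affect_plant_shift if planted else 0.0
        rows.append(
            {
                "person_id": truth.person_id,
                "hour_end_s": float(h0 + HOUR_SECONDS),
                "worry_count": int(rng.random() < p_worry),
                "stress_count": int(rng.random() < p_stress),
                "positive_affect": float(
                    np.clip(rng.normal(cfg.affect_pa_mean - shift, cfg.affect_sd), 1, 6)
                ),
                "negative_affect": float(
                    np.clip(rng.normal(cfg.affect_na_mean + shift, cfg.affect_sd), 1, 6)
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryMetrics:
    """Episode-level and hour-level agreement between plants and detections."""

    sensitivity: float
    precision: float | None  # None when nothing was detected
    hour_tp: int
    hour_fp: int
    hour_fn: int
    hour_tn: int


def evaluate_recovery(
    truth: SyntheticTruth, detected: EpisodeSet, hourly: pd.DataFrame | None = None
) -> RecoveryMetrics:
    """Score detections against the planted windows.

    Sensitivity is the fraction of plants overlapped by at least one
    detected episode; precision the fraction of detections overlapping at
    least one plant.  Hour-level confusion counts come from the coded hours
    when ``hourly`` is given.
    """
    if abs(truth.epoch_length - detected.epoch_length) > 1e-9:
        raise ValidationError("truth and detections use different epoch grids")
    det_spans = detected.spans()
    plant_spans = truth.plant_spans

    def overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    if plant_spans:
        hit = sum(1 for p in plant_spans if any(overlaps(p, d) for d in det_spans))
        sensitivity = hit / len(plant_spans)
    else:
        sensitivity = float("nan")
    if det_spans:
        good = sum(1 for d in det_spans if any(overlaps(d, p) for p in plant_spans))
        precision: float | None = good / len(det_spans)
    else:
        precision = None

    tp = fp = fn = tn = 0
    if hourly is not None and not hourly.empty:
        coded = dict(zip(hourly["hour_end_s"], hourly["add_hrvr"]))
        for h0, truth_flag in zip(truth.hour_starts, truth.hour_flags):
            code = bool(coded.get(h0 + HOUR_SECONDS, 0))
            if truth_flag and code:
                tp += 1
            elif truth_flag and not code:
                fn += 1
            elif code:
                fp += 1
            else:
                tn += 1
    return RecoveryMetrics(sensitivity, precision, tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# whole-dataset convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticPerson:
    person_id: str
    session: CalibrationSession
    model: PersonModel
    day: EpochSeries
    truth: SyntheticTruth
    reports: pd.DataFrame


def simulate_person(cfg: SimConfig, seed: int, index: int) -> SyntheticPerson:
    pid = f"p{index:03d}"
    person_seed_rng = _rng(seed, index)
    person_seed = int(person_seed_rng.integers(0, 2**31 - 1))
    session = simulate_calibration(cfg, person_seed, person_id=pid)
    model = fit_inverse_model(session)
    truth = truth_from_calibration(session, cfg)
    day, truth_out = simulate_day(cfg, truth, person_seed, person_id=pid)
    reports = simulate_reports(truth_out, cfg, person_seed)
    return SyntheticPerson(pid, session, model, day, truth_out, reports)


def simulate_dataset(cfg: SimConfig, seed: int) -> list[SyntheticPerson]:
    """Generate the full cohort; deterministic in ``(cfg, seed)``."""
    return [simulate_person(cfg, seed, i) for i in range(cfg.n_persons)]


def truth_model(truth: SyntheticTruth, cfg: SimConfig, k: float = 2.0, min_run: int = 15) -> PersonModel:
    """Detector model built from the generating law (oracle calibration)."""
    return PersonModel(
        person_id=truth.person_id,
        b0=truth.truth.b0,
        b1=truth.truth.b1,
        se=truth.truth.se,
        r2=1.0,
        b1_pvalue=0.0,
        status=ModelStatus.OK,
        k=k,
        min_run=min_run,
        epoch_length=cfg.epoch_length,
        n_valid_epochs=0,
    )
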