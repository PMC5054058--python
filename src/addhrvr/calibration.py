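"""Person-specific inverse movement->RMSSD model fitting and quality gates.

The calibration model is ``expected_rmssd = b0 + b1 / acceleration`` with
acceleration floored before inversion, fitted by ordinary least squares on
the transformed predictor ``1/acceleration`` over all valid calibration
epochs.  The detection threshold offset ``se`` defaults to the standard
error of the mean of the raw calibration RMSSD values (``sd/sqrt(n)``);
``sd`` and the regression's residual standard error are available as
configurable alternatives for sensitivity analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CalibrationSession, MissingPhaseError, ValidationError

DEFAULT_ACCEL_FLOOR = 0.005  # g; prevents unbounded 1/acceleration
MIN_FIT_EPOCHS = 6
R2_GATE = 0.25
ALPHA = 0.05

ERROR_QUANTITIES = ("sem", "sd", "residual_se")


class ModelStatus(enum.Enum):
    OK = "ok"
    EXCLUDED_LOW_R2 = "excluded_low_r2"
    EXCLUDED_NONSIGNIFICANT = "excluded_nonsignificant"
    EXCLUDED_NO_INVERSE_FIT = "excluded_no_inverse_fit"
    EXCLUDED_INSUFFICIENT_DATA = "excluded_insufficient_data"


class ModelStatusError(ValueError):
    """An excluded model was used where an ok model is required."""


@dataclass
class PersonModel:
    """Fitted calibration model plus detector configuration for one person.

    ``b0`` is the RMSSD level in the absence of acceleration, ``b1`` the
    change in RMSSD attributable to acceleration (via 1/acceleration).
    """

    person_id: str
    b0: float = np.nan
    b1: float = np.nan
    se: float = np.nan
    r2: float = np.nan
    b1_pvalue: float = np.nan
    resting_rmssd: float = np.nan
    status: ModelStatus = ModelStatus.EXCLUDED_INSUFFICIENT_DATA
    k: float = 2.0
    min_run: int = 15
    accel_floor: float = DEFAULT_ACCEL_FLOOR
    n_valid_epochs: int = 0
    b0_stderr: float = np.nan
    b1_stderr: float = np.nan
    error_quantity: str = "sem"

    def __post_init__(self) -> None:
        if not np.isnan(self.se) and self.se < 0:
            raise ValidationError("se must be >= 0")
        if not np.isnan(self.r2) and not 0 <= self.r2 <= 1 + 1e-12:
            raise ValidationError("r2 must lie in [0, 1]")
        if self.k < 0:
            raise ValidationError("k must be >= 0")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")
        if self.accel_floor <= 0:
            raise ValidationError("accel_floor must be > 0")
        if self.error_quantity not in ERROR_QUANTITIES:
            raise ValidationError(f"error_quantity must be one of {ERROR_QUANTITIES}")

    @property
    def ok(self) -> bool:
        return self.status is ModelStatus.OK

    epoch_length: float = 30.0

    @property
    def min_episode_minutes(self) -> float:
        """Minimum qualifying episode duration implied by the configuration."""
        return self.min_run * self.epoch_length / 60.0


def quality_gate(
    b1: float, r2: float, b1_pvalue: float, x_variance: float | None = None
) -> ModelStatus:
    """Classify a fitted model as ok or excluded.

    Exclusion reasons: a degenerate transformed regression (no variance in
    1/acceleration), no significant movement-RMSSD relation (p >= 0.05),
    explained variance below 25 %, or a non-inverse (b1 <= 0) curve.
    """
    if x_variance is not None and x_variance <= 0:
        return ModelStatus.EXCLUDED_NO_INVERSE_FIT
    if not np.isfinite(b1) or not np.isfinite(b1_pvalue):
        return ModelStatus.EXCLUDED_NO_INVERSE_FIT
    if b1_pvalue >= ALPHA:
        return ModelStatus.EXCLUDED_NONSIGNIFICANT
    if r2 < R2_GATE:
        return ModelStatus.EXCLUDED_LOW_R2
    if b1 <= 0:
        return ModelStatus.EXCLUDED_NO_INVERSE_FIT
    return ModelStatus.OK


def fit_inverse_model(
    session: CalibrationSession,
    accel_floor: float = DEFAULT_ACCEL_FLOOR,
    k: float = 2.0,
    min_run: int = 15,
    error_quantity: str = "sem",
) -> PersonModel:
    """Fit the inverse calibration model for one person.

    Uses every valid epoch of the session.  Fewer than six valid epochs
    yields an ``excluded_insufficient_data`` model rather than an error;
    exclusion is a data outcome, not a process failure.
    """
    epochs = session.epochs
    mask = epochs.valid
    n = int(mask.sum())
    resting = np.nan
    if session.has_rest:
        try:
            resting = resting_rmssd(session)
        except MissingPhaseError:
            pass
    base = PersonModel(
        person_id=session.person_id,
        resting_rmssd=resting,
        k=k,
        min_run=min_run,
        accel_floor=accel_floor,
        n_valid_epochs=n,
        error_quantity=error_quantity,
        epoch_length=epochs.epoch_length,
    )
    if n < MIN_FIT_EPOCHS:
        base.status = ModelStatus.EXCLUDED_INSUFFICIENT_DATA
        return base

    y = epochs.rmssd[mask]
    x = 1.0 / np.maximum(epochs.accel[mask], accel_floor)
    base.se = _error_quantity(y, x, error_quantity)
    if np.var(x) <= 0:
        base.status = ModelStatus.EXCLUDED_NO_INVERSE_FIT
        return base
    fit = stats.linregress(x, y)
    base.b0 = float(fit.intercept)
    base.b1 = float(fit.slope)
    base.b0_stderr = float(fit.intercept_stderr)
    base.b1_stderr = float(fit.stderr)
    base.r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    base.b1_pvalue = float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0
    base.status = quality_gate(base.b1, base.r2, base.b1_pvalue, float(np.var(x)))
    return base


def _error_quantity(y: np.ndarray, x: np.ndarray, kind: str) -> float:
    n = y.size
    if kind == "sem":
        return float(np.std(y, ddof=1) / np.sqrt(n))
    if kind == "sd":
        return float(np.std(y, ddof=1))
    if kind == "residual_se":
        if np.var(x) <= 0:
            return float(np.std(y, ddof=1))
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        return float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
    raise ValidationError(f"unknown error quantity {kind!r}")


def resting_rmssd(session: CalibrationSession) -> float:
    """Mean RMSSD over valid epochs of the rest phase."""
    if not session.has_rest:
        raise MissingPhaseError(
            f"person {session.person_id}: calibration session has no rest phase"
        )
    mask = session.phase_mask("rest") & session.epochs.valid
    if not mask.any():
        raise MissingPhaseError(
            f"person {session.person_id}: rest phase contains no valid epoch"
        )
    return float(np.mean(session.epochs.rmssd[mask]))
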