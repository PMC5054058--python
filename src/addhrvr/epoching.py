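"""Interbeat-interval artifact cleaning and 30-s epoch aggregation.

Cleaning marks samples rather than deleting them so that epoch coverage can
be computed against the raw stream.  Epochs live on a fixed grid anchored at
t = 0; only windows fully contained in the overlap of the IBI and
acceleration streams become epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AccelStream, EpochSeries, IbiStream, ValidationError


@dataclass(frozen=True)
class ArtifactPolicy:
    """Range + relative-difference artifact rule and epoch validity limits.

    An interbeat interval is retained when it lies in ``[ibi_min, ibi_max]``
    and differs from the previously retained interval by at most
    ``max_rel_diff`` (relative; the first retained sample is exempt).  An
    epoch is valid when retained beats cover at least ``min_epoch_coverage``
    of its duration and number at least ``min_beats_per_epoch``.
    """

    ibi_min: float = 300.0
    ibi_max: float = 2000.0
    max_rel_diff: float = 0.30
    min_epoch_coverage: float = 0.8
    min_beats_per_epoch: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.ibi_min < self.ibi_max:
            raise ValidationError("require 0 < ibi_min < ibi_max")
        if not 0 < self.max_rel_diff < 1:
            raise ValidationError("require 0 < max_rel_diff < 1")
        if not 0 < self.min_epoch_coverage <= 1:
            raise ValidationError("require 0 < min_epoch_coverage <= 1")
        if self.min_beats_per_epoch < 2:
            raise ValidationError("min_beats_per_epoch must be >= 2")


def clean_ibis(stream: IbiStream, policy: ArtifactPolicy = ArtifactPolicy()) -> IbiStream:
    """Mark artifact interbeat intervals invalid; never deletes samples.

    Samples already marked invalid stay invalid, which makes the operation
    idempotent.  An all-invalid result is legal output.
    """
    valid = stream.valid.copy()
    prev: float | None = None
    for i in range(len(stream)):
        if not valid[i]:
            continue
        v = stream.ibi[i]
        if not (policy.ibi_min <= v <= policy.ibi_max):
            valid[i] = False
            continue
        if prev is not None and abs(v - prev) / prev > policy.max_rel_diff:
            valid[i] = False
            continue
        prev = v
    return IbiStream(stream.person_id, stream.time.copy(), stream.ibi.copy(), valid)


def rmssd(ibis) -> float:
    """Root mean square of successive differences, in the input's units."""
    values = np.asarray(ibis, dtype=float)
    if values.size < 2:
        raise ValueError("rmssd requires at least 2 interbeat intervals")
    diffs = np.diff(values)
    return float(np.sqrt(np.mean(diffs**2)))


def accel_magnitude(x, y=None, z=None) -> np.ndarray:
    """Per-sample Euclidean norm of three axes; identity for one channel."""
    x = np.asarray(x, dtype=float)
    if y is None and z is None:
        return x
    if y is None or z is None:
        raise ValueError("provide either one channel or all three axes")
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis arrays must have equal length")
    return np.sqrt(x**2 + y**2 + z**2)


def epoch_series(
    ibis: IbiStream,
    accel: AccelStream,
    epoch_length: float = 30.0,
    policy: ArtifactPolicy = ArtifactPolicy(),
) -> EpochSeries:
    """Aggregate cleaned IBIs and acceleration onto a common epoch grid.

    Per half-open window ``[k*L, (k+1)*L)``: RMSSD over retained IBIs whose
    end-timestamp falls in the window, mean of acceleration samples in the
    window.  An epoch is valid iff coverage and beat-count limits are met
    and acceleration is present.  Incomplete trailing windows are dropped.
    """
    if not len(ibis) or not len(accel):
        raise ValidationError("both streams must contain samples")
    lo = max(ibis.span[0], accel.span[0])
    hi = min(ibis.span[1], accel.span[1])
    if hi <= lo:
        raise ValidationError(
            f"ibi span {ibis.span} and acceleration span {accel.span} are disjoint"
        )
    n_epochs = int(np.floor(hi / epoch_length + 1e-9))
    starts = np.arange(n_epochs, dtype=float) * epoch_length
    rmssd_out = np.full(n_epochs, np.nan)
    accel_out = np.full(n_epochs, np.nan)
    valid_out = np.zeros(n_epochs, dtype=bool)

    ibi_bins = np.floor(ibis.time / epoch_length + 1e-9).astype(int)
    acc_bins = np.floor(accel.time / epoch_length + 1e-9).astype(int)
    for k in range(n_epochs):
        in_epoch = ibi_bins == k
        retained = in_epoch & ibis.valid
        beats = int(retained.sum())
        coverage = float(ibis.ibi[retained].sum() / 1000.0) / epoch_length
        if beats >= policy.min_beats_per_epoch and coverage >= policy.min_epoch_coverage:
            rmssd_out[k] = rmssd(ibis.ibi[retained])
        acc_here = accel.value[acc_bins == k]
        if acc_here.size:
            accel_out[k] = float(acc_here.mean())
        valid_out[k] = not np.isnan(rmssd_out[k]) and not np.isnan(accel_out[k])
    return EpochSeries(
        ibis.person_id, starts, rmssd_out, accel_out, valid_out, epoch_length=epoch_length
    )


def with_offset_removed(accel: AccelStream, offset: float) -> AccelStream:
    """Optional constant-offset removal (e.g. gravity component), clipped at 0.

    Off by default everywhere; provided for sensors whose magnitude average
    includes a static component.
    """
    return AccelStream(
        accel.person_id, accel.time.copy(), np.clip(accel.value - offset, 0.0, None)
    )
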