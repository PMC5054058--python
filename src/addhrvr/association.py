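"""Within/between-person decomposition and person-level summaries."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one input has no variance."""


class JoinError(ValueError):
    """Report rows reference persons absent from the detection table."""


def decompose(hourly: pd.DataFrame, value_col: str = "add_hrvr") -> pd.DataFrame:
    """Split an hourly value into a person mean and hourly deviations.

    Returns the input rows with ``between`` (person mean of ``value_col``)
    and ``within`` (deviation from that mean) columns appended, so that
    ``between + within`` reconstructs the hourly value exactly.  Persons
    with no hours are skipped with a warning.
    """
    if value_col not in hourly.columns:
        raise ValidationError(f"column {value_col!r} not present")
    df = hourly.copy()
    present = df[value_col].notna()
    if (~present).any():
        empty = df.loc[~present, "person_id"].unique().tolist()
        warnings.warn(f"skipping hours with missing {value_col} for persons {empty}")
        df = df[present].copy()
    grouped = df.groupby("person_id")[value_col]
    df["between"] = grouped.transform("mean")
    df["within"] = df[value_col] - df["between"]
    return df


def aggregate(
    hourly: pd.DataFrame,
    reports: pd.DataFrame | None = None,
    resting: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-person totals: flagged hours, episodes, worry/stress, mean affect.

    Persons in ``hourly`` but absent from ``reports`` get missing report
    totals; report rows for unknown persons raise :class:`JoinError`.
    """
    if hourly.empty:
        return pd.DataFrame(
            columns=["person_id", "n_hours", "total_addhrvr_hours", "total_episodes"]
        )
    g = hourly.groupby("person_id", sort=True)
    out = pd.DataFrame(
        {
            "n_hours": g.size(),
            "total_addhrvr_hours": g["add_hrvr"].sum(),
        }
    )
    if "n_episodes" in hourly.columns:
        out["total_episodes"] = g["n_episodes"].sum()
    if reports is not None and not reports.empty:
        unknown = set(reports["person_id"].astype(str)) - set(out.index.astype(str))
        if unknown:
            raise JoinError(f"reports reference unknown persons: {sorted(unknown)}")
        rg = reports.groupby("person_id")
        out["total_worry_episodes"] = rg["worry_count"].sum()
        out["total_stress_episodes"] = rg["stress_count"].sum()
        out["worry_hours"] = rg["worry_count"].apply(lambda s: int((s >= 1).sum()))
        out["stress_hours"] = rg["stress_count"].apply(lambda s: int((s >= 1).sum()))
        affect_cols = [
            c
            for c in reports.columns
            if c not in ("person_id", "hour_end_s", "worry_count", "stress_count")
            and pd.api.types.is_numeric_dtype(reports[c])
        ]
        for col in affect_cols:
            out[f"mean_{col}"] = rg[col].mean()
    if resting:
        out["resting_rmssd"] = pd.Series(resting, dtype=float)
    return out.reset_index().rename(columns={"index": "person_id"})


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("pearson requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom == 0:
        raise ZeroVarianceError("correlation undefined: zero variance input")
    r = float(np.sum(sx * sy) / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def cohort_rates(
    hourly: pd.DataFrame, reports: pd.DataFrame | None = None
) -> dict[str, float]:
    """Cohort-level shares and means over all hourly assessments.

    Percentages are over all hours pooled across persons; the flagged-hours
    mean is taken over person totals from :func:`aggregate`.
    """
    summary = aggregate(hourly, reports)
    n_hours = int(len(hourly))
    out = {
        "n_persons": int(summary.shape[0]),
        "n_hours": n_hours,
        "pct_addhrvr_hours": 100.0 * float(hourly["add_hrvr"].mean()) if n_hours else np.nan,
        "mean_addhrvr_hours_per_person": float(summary["total_addhrvr_hours"].mean())
        if len(summary)
        else np.nan,
    }
    if reports is not None and not reports.empty:
        out["pct_worry_hours"] = 100.0 * float((reports["worry_count"] >= 1).mean())
        out["pct_stress_hours"] = 100.0 * float((reports["stress_count"] >= 1).mean())
    return out


def analysis_table(
    hourly: pd.DataFrame,
    reports: pd.DataFrame | None = None,
    value_col: str = "add_hrvr",
) -> pd.DataFrame:
    """Long-format table joining hourly detection, decomposition, and reports.

    Ready for consumption by any mixed-model tool: one row per person-hour
    with the raw hourly value, its between/within split, and the report
    columns where available.
    """
    df = decompose(hourly, value_col=value_col).rename(
        columns={"between": f"{value_col}_between", "within": f"{value_col}_within"}
    )
    if reports is not None and not reports.empty:
        unknown = set(reports["person_id"].astype(str)) - set(
            df["person_id"].astype(str)
        )
        if unknown:
            raise JoinError(f"reports reference unknown persons: {sorted(unknown)}")
        df = df.merge(reports, on=["person_id", "hour_end_s"], how="left")
    return df
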