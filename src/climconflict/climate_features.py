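"""Construction of the climate regressors and pooled-covariate features.

Covers the variable-construction conventions of the study panel:

* monthly anomalies w.r.t. a calendar-month climatology over a baseline
  window (1980-2009 for temperature in the original data),
* trailing 3-month averaging of anomalies,
* drought length as the running count of consecutive months with positive
  temperature anomaly,
* the country-wide climate forcing ``C_t = sum_i c_it / Q_{c_i}(0.5)``
  (per-region median scaling, emphasizing common threshold exceedance) and
  its standardized-deviation alternative,
* region-level and period-level group means of the regressors, the
  covariates of the within-between (Mundlak) correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel_core import RegionalPanel

__all__ = [
    "ClimateForcingSeries",
    "GroupMeans",
    "monthly_anomaly",
    "rolling_mean",
    "drought_length",
    "climate_forcing",
    "group_means",
    "attach_group_means",
]

#: guard against division by a near-zero per-region median in the
#: median-ratio forcing (anomaly series have medians near 0 by construction)
MEDIAN_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class ClimateForcingSeries:
    """Country-wide forcing C_t, one value per period (panel period order)."""

    values: np.ndarray
    mode: str
    denominators: np.ndarray  # per-region scaling constants


@dataclasses.dataclass(frozen=True)
class GroupMeans:
    """Region- and period-level averages of the climate regressors.

    ``region_means``: rows indexed like ``panel.regions``, columns TA/DL/PA
    (the time-invariant covariates TA_bar_i, DL_bar_i, PA_bar_i).
    ``period_means``: rows indexed like ``panel.periods`` (TA_bar_t, DL_bar_t,
    PA_bar_t).
    """

    region_means: pd.DataFrame
    period_means: pd.DataFrame


def monthly_anomaly(
    values: np.ndarray,
    months: np.ndarray,
    baseline_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Deviation from the calendar-month mean over a baseline window.

    Parameters
    ----------
    values, months
        Aligned series of raw values and calendar months (1..12).
    baseline_mask
        Boolean mask selecting the climatology window; defaults to the whole
        series. Every calendar month present in the series must occur at
        least once inside the window.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(months, dtype=int)
    if baseline_mask is None:
        baseline_mask = np.ones_like(values, dtype=bool)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    out = np.empty_like(values)
    for m in np.unique(months):
        sel = months == m
        base = sel & baseline_mask
        if not base.any():
            raise ValueError(f"no baseline observations for calendar month {m}")
        out[sel] = values[sel] - values[base].mean()
    return out


def rolling_mean(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Trailing mean over the current and previous ``window - 1`` months.

    The first ``window - 1`` entries average over the months available so
    far (partial mean), preserving series length and panel balance. The
    trailing (rather than centered) alignment keeps the regressor known at
    time t.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def drought_length(ta: np.ndarray) -> np.ndarray:
    """Count of consecutive months with positive temperature anomaly.

    ``DL_t = DL_{t-1} + 1`` if ``TA_t > 0`` else 0, with ``DL_0 = 0`` before
    the series starts.
    """
    ta = np.asarray(ta, dtype=float)
    out = np.zeros(len(ta), dtype=np.int64)
    run = 0
    for t, v in enumerate(ta):
        run = run + 1 if v > 0 else 0
        out[t] = run
    return out


def climate_forcing(
    panel: RegionalPanel, variable: str = "PA", mode: str = "median-ratio"
) -> ClimateForcingSeries:
    """Country-wide forcing series from a per-region climate column.

    ``median-ratio`` (the primary definition): ``C_t = sum_i c_it / Q_i``
    where ``Q_i`` is region i's median of the series; emphasizes common
    threshold exceedance but is undefined when a median is ~0, as happens
    for anomaly series -- then an explicit error points to the alternative.
    ``mean-deviation`` (the robust alternative): ``C_t = sum_i
    (c_it - mean_i) / sd_i``.
    """
    wide = panel.data.pivot(index="period", columns="region", values=variable)
    wide = wide.loc[panel.periods, panel.regions]
    X = wide.to_numpy(dtype=float)  # T x n
    if mode == "median-ratio":
        q = np.median(X, axis=0)
        if np.any(np.abs(q) < MEDIAN_FLOOR):
            bad = [panel.regions[i] for i in np.flatnonzero(np.abs(q) < MEDIAN_FLOOR)]
            raise ValueError(
                f"median-ratio forcing undefined: per-region median of {variable!r} "
                f"is below {MEDIAN_FLOOR:g} in magnitude for region(s) {bad}; use "
                "mode='mean-deviation' or supply a custom denominator"
            )
        values = (X / q).sum(axis=1)
        denom = q
    elif mode == "mean-deviation":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("mean-deviation forcing undefined for a constant region series")
        values = ((X - mu) / sd).sum(axis=1)
        denom = sd
    else:
        raise ValueError(f"unknown forcing mode {mode!r}")
    return ClimateForcingSeries(values=values, mode=mode, denominators=denom)


def group_means(panel: RegionalPanel, columns: tuple = ("TA", "DL", "PA")) -> GroupMeans:
    """Region-level and period-level arithmetic means of the regressors."""
    cols = list(columns)
    rm = panel.data.groupby("region")[cols].mean().loc[panel.regions]
    pm = panel.data.groupby("period")[cols].mean().loc[panel.periods]
    return GroupMeans(region_means=rm, period_means=pm)


def attach_group_means(panel: RegionalPanel, gm: GroupMeans | None = None) -> RegionalPanel:
    """Reattach group means as constant-within-group panel columns.

    Adds ``TA_bar_i``-style region means and ``TA_bar_t``-style period means
    for TA, DL and PA.
    """
    gm = gm or group_means(panel)
    out = panel
    for col in gm.region_means.columns:
        vals = panel.data["region"].map(gm.region_means[col]).to_numpy(dtype=float)
        out = out.with_column(f"{col}_bar_i", vals)
    for col in gm.period_means.columns:
        vals = panel.data["period"].map(gm.period_means[col]).to_numpy(dtype=float)
        out = out.with_column(f"{col}_bar_t", vals)
    return out
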