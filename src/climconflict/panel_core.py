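"""Domain types, panel I/O, validation and region geometry.

The universal input of the pipeline is a *balanced* region x month panel of
conflict-event counts together with three climate regressors:

* ``TA`` -- temperature anomaly (deg C, deviation from a calendar-month
  climatology, smoothed over 3 months),
* ``DL`` -- drought length (running count of consecutive months with
  positive TA),
* ``PA`` -- precipitation anomaly.

Everything downstream (fixed-effects OLS, NB GLMs, hierarchical Bayesian
models) consumes a :class:`RegionalPanel`, which pins a stable region and
period ordering so that all design matrices are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PANEL_COLUMNS",
    "RegionalPanel",
    "RegionGeometry",
    "ValidationReport",
    "PanelValidationError",
    "load_panel",
    "write_panel",
    "load_geometry",
    "period_index",
    "pairwise_distances",
    "validate_panel",
]

#: canonical column names of a panel file
PANEL_COLUMNS = ("region", "year", "month", "conflict", "TA", "DL", "PA")

#: mean Earth radius in km (IUGG), used for great-circle distances
EARTH_RADIUS_KM = 6371.0088


class PanelValidationError(ValueError):
    """Raised when a panel file violates the balanced-panel contract."""


def period_index(year: int, month: int, first_year: int) -> int:
    """1-based running month index ``12*(year - first_year) + month``.

    Strictly increasing in chronological order; the 1997-2009 monthly panel
    spans indices 1..156.
    """
    month = int(month)
    if not 1 <= month <= 12:
        raise PanelValidationError(f"month must be in 1..12, got {month}")
    return 12 * (int(year) - int(first_year)) + month


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a panel for balance and well-typed fields."""

    is_balanced: bool
    missing_cells: list
    type_violations: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=str)


@dataclasses.dataclass
class RegionalPanel:
    """Balanced region x period panel.

    ``data`` holds one row per (region, period) with columns
    :data:`PANEL_COLUMNS` plus ``period``; rows are sorted by
    (region, period). ``regions`` are sorted lexically and ``periods``
    chronologically, and these orderings are shared by every matrix built
    downstream.
    """

    data: pd.DataFrame
    regions: list
    periods: list
    first_year: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def region_codes(self) -> np.ndarray:
        """0-based region index per observation, in panel row order."""
        lookup = {r: i for i, r in enumerate(self.regions)}
        return self.data["region"].map(lookup).to_numpy(dtype=np.int64)

    def period_codes(self) -> np.ndarray:
        """0-based period index per observation, in panel row order."""
        lookup = {p: i for i, p in enumerate(self.periods)}
        return self.data["period"].map(lookup).to_numpy(dtype=np.int64)

    def month_codes(self) -> np.ndarray:
        """0-based calendar-month index per observation."""
        return self.data["month"].to_numpy(dtype=np.int64) - 1

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def counts(self) -> np.ndarray:
        return self.data["conflict"].to_numpy(dtype=np.int64)

    def with_column(self, name: str, values: np.ndarray) -> "RegionalPanel":
        df = self.data.copy()
        df[name] = np.asarray(values)
        return RegionalPanel(df, list(self.regions), list(self.periods), self.first_year)

    def copy(self) -> "RegionalPanel":
        return RegionalPanel(
            self.data.copy(), list(self.regions), list(self.periods), self.first_year
        )


@dataclasses.dataclass(frozen=True)
class RegionGeometry:
    """Region centroids (decimal degrees) and great-circle distance matrix."""

    regions: list
    lat: np.ndarray
    lon: np.ndarray
    distance_km: np.ndarray

    def covers(self, regions: Sequence) -> bool:
        return set(regions) <= set(self.regions)

    def distances_for(self, regions: Sequence) -> np.ndarray:
        """Distance submatrix in the order of ``regions``."""
        idx = [self.regions.index(r) for r in regions]
        return self.distance_km[np.ix_(idx, idx)]


def pairwise_distances(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Haversine great-circle distances (km) between all centroid pairs."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise PanelValidationError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 360.0):
        raise PanelValidationError("longitude outside [-360, 360]")
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return d


def _coerce_counts(values: pd.Series, tol: float = 1e-9) -> tuple[np.ndarray, list]:
    """Cast counts to int, collecting row-level violations."""
    arr = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    violations = []
    for i, v in enumerate(arr):
        if not np.isfinite(v):
            violations.append(f"row {values.index[i]}: conflict is not numeric")
        elif v < 0:
            violations.append(f"row {values.index[i]}: conflict is negative ({v})")
        elif abs(v - round(v)) > tol:
            violations.append(f"row {values.index[i]}: conflict is not integral ({v})")
    counts = np.rint(np.nan_to_num(arr)).astype(np.int64)
    return counts, violations


def validate_panel(df: pd.DataFrame) -> ValidationReport:
    """Check balance (one row per region x period) and field types."""
    _, violations = _coerce_counts(df["conflict"])
    bad_month = df.loc[(df["month"] < 1) | (df["month"] > 12)]
    for idx in bad_month.index:
        violations.append(f"row {idx}: month out of range 1..12")

    regions = sorted(df["region"].unique())
    keys = list(zip(df["region"], df["year"], df["month"]))
    missing: list = []
    if len(set(keys)) != len(keys):
        seen: set = set()
        for k in keys:
            if k in seen:
                violations.append(f"duplicate cell {k}")
            seen.add(k)
    ym = sorted({(y, m) for y, m in zip(df["year"], df["month"])})
    have = set(keys)
    for r in regions:
        for y, m in ym:
            if (r, y, m) not in have:
                missing.append((r, int(y), int(m)))
    balanced = not missing and len(df) == len(regions) * len(ym)
    return ValidationReport(balanced, missing, violations)


def load_panel(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> RegionalPanel:
    """Read a delimited panel file into a :class:`RegionalPanel`.

    Parameters
    ----------
    path
        CSV/TSV file with a header; delimiter sniffed from the extension.
    column_map
        Optional mapping from canonical names (:data:`PANEL_COLUMNS`) to the
        file's column names.
    strict
        Refuse unbalanced panels (the study panel is balanced; silent
        imputation would corrupt fixed-effects estimates).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in PANEL_COLUMNS}
    missing_cols = [src for src in rename if src not in df.columns]
    if missing_cols:
        raise KeyError(f"panel file {path} lacks required column(s): {missing_cols}")
    df = df.rename(columns=rename)[list(PANEL_COLUMNS)]
    return panel_from_frame(df, strict=strict)


def panel_from_frame(df: pd.DataFrame, strict: bool = True) -> RegionalPanel:
    """Build a panel from an in-memory frame with canonical columns."""
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    report = validate_panel(df)
    if report.type_violations:
        raise PanelValidationError("; ".join(report.type_violations[:5]))
    if strict and not report.is_balanced:
        raise PanelValidationError(
            f"panel is unbalanced: {len(report.missing_cells)} missing cell(s), "
            f"e.g. {report.missing_cells[:3]}"
        )
    counts, _ = _coerce_counts(df["conflict"])
    df["conflict"] = counts
    for col in ("TA", "DL", "PA"):
        df[col] = pd.to_numeric(df[col]).astype(float)
    first_year = int(df["year"].min())
    df["period"] = [
        period_index(y, m, first_year) for y, m in zip(df["year"], df["month"])
    ]
    df = df.sort_values(["region", "period"], kind="mergesort").reset_index(drop=True)
    regions = sorted(df["region"].unique())
    periods = sorted(df["period"].unique())
    return RegionalPanel(df, regions, periods, first_year)


def write_panel(panel: RegionalPanel, path: str | Path) -> None:
    """Write the panel back to CSV (round-trips finite decimals exactly)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    panel.data[list(PANEL_COLUMNS)].to_csv(path, sep=sep, index=False)


def load_geometry(path: str | Path) -> RegionGeometry:
    """Read a centroid file (columns region, lat, lon)."""
    df = pd.read_csv(path)
    for col in ("region", "lat", "lon"):
        if col not in df.columns:
            raise KeyError(f"geometry file lacks column {col!r}")
    df = df.sort_values("region").reset_index(drop=True)
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    return RegionGeometry(list(df["region"]), lat, lon, pairwise_distances(lat, lon))


def geometry_from_centroids(regions: Sequence, lat: np.ndarray, lon: np.ndarray) -> RegionGeometry:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    order = np.argsort(np.asarray(regions, dtype=object))
    regions = [regions[i] for i in order]
    lat, lon = lat[order], lon[order]
    return RegionGeometry(list(regions), lat, lon, pairwise_distances(lat, lon))


def write_geometry(geom: RegionGeometry, path: str | Path) -> None:
    pd.DataFrame({"region": geom.regions, "lat": geom.lat, "lon": geom.lon}).to_csv(
        path, index=False
    )
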