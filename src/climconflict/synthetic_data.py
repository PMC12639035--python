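"""Somalia-like synthetic panels with known ground truth.

The generator emulates the statistical structure the analysis assumes --
not any real data distribution: 18 regions x 156 months (1997-2009) by
default, climate anomaly series built from seasonal-plus-AR(1) raw series
with spatially correlated innovations (exponential distance decay across
jittered-grid centroids), drought length derived deterministically from the
sign runs of the temperature anomaly, region coefficients drawn from a
multivariate normal whose intercept component can be deliberately
confounded with the realized region-mean temperature anomaly (to exercise
the within-between correction), period effects driven by a country-wide
climate forcing, and NB2 counts with a realistic preponderance of zeros.

All randomness flows from the single ``seed``; identical configs give
bit-identical panels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_features as cf
from .panel_core import RegionalPanel, RegionGeometry, geometry_from_centroids, panel_from_frame

__all__ = ["ClimateConfig", "TruthConfig", "SyntheticConfig", "SyntheticTruth",
           "simulate_panel", "scenario_shift", "default_omega"]


def default_omega() -> np.ndarray:
    """Default between-region correlation of (a, b, c, f): modest couplings."""
    return np.array(
        [
            [1.0, 0.3, -0.2, 0.2],
            [0.3, 1.0, -0.1, 0.1],
            [-0.2, -0.1, 1.0, -0.1],
            [0.2, 0.1, -0.1, 1.0],
        ]
    )


@dataclasses.dataclass(frozen=True)
class ClimateConfig:
    """Generating process of the raw climate series (monthly, per region)."""

    seasonal_amplitude_t: float = 3.0  # deg C, annual temperature cycle
    seasonal_amplitude_p: float = 1.5  # precipitation units
    ar_coefficient: float = 0.6  # AR(1) of anomaly innovations
    innovation_sd_t: float = 0.6  # deg C
    innovation_sd_p: float = 1.2
    spatial_range_km: float = 300.0  # exponential decay of innovation corr.
    baseline_years: int = 17  # pre-panel years feeding the climatology


@dataclasses.dataclass(frozen=True)
class TruthConfig:
    """Generating parameters of the outcome model (NB2, log link)."""

    hypermeans: tuple = (0.1, 0.05, -0.1, -0.5)  # alpha0, gamma0, delta0, phi0
    tau: tuple = (0.2, 0.05, 0.2, 1.0)
    omega: tuple = tuple(map(tuple, default_omega()))
    eta: tuple = (0.0, 0.0, 0.0)
    psi0: float = 0.0
    psi_lvl: tuple = (0.3, -0.05, 0.05)  # on TA_bar_t, DL_bar_t, C_t
    sigma_w: float = 0.3
    theta: float = 0.8
    forcing_mode: str = "mean-deviation"


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    n_regions: int = 18
    n_years: int = 13
    first_year: int = 1997
    climate: ClimateConfig = ClimateConfig()
    truth: TruthConfig = TruthConfig()
    confounding_strength: float = 0.0  # additive pull of f_i toward std. TA_bar_i
    seed: int = 0


@dataclasses.dataclass
class SyntheticTruth:
    """Realized generating quantities accompanying a simulated panel."""

    config: SyntheticConfig
    coefs: np.ndarray  # (n_regions, 4): a_i, b_i, c_i, f_i
    w: np.ndarray  # (T,) realized period effects
    regions: list

    @property
    def hypermeans(self) -> np.ndarray:
        return np.asarray(self.config.truth.hypermeans, dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        tau = np.asarray(self.config.truth.tau, dtype=float)
        return tau[:, None] * np.asarray(self.config.truth.omega) * tau[None, :]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "coefs": self.coefs.tolist(),
            "w": self.w.tolist(),
            "regions": list(map(str, self.regions)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _centroid_grid(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Jittered grid over a Horn-of-Africa-sized box (lat 1-11, lon 42-50)."""
    ncols = int(np.ceil(np.sqrt(n / 2.0)))
    nrows = int(np.ceil(n / ncols))
    lats = np.linspace(1.5, 10.5, nrows)
    lons = np.linspace(42.5, 49.5, ncols)
    lat, lon = [], []
    for i in range(n):
        r, c = divmod(i, ncols)
        lat.append(lats[r] + rng.uniform(-0.3, 0.3))
        lon.append(lons[c] + rng.uniform(-0.3, 0.3))
    return np.asarray(lat), np.asarray(lon)


def _spatial_ar1_series(
    n_months: int,
    months: np.ndarray,
    dist: np.ndarray,
    amplitude: float,
    rho: float,
    innov_sd: float,
    spatial_range: float,
    rng: np.random.Generator,
    phase: float,
) -> np.ndarray:
    """(n_months, n_regions) raw series: seasonal cycle + spatial AR(1) noise."""
    n_regions = dist.shape[0]
    corr = np.exp(-dist / spatial_range)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n_regions))
    seasonal = amplitude * np.sin(2.0 * np.pi * (months - 1) / 12.0 + phase)
    eps = np.zeros((n_months, n_regions))
    scale = innov_sd * np.sqrt(1.0 - rho**2)
    state = (L @ rng.standard_normal(n_regions)) * innov_sd
    for t in range(n_months):
        eps[t] = state
        state = rho * state + scale * (L @ rng.standard_normal(n_regions))
    return seasonal[:, None] + eps


def simulate_panel(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[RegionalPanel, RegionGeometry, SyntheticTruth]:
    """Simulate a balanced panel, its geometry and the generating truth.

    The raw climate series start ``climate.baseline_years`` before the
    panel window so that anomalies are computed against a proper
    calendar-month climatology and drought length carries no edge artifact
    at the panel start.
    """
    rng = np.random.default_rng(cfg.seed)
    regions = [f"R{i:02d}" for i in range(cfg.n_regions)]
    lat, lon = _centroid_grid(cfg.n_regions, rng)
    geometry = geometry_from_centroids(regions, lat, lon)
    dist = geometry.distances_for(regions)

    cl = cfg.climate
    total_years = cl.baseline_years + cfg.n_years
    n_months = total_years * 12
    months_cal = np.tile(np.arange(1, 13), total_years)
    years = np.repeat(np.arange(cfg.first_year - cl.baseline_years,
                                cfg.first_year + cfg.n_years), 12)

    raw_t = _spatial_ar1_series(n_months, months_cal, dist, cl.seasonal_amplitude_t,
                                cl.ar_coefficient, cl.innovation_sd_t,
                                cl.spatial_range_km, rng, phase=0.0)
    raw_p = _spatial_ar1_series(n_months, months_cal, dist, cl.seasonal_amplitude_p,
                                cl.ar_coefficient * 0.5, cl.innovation_sd_p,
                                cl.spatial_range_km, rng, phase=np.pi / 2.0)

    ta = np.empty_like(raw_t)
    pa = np.empty_like(raw_p)
    dl = np.empty_like(raw_t, dtype=np.int64)
    for i in range(cfg.n_regions):
        a_t = cf.monthly_anomaly(raw_t[:, i], months_cal)
        a_p = cf.monthly_anomaly(raw_p[:, i], months_cal)
        ta[:, i] = cf.rolling_mean(a_t, 3)
        pa[:, i] = cf.rolling_mean(a_p, 3)
        dl[:, i] = cf.drought_length(ta[:, i])

    window = slice(cl.baseline_years * 12, n_months)
    T = cfg.n_years * 12
    frame = pd.DataFrame(
        {
            "region": np.repeat(regions, T),
            "year": np.tile(years[window], cfg.n_regions),
            "month": np.tile(months_cal[window], cfg.n_regions),
            "conflict": 0,
            "TA": ta[window].T.reshape(-1),
            "DL": dl[window].T.reshape(-1),
            "PA": pa[window].T.reshape(-1),
        }
    )
    panel = panel_from_frame(frame)

    tr = cfg.truth
    tau = np.asarray(tr.tau, dtype=float)
    omega = np.asarray(tr.omega, dtype=float)
    sigma = tau[:, None] * omega * tau[None, :]
    try:
        Ls = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("configured between-region covariance is not positive definite") from err

    gm = cf.group_means(panel)
    zbar = gm.region_means.to_numpy(dtype=float)  # (R, 3), panel region order
    mean = np.tile(np.asarray(tr.hypermeans, dtype=float), (cfg.n_regions, 1))
    if cfg.confounding_strength != 0.0:
        ta_bar = zbar[:, 0]
        std = (ta_bar - ta_bar.mean()) / max(ta_bar.std(), 1e-12)
        mean[:, 3] += cfg.confounding_strength * std
    coefs = mean + rng.standard_normal((cfg.n_regions, 4)) @ Ls.T

    forcing = cf.climate_forcing(panel, "PA", tr.forcing_mode)
    pm = gm.period_means.to_numpy(dtype=float)
    mlvl = np.column_stack([pm[:, 0], pm[:, 1], forcing.values])
    w = tr.psi0 + mlvl @ np.asarray(tr.psi_lvl) + tr.sigma_w * rng.standard_normal(T)

    r = panel.region_codes()
    t = panel.period_codes()
    X = np.column_stack([panel.column(c) for c in ("TA", "DL", "PA")])
    lp = (
        np.einsum("nk,nk->n", X, coefs[r, :3])
        + coefs[r, 3]
        + (zbar @ np.asarray(tr.eta))[r]
        + w[t]
    )
    mu = np.exp(lp)
    lam = rng.gamma(shape=tr.theta, scale=mu / tr.theta)
    y = rng.poisson(lam)
    panel = panel.with_column("conflict", y.astype(np.int64))

    truth = SyntheticTruth(cfg, coefs, w, regions)
    return panel, geometry, truth


def scenario_shift(panel: RegionalPanel, variable: str, shift: float) -> RegionalPanel:
    """Shift a climate variable by ``shift`` per-region standard deviations.

    Drought length is re-derived from the shifted temperature anomaly when
    TA is shifted (DL is a deterministic function of TA sign runs; the run
    counter restarts at the panel window start).
    """
    if variable not in {"TA", "PA"}:
        raise KeyError(f"unknown shiftable variable {variable!r} (use TA or PA)")
    if shift == 0.0:
        return panel.copy()
    df = panel.data.copy()
    sds = df.groupby("region")[variable].transform(lambda s: s.std(ddof=0))
    df[variable] = df[variable] + shift * sds
    if variable == "TA":
        df["DL"] = (
            df.sort_values(["region", "period"])
            .groupby("region")["TA"]
            .transform(lambda s: cf.drought_length(s.to_numpy()))
        )
    out = panel.copy()
    out.data = df
    return out
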