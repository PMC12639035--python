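"""Predictive count distributions under climate scenarios.

Combines posterior draws with a (possibly shifted) panel of predictors to
produce per-region and aggregate predictive distributions of conflict-event
counts with full uncertainty propagation: parameter uncertainty (posterior
draws), period-effect uncertainty (sampled from the fitted period-level
model for out-of-sample horizons), and sampling variability (NB2 draws).

Only the temporally pooled model carries a generative model for period
effects; the fixed-effect-period rungs are refused for out-of-sample
horizons because their period coefficients are undefined beyond the sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import climate_features as cf
from .bayes_hier import PosteriorDraws
from .panel_core import RegionalPanel

__all__ = ["ProjectionResult", "project"]


@dataclasses.dataclass
class ProjectionResult:
    scenario: str
    horizon: str
    regions: list
    regional_draws: np.ndarray  # (n_draws, n_regions) total counts per region
    aggregate_draws: np.ndarray  # (n_draws,) country totals

    def summary(self):
        import pandas as pd

        lo, med, hi = np.percentile(self.regional_draws, [2.5, 50.0, 97.5], axis=0)
        rows = pd.DataFrame(
            {"region": self.regions, "median": med, "lo95": lo, "hi95": hi}
        )
        alo, amed, ahi = np.percentile(self.aggregate_draws, [2.5, 50.0, 97.5])
        rows.loc[len(rows)] = ["(aggregate)", amed, alo, ahi]
        rows.insert(0, "scenario", self.scenario)
        return rows


def project(
    draws: PosteriorDraws,
    scenario: RegionalPanel,
    horizon: str = "in-sample",
    n_draws: int | None = None,
    seed: int = 0,
    label: str = "",
) -> ProjectionResult:
    """Predictive counts for a scenario panel.

    ``horizon="in-sample"`` reuses each draw's realized period effects;
    ``horizon="out-of-sample"`` treats the scenario periods as new and
    samples period effects from the fitted level model
    ``w ~ normal(psi0 + psi1*TA_bar_t + psi2*DL_bar_t + psi3*C_t, sigma_w)``
    with period averages recomputed from the scenario panel itself.
    """
    if horizon not in {"in-sample", "out-of-sample"}:
        raise ValueError(f"unknown horizon {horizon!r}")
    model = draws.model
    spec = model.spec
    if horizon == "out-of-sample" and spec.pooling != "region_time":
        raise ValueError(
            "out-of-sample projection requires pooling='region_time': models "
            "with fixed period effects have no generative model for periods "
            "outside the sample"
        )
    if spec.pooling == "none":
        raise ValueError("projection requires a region-pooled model")

    rng = np.random.default_rng(seed)
    thetas = draws.theta_stacked()
    S = thetas.shape[0]
    take = np.arange(S) if n_draws is None or n_draws >= S else rng.choice(S, n_draws, replace=False)

    r = scenario.region_codes()
    t = scenario.period_codes()
    X = np.column_stack([scenario.column(c) for c in ("TA", "DL", "PA")])
    gm = cf.group_means(scenario)
    zbar = gm.region_means.to_numpy(dtype=float)
    R = scenario.n_regions

    if horizon == "out-of-sample":
        forcing = cf.climate_forcing(scenario, spec.forcing_variable, spec.forcing_mode)
        pm = gm.period_means.to_numpy(dtype=float)
        mlvl = np.column_stack([pm[:, 0], pm[:, 1], forcing.values])

    regional = np.empty((len(take), R))
    for j, s in enumerate(take):
        params = model.unpack(thetas[s])
        B = params["coefs"]
        eta = params["eta"]
        if horizon == "in-sample":
            w = params["period_effect"]
        else:
            loc = params["psi0"] + mlvl @ params["psi_lvl"]
            w = rng.normal(loc, params["sigma_w"])
        lp = (
            np.einsum("nk,nk->n", X, B[r, :3])
            + B[r, 3]
            + (zbar @ eta)[r]
            + w[t]
        )
        if spec.family == "negbin":
            th = params["Theta"]
            mu = np.exp(np.clip(lp, -30.0, 30.0))
            y = rng.poisson(rng.gamma(shape=th, scale=mu / th))
        else:
            y = np.rint(np.clip(rng.normal(lp, params["sigma"]), 0.0, None))
        regional[j] = np.bincount(r, weights=y, minlength=R)

    return ProjectionResult(
        scenario=label or "scenario",
        horizon=horizon,
        regions=list(scenario.regions),
        regional_draws=regional,
        aggregate_draws=regional.sum(axis=1),
    )
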