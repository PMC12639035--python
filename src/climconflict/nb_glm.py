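"""Frequentist fixed-effects negative binomial (NB2) GLM with log link.

The count model

    conflict_it ~ NB(mu_it, Theta),
    log mu_it = alpha*TA_it + gamma*DL_it + delta*PA_it + phi_i + psi_t

is fit by alternating iteratively reweighted least squares for the
coefficients with a profile update of the NB2 size parameter Theta
(variance function mu + mu^2/Theta), until the relative log-likelihood
change drops below 1e-9. Fixed effects enter as explicit dummy columns with
one reference level dropped per set; a small ridge (1e-6) on the FE
coefficients guards against separation (e.g. a region with all-zero
counts, whose fixed effect would otherwise diverge to -inf).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .fe_ols import DiagnosticsReport, FixedEffectsSpec, fe_group_codes
from .panel_core import RegionalPanel

__all__ = [
    "NBGLMFit",
    "fit_nb_glm",
    "nb2_loglik",
    "nb_quantile_residuals",
    "build_glm_design",
]

FE_RIDGE = 1e-6
LOGLIK_RTOL = 1e-9
MAX_OUTER = 200
MAX_IRLS = 100
#: quantile residuals are capped just below the standard-normal quantile at
#: (1 - 1e-16), the resolution limit of the CDF in double precision
MAX_QRESID = 8.2


@dataclasses.dataclass
class NBGLMFit:
    treatments: list
    slopes: np.ndarray  # on the log scale
    coef: np.ndarray  # full coefficient vector (intercept, slopes, FEs)
    colnames: list
    dispersion: float  # Theta (NB2 size)
    loglik: float
    aic: float
    fitted_means: np.ndarray
    vcov_slopes: np.ndarray  # Fisher-information block for the treatments
    n: int
    converged: bool
    n_iter: int
    deviance_trace: list
    flags: list

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_slopes))

    def summary(self) -> dict:
        return {
            "slopes": dict(zip(self.treatments, self.slopes.tolist())),
            "se": dict(zip(self.treatments, self.se.tolist())),
            "dispersion": self.dispersion,
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def build_glm_design(
    panel: RegionalPanel,
    treatments: Sequence[str],
    fes: FixedEffectsSpec,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Design matrix with intercept, treatments and reference-dropped dummies.

    Returns ``(X, colnames, ridge_mask)`` where ``ridge_mask`` marks the FE
    columns that receive the stabilizing ridge.
    """
    n = panel.n_obs
    cols = [np.ones(n)]
    names = ["(intercept)"]
    for c in treatments:
        cols.append(panel.column(c))
        names.append(c)
    fe_names = []
    if fes.include_region:
        fe_names.append("region")
    if fes.include_period:
        fe_names.append("period")
    if fes.include_region_month:
        fe_names.append("region_month")
    for label, g in zip(fe_names, fe_group_codes(panel, fes)):
        for level in range(1, int(g.max()) + 1):  # drop level 0 as reference
            cols.append((g == level).astype(float))
            names.append(f"{label}[{level}]")
    X = np.column_stack(cols)
    ridge_mask = np.array([n.startswith(("region", "period")) for n in names])
    return X, names, ridge_mask


def nb2_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Sum of NB2 log-pmf terms (mean mu, size theta)."""
    y = np.asarray(y, dtype=float)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta)
            + y * np.log(mu)
            - (y + theta) * np.log(mu + theta)
        )
    )


def _nb2_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    theta: float,
    ridge: np.ndarray,
    max_iter: int = MAX_IRLS,
    tol: float = 1e-10,
) -> tuple[np.ndarray, list]:
    """IRLS for the log-link NB2 mean model at fixed theta.

    Deviance is made monotone by step-halving; the trace of deviance values
    is returned for the monotonicity contract.
    """
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    dev = _nb2_deviance(y, mu, theta) + float(ridge @ beta**2)
    trace = [dev]
    for _ in range(max_iter):
        w = mu * theta / (mu + theta)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        A = X.T @ WX + np.diag(ridge)
        b = WX.T @ z
        beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        step = beta_new - beta
        # step-halving until the (ridge-penalized) deviance does not increase
        lam, ok = 1.0, False
        for _ in range(30):
            cand = beta + lam * step
            eta_c = np.clip(X @ cand, -30, 30)
            mu_c = np.exp(eta_c)
            dev_c = _nb2_deviance(y, mu_c, theta) + float(ridge @ cand**2)
            if dev_c <= dev + 1e-12:
                ok = True
                break
            lam *= 0.5
        if not ok:
            break
        beta, eta, mu = cand, eta_c, mu_c
        improved = dev - dev_c
        dev = dev_c
        trace.append(dev)
        if improved < tol * (abs(dev) + 1.0):
            break
    return beta, trace


def _profile_theta(y: np.ndarray, mu: np.ndarray, lo: float = -12.0, hi: float = 16.0) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -nb2_loglik(y, mu, float(np.exp(lt))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def fit_nb_glm(
    panel: RegionalPanel,
    treatments: Sequence[str] = ("TA", "DL", "PA"),
    fes: FixedEffectsSpec = FixedEffectsSpec(include_region_month=False),
) -> NBGLMFit:
    """Maximum-likelihood NB2 GLM fit over coefficients and dispersion."""
    treatments = list(treatments)
    y = panel.counts().astype(float)
    if np.all(y == 0):
        raise ValueError("all-zero outcome: dispersion Theta is unidentifiable")
    X, names, fe_mask = build_glm_design(panel, treatments, fes)
    ridge = np.where(fe_mask, FE_RIDGE, 0.0)

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3))
    mu = np.exp(np.clip(X @ beta, -30, 30))
    # moment start for Theta
    v = y.var()
    m = y.mean()
    theta = float(np.clip(m**2 / max(v - m, 1e-3), 1e-2, 1e4))

    ll = nb2_loglik(y, mu, theta)
    dev_trace: list = []  # one monotone trace per IRLS run (fixed theta)
    converged = False
    n_outer = 0
    for n_outer in range(1, MAX_OUTER + 1):
        beta, tr = _irls(y, X, beta, theta, ridge)
        dev_trace.append(tr)
        mu = np.exp(np.clip(X @ beta, -30, 30))
        theta = _profile_theta(y, mu)
        ll_new = nb2_loglik(y, mu, theta)
        if abs(ll_new - ll) < LOGLIK_RTOL * (abs(ll_new) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        raise RuntimeError(
            f"NB GLM did not converge after {MAX_OUTER} outer iterations; "
            f"deviance trace tail: {dev_trace[-5:]}"
        )

    flags: list = []
    big = [names[j] for j in np.flatnonzero((np.abs(beta) > 15) & fe_mask)]
    if big:
        flags.append(f"possible separation; ridged FE coefficient(s) large: {big[:5]}")

    slope_idx = np.array([names.index(c) for c in treatments])
    w = mu * theta / (mu + theta)
    info = X.T @ (X * w[:, None]) + np.diag(ridge)
    vcov = np.linalg.pinv(info)
    vcov_slopes = vcov[np.ix_(slope_idx, slope_idx)]

    n_params = X.shape[1] + 1  # coefficients + Theta
    return NBGLMFit(
        treatments=treatments,
        slopes=beta[slope_idx],
        coef=beta,
        colnames=names,
        dispersion=theta,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * n_params,
        fitted_means=mu,
        vcov_slopes=vcov_slopes,
        n=len(y),
        converged=converged,
        n_iter=n_outer,
        deviance_trace=dev_trace,
        flags=flags,
    )


def nb_quantile_residuals(fit: NBGLMFit, y: np.ndarray, seed: int = 0) -> DiagnosticsReport:
    """Randomized quantile residuals of an NB2 fit.

    For each observation, draw u uniformly between the NB CDF at y-1 and at
    y and map through the standard-normal quantile; under a correct model
    the residuals are iid standard normal (probability integral transform).
    Residuals beyond the numeric range of the normal quantile are capped at
    +/-8.2 and flagged.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    theta = fit.dispersion
    p = theta / (theta + fit.fitted_means)
    lo = np.where(y > 0, stats.nbinom.cdf(y - 1, theta, p), 0.0)
    hi = stats.nbinom.cdf(y, theta, p)
    u = lo + rng.uniform(size=len(y)) * np.maximum(hi - lo, 1e-300)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    z = stats.norm.ppf(u)
    flags: list = []
    capped = np.abs(z) > MAX_QRESID
    if capped.any():
        flags.append(f"{int(capped.sum())} quantile residual(s) capped at |z|={MAX_QRESID}")
        z = np.clip(z, -MAX_QRESID, MAX_QRESID)
    ks_stat, ks_p = stats.kstest(z, "norm")
    sh_stat, sh_p = stats.shapiro(z) if len(z) >= 3 else (float("nan"), float("nan"))
    order = np.argsort(z)
    probs = (np.arange(1, len(z) + 1) - 0.5) / len(z)
    return DiagnosticsReport(
        std_residuals=z,
        qq_theoretical=stats.norm.ppf(probs),
        qq_sample=z[order],
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        shapiro_stat=float(sh_stat),
        shapiro_p=float(sh_p),
        outliers=np.flatnonzero(np.abs(z) > 3.0),
        flags=flags,
    )
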