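"""The Bayesian model ladder for conflict-count panels.

Three nested specifications over a balanced region x month panel, all with
an NB2 likelihood and log link (or a Gaussian likelihood with identity link
as a variant):

``pooling="none"`` -- varying intercepts, fixed slopes:
    log mu_it = alpha*TA + gamma*DL + delta*PA + phi_i + psi_t

``pooling="region"`` -- region coefficients (a_i, b_i, c_i, f_i) partially
pooled through a multivariate normal with hypermeans (alpha0, gamma0,
delta0, phi0) and covariance diag(tau)*Omega*diag(tau); the group means
TA_bar_i, DL_bar_i, PA_bar_i enter with slopes eta_1..3 (the within-between
/ Mundlak correction for time-invariant confounding):
    log mu_it = a_i*TA + b_i*DL + c_i*PA + f_i
                + eta1*TA_bar_i + eta2*DL_bar_i + eta3*PA_bar_i + psi_t

``pooling="region_time"`` -- additionally pools the period effects through
a country-level model driven by period group means and a climate forcing:
    w_t ~ normal(psi0 + psi1*TA_bar_t + psi2*DL_bar_t + psi3*C_t, sigma_w)

Priors are weakly informative and overridable: regression-level
coefficients, hypermeans, eta, psi ~ normal(0, 5); scales tau and sigma_w ~
half-normal(0, 2); correlation matrix Omega ~ LKJ(2); NB2 dispersion via
1/sqrt(Theta) ~ half-normal(0, 1).

Everything is parameterized on an unconstrained space (non-centered region
coefficients, centered period effects, log scales, tanh-transformed
canonical partial correlations for the Cholesky factor of Omega; both
hierarchical blocks can be switched between centered and non-centered form)
with hand-derived analytic gradients, and sampled with the adaptive HMC
engine in :mod:`climconflict.sampling`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import linalg as sla, special

from . import climate_features as cf
from .panel_core import RegionalPanel
from .sampling import SamplerConfig, SamplerResult, sample_hmc

__all__ = [
    "PriorConfig",
    "HierModelSpec",
    "HierModel",
    "PosteriorDraws",
    "build_model",
    "fit_bayes",
    "posterior_from_draws",
    "summarize_posterior",
    "MODEL_LADDER",
]

COEF_NAMES = ("a", "b", "c", "f")  # region coefficients on TA, DL, PA, intercept
HYPER_NAMES = ("alpha0", "gamma0", "delta0", "phi0")

#: the four specifications compared in the study, in predictive order
MODEL_LADDER = (
    ("gaussian_fe", "normal", "none"),
    ("nb_fe", "negbin", "none"),
    ("nb_region", "negbin", "region"),
    ("nb_region_time", "negbin", "region_time"),
)


@dataclasses.dataclass(frozen=True)
class PriorConfig:
    """Weakly informative prior scales (all overridable)."""

    coef_scale: float = 5.0  # hypermeans, eta, psi, unpooled FEs
    tau_scale: float = 2.0  # half-normal on between-region scales
    lkj_eta: float = 2.0  # LKJ shape on the correlation matrix
    theta_scale: float = 1.0  # half-normal on 1/sqrt(Theta)
    sigma_w_scale: float = 2.0  # half-normal on the period-level scale
    sigma_scale: float | None = None  # Gaussian residual sd; default 2*sd(y)


@dataclasses.dataclass(frozen=True)
class HierModelSpec:
    """Declarative description of one rung of the model ladder."""

    family: str = "negbin"  # {"negbin", "normal"}
    pooling: str = "none"  # {"none", "region", "region_time"}
    include_region_month_fe: bool = False  # off for multilevel rungs
    include_group_means: bool = True  # the within-between (Mundlak) correction
    # hierarchical-block parameterizations: the region coefficients are only
    # moderately identified per region (funnel risk -> non-centered), while
    # each period effect is informed by all regions in that month (centered)
    region_coef_param: str = "non-centered"
    period_param: str = "centered"
    forcing_variable: str = "PA"
    forcing_mode: str = "mean-deviation"
    priors: PriorConfig = PriorConfig()

    def __post_init__(self):
        if self.family not in {"negbin", "normal"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.pooling not in {"none", "region", "region_time"}:
            raise ValueError(f"unknown pooling {self.pooling!r}")
        for p in (self.region_coef_param, self.period_param):
            if p not in {"centered", "non-centered"}:
                raise ValueError(f"unknown parameterization {p!r}")


# ---------------------------------------------------------------------------
# LKJ / Cholesky machinery (canonical partial correlations)

def cpc_to_chol(u: np.ndarray, d: int) -> tuple[np.ndarray, list]:
    """Unconstrained CPCs -> Cholesky factor of a correlation matrix.

    ``u`` holds the row-major strictly-lower-triangular entries; the
    construction follows the C-vine: L[i,j] = x_ij * sqrt(remaining
    variance), with x = tanh(u). Returns (L, stash) where ``stash`` keeps
    the per-row partial variances for the adjoint pass.
    """
    x = np.tanh(u)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    stash = []
    k = 0
    for i in range(1, d):
        c = 1.0
        cs = []
        for j in range(i):
            cs.append(c)
            L[i, j] = x[k] * np.sqrt(c)
            c = c * (1.0 - x[k] ** 2)
            k += 1
        L[i, i] = np.sqrt(c)
        stash.append((cs, c))
    return L, stash


def chol_pullback(Lbar: np.ndarray, u: np.ndarray, d: int) -> np.ndarray:
    """Adjoint of :func:`cpc_to_chol`: dF/dL -> dF/du."""
    x = np.tanh(u)
    _, stash = cpc_to_chol(u, d)
    xbar = np.zeros_like(x)
    k = 0
    for i in range(1, d):
        cs, c_end = stash[i - 1]
        row = slice(k, k + i)
        xi = x[row]
        # reverse the row recursion
        cbar = Lbar[i, i] * 0.5 / np.sqrt(c_end) if c_end > 0 else 0.0
        for j in range(i - 1, -1, -1):
            cj = cs[j]
            xk = xi[j]
            xb = cbar * cj * (-2.0 * xk)
            cbar = cbar * (1.0 - xk**2)
            xb += Lbar[i, j] * np.sqrt(cj)
            cbar += Lbar[i, j] * xk * 0.5 / np.sqrt(cj)
            xbar[k + j] += xb
        k += i
    return xbar * (1.0 - x**2)  # tanh chain rule


def lkj_cpc_logprior_grad(u: np.ndarray, d: int, eta: float) -> tuple[float, np.ndarray]:
    """LKJ(eta) prior on the correlation matrix, expressed in CPC space.

    Under LKJ(eta) the canonical partial correlations are independent with
    (r+1)/2 ~ Beta(b, b), b = eta + (d - 2 - j)/2 for conditioning depth j
    (0-based column); combined with the tanh Jacobian the unconstrained log
    prior is sum b_j * log(1 - tanh(u)^2).
    """
    x = np.tanh(u)
    b = np.asarray([eta + (d - 2 - j) / 2.0 for i in range(1, d) for j in range(i)])
    with np.errstate(divide="ignore"):  # |r| -> 1 legitimately gives -inf
        logp = float(np.sum(b * np.log1p(-(x**2))))
    grad = -2.0 * b * x
    return logp, grad


# ---------------------------------------------------------------------------


class HierModel:
    """A built model: data bindings, parameter layout, log posterior.

    ``prior_only=True`` drops the likelihood term, turning the posterior
    into the joint prior (used for prior-predictive checks).
    """

    def __init__(self, spec: HierModelSpec, panel: RegionalPanel, prior_only: bool = False):
        self.spec = spec
        self.prior_only = prior_only
        self.panel = panel
        self.y = panel.counts().astype(float)
        self.X = np.column_stack([panel.column(c) for c in ("TA", "DL", "PA")])
        self.r = panel.region_codes()
        self.t = panel.period_codes()
        self.rm = self.r * 12 + panel.month_codes()
        self.R = panel.n_regions
        self.T = panel.n_periods
        self.n = panel.n_obs

        gm = cf.group_means(panel)
        self.Zbar = gm.region_means.to_numpy(dtype=float)  # (R, 3)
        if spec.pooling == "region_time":
            forcing = cf.climate_forcing(panel, spec.forcing_variable, spec.forcing_mode)
            pm = gm.period_means.to_numpy(dtype=float)
            # period-level predictors: TA_bar_t, DL_bar_t, C_t
            self.Mlvl = np.column_stack([pm[:, 0], pm[:, 1], forcing.values])
            self.forcing = forcing
        else:
            self.Mlvl = None
            self.forcing = None

        pr = spec.priors
        self.sigma_scale = (
            pr.sigma_scale if pr.sigma_scale is not None else 2.0 * max(self.y.std(), 1.0)
        )
        self._layout()

    # -- parameter layout ---------------------------------------------------

    def _layout(self):
        idx: dict = {}
        pos = 0

        def add(name, size):
            nonlocal pos
            idx[name] = slice(pos, pos + size)
            pos += size

        if self.spec.pooling == "none":
            add("beta", 3)
            add("phi", self.R)
            add("psi", self.T)
        else:
            add("B" if self.spec.region_coef_param == "centered" else "z", self.R * 4)
            add("m", 4)
            add("log_tau", 4)
            add("u", 6)
            if self.spec.include_group_means:
                add("eta", 3)
            if self.spec.pooling == "region":
                add("psi", self.T)
            else:
                add("w" if self.spec.period_param == "centered" else "zw", self.T)
                add("psi0", 1)
                add("psi_lvl", 3)
                add("log_sigma_w", 1)
        if self.spec.include_region_month_fe:
            add("omega", self.R * 12)
        add("fam", 1)  # log Theta (negbin) or log sigma (normal)
        self.idx = idx
        self.dim = pos

    def init_vector(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        level = np.log(self.y.mean() + 0.05) if self.spec.family == "negbin" else self.y.mean()
        if self.spec.pooling == "none":
            theta[self.idx["phi"]] = level
        else:
            theta[self.idx["m"]][3] = level
            theta[self.idx["log_tau"]] = np.log(0.3)
            if "B" in self.idx:
                B0 = np.zeros((self.R, 4))
                B0[:, 3] = level
                theta[self.idx["B"]] = B0.reshape(-1)
        if self.spec.family == "normal":
            theta[self.idx["fam"]] = np.log(max(self.y.std(), 1.0))
        return theta

    # -- likelihood pieces --------------------------------------------------

    def _region_coefs(self, theta):
        """(B, aux) where B[i] = (a_i, b_i, c_i, f_i)."""
        m = theta[self.idx["m"]]
        tau = np.exp(theta[self.idx["log_tau"]])
        u = theta[self.idx["u"]]
        L, _ = cpc_to_chol(u, 4)
        A = tau[:, None] * L
        if "B" in self.idx:
            B = theta[self.idx["B"]].reshape(self.R, 4)
            z = None
        else:
            z = theta[self.idx["z"]].reshape(self.R, 4)
            B = m[None, :] + z @ A.T
        return B, (z, m, tau, u, L, A)

    def _period_term(self, theta):
        if self.spec.pooling == "region_time":
            psi0 = theta[self.idx["psi0"]][0]
            psi_lvl = theta[self.idx["psi_lvl"]]
            sw = np.exp(theta[self.idx["log_sigma_w"]][0])
            if "w" in self.idx:
                w = theta[self.idx["w"]]
                return w, (None, psi0, psi_lvl, sw)
            zw = theta[self.idx["zw"]]
            w = psi0 + self.Mlvl @ psi_lvl + sw * zw
            return w, (zw, psi0, psi_lvl, sw)
        return theta[self.idx["psi"]], None

    def linear_predictor(self, theta: np.ndarray) -> np.ndarray:
        if self.spec.pooling == "none":
            beta = theta[self.idx["beta"]]
            lp = self.X @ beta + theta[self.idx["phi"]][self.r]
            lp = lp + self._period_term(theta)[0][self.t]
        else:
            B, _ = self._region_coefs(theta)
            lp = (
                np.einsum("nk,nk->n", self.X, B[self.r, :3])
                + B[self.r, 3]
                + self._period_term(theta)[0][self.t]
            )
            if self.spec.include_group_means:
                lp = lp + (self.Zbar @ theta[self.idx["eta"]])[self.r]
        if self.spec.include_region_month_fe:
            lp = lp + theta[self.idx["omega"]][self.rm]
        return lp

    # -- log posterior and gradient -----------------------------------------

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        y, n = self.y, self.n
        pr = self.spec.priors
        cs2 = pr.coef_scale**2
        grad = np.zeros(self.dim)
        lp_lin = self.linear_predictor(theta)
        if not np.all(np.isfinite(lp_lin)):
            return -np.inf, grad

        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            if self.spec.family == "negbin":
                lt = theta[self.idx["fam"]][0]
                th = np.exp(lt)
                mu = np.exp(lp_lin)
                if not np.all(np.isfinite(mu)):
                    return -np.inf, grad
                ll = np.sum(
                    special.gammaln(y + th)
                    - special.gammaln(th)
                    + th * lt
                    + y * lp_lin
                    - (y + th) * np.log(mu + th)
                )
                g_obs = y - (y + th) * mu / (mu + th)
                dth = np.sum(
                    special.digamma(y + th)
                    - special.digamma(th)
                    + lt
                    + 1.0
                    - np.log(mu + th)
                    - (y + th) / (mu + th)
                )
                # prior: 1/sqrt(Theta) ~ half-normal(0, theta_scale)
                s2 = pr.theta_scale**2
                ll += -np.exp(-lt) / (2.0 * s2) - 0.5 * lt
                grad[self.idx["fam"]] = th * dth + np.exp(-lt) / (2.0 * s2) - 0.5
            else:
                ls = theta[self.idx["fam"]][0]
                sig = np.exp(ls)
                resid = y - lp_lin
                ll = -n * ls - 0.5 * np.sum(resid**2) / sig**2
                g_obs = resid / sig**2
                # half-normal(0, sigma_scale) on sigma (log parameterization)
                ll += -(sig**2) / (2.0 * self.sigma_scale**2) + ls
                grad[self.idx["fam"]] = (
                    -n + np.sum(resid**2) / sig**2 - sig**2 / self.sigma_scale**2 + 1.0
                )
        if not np.isfinite(ll):
            return -np.inf, grad
        if self.prior_only:
            g_obs = np.zeros_like(g_obs)
            if self.spec.family == "negbin":
                lt = theta[self.idx["fam"]][0]
                s2 = pr.theta_scale**2
                ll = -np.exp(-lt) / (2.0 * s2) - 0.5 * lt
                grad[self.idx["fam"]] = np.exp(-lt) / (2.0 * s2) - 0.5
            else:
                ls = theta[self.idx["fam"]][0]
                sig = np.exp(ls)
                ll = -(sig**2) / (2.0 * self.sigma_scale**2) + ls
                grad[self.idx["fam"]] = -(sig**2) / self.sigma_scale**2 + 1.0

        gt = np.bincount(self.t, weights=g_obs, minlength=self.T)
        gr = np.bincount(self.r, weights=g_obs, minlength=self.R)

        if self.spec.pooling == "none":
            beta = theta[self.idx["beta"]]
            phi = theta[self.idx["phi"]]
            psi = theta[self.idx["psi"]]
            grad[self.idx["beta"]] = self.X.T @ g_obs - beta / cs2
            grad[self.idx["phi"]] = gr - phi / cs2
            grad[self.idx["psi"]] = gt - psi / cs2
            ll += -0.5 * (beta @ beta + phi @ phi + psi @ psi) / cs2
        else:
            B, (z, m, tau, u, L, A) = self._region_coefs(theta)
            GB = np.empty((self.R, 4))
            for k in range(3):
                GB[:, k] = np.bincount(self.r, weights=self.X[:, k] * g_obs, minlength=self.R)
            GB[:, 3] = gr
            eta_quad = 0.0
            if self.spec.include_group_means:
                eta = theta[self.idx["eta"]]
                grad[self.idx["eta"]] = self.Zbar.T @ gr - eta / cs2
                eta_quad = eta @ eta
            ts2 = pr.tau_scale**2
            lkj_lp, lkj_g = lkj_cpc_logprior_grad(u, 4, pr.lkj_eta)
            if z is None:
                # centered: B_i ~ MVN(m, A A') directly
                dA = np.diag(A)
                if not np.all(np.isfinite(A)) or np.min(dA) < 1e-12:
                    return -np.inf, grad  # degenerate covariance proposal
                E = B - m[None, :]
                Ainv = sla.solve_triangular(A, np.eye(4), lower=True)
                V = E @ Ainv.T
                VAinv = V @ Ainv
                grad[self.idx["B"]] = (GB - VAinv).reshape(-1)
                grad[self.idx["m"]] = VAinv.sum(axis=0) - m / cs2
                Abar = Ainv.T @ (V.T @ V) - self.R * np.diag(1.0 / np.diag(A))
                mvn_lp = -0.5 * np.sum(V**2) - self.R * np.sum(np.log(np.diag(A)))
            else:
                # non-centered: B = m + z A', z ~ N(0, 1)
                zflat = z.reshape(-1)
                grad[self.idx["m"]] = GB.sum(axis=0) - m / cs2
                grad[self.idx["z"]] = (GB @ A).reshape(-1) - zflat
                Abar = GB.T @ z  # (4, 4)
                mvn_lp = -0.5 * zflat @ zflat
            taubar = np.sum(np.tril(Abar) * L, axis=1)
            grad[self.idx["log_tau"]] = tau * taubar - tau**2 / ts2 + 1.0
            Lbar = tau[:, None] * np.tril(Abar)
            grad[self.idx["u"]] = chol_pullback(Lbar, u, 4) + lkj_g
            ll += (
                -0.5 * (m @ m + eta_quad) / cs2
                + mvn_lp
                - np.sum(tau**2) / (2.0 * ts2)
                + np.sum(np.log(np.maximum(tau, 1e-300)))
                + lkj_lp
            )
            if self.spec.pooling == "region":
                psi = theta[self.idx["psi"]]
                grad[self.idx["psi"]] = gt - psi / cs2
                ll += -0.5 * psi @ psi / cs2
            else:
                psi0 = theta[self.idx["psi0"]][0]
                psi_lvl = theta[self.idx["psi_lvl"]]
                sw = np.exp(theta[self.idx["log_sigma_w"]][0])
                ws2 = pr.sigma_w_scale**2
                if "w" in self.idx:
                    # centered: w_t ~ normal(psi0 + Mlvl psi, sigma_w) directly
                    w = theta[self.idx["w"]]
                    rw = w - psi0 - self.Mlvl @ psi_lvl
                    grad[self.idx["w"]] = gt - rw / sw**2
                    grad[self.idx["psi0"]] = rw.sum() / sw**2 - psi0 / cs2
                    grad[self.idx["psi_lvl"]] = self.Mlvl.T @ rw / sw**2 - psi_lvl / cs2
                    grad[self.idx["log_sigma_w"]] = (
                        -self.T + np.sum(rw**2) / sw**2 - sw**2 / ws2 + 1.0
                    )
                    ll += (
                        -self.T * np.log(sw)
                        - 0.5 * np.sum(rw**2) / sw**2
                        - 0.5 * (psi0**2 + psi_lvl @ psi_lvl) / cs2
                        - sw**2 / (2.0 * ws2)
                        + np.log(sw)
                    )
                else:
                    zw = theta[self.idx["zw"]]
                    grad[self.idx["zw"]] = gt * sw - zw
                    grad[self.idx["psi0"]] = gt.sum() - psi0 / cs2
                    grad[self.idx["psi_lvl"]] = self.Mlvl.T @ gt - psi_lvl / cs2
                    grad[self.idx["log_sigma_w"]] = (
                        np.sum(gt * zw) * sw - sw**2 / ws2 + 1.0
                    )
                    ll += (
                        -0.5 * zw @ zw
                        - 0.5 * (psi0**2 + psi_lvl @ psi_lvl) / cs2
                        - sw**2 / (2.0 * ws2)
                        + np.log(sw)
                    )

        if self.spec.include_region_month_fe:
            om = theta[self.idx["omega"]]
            gm_ = np.bincount(self.rm, weights=g_obs, minlength=self.R * 12)
            grad[self.idx["omega"]] = gm_ - om / cs2
            ll += -0.5 * om @ om / cs2

        return float(ll), grad

    # -- constrained views ---------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict:
        """Constrained parameter values for a single unconstrained draw."""
        out: dict = {}
        if self.spec.pooling == "none":
            out["beta"] = theta[self.idx["beta"]].copy()
            out["phi"] = theta[self.idx["phi"]].copy()
            out["period_effect"] = theta[self.idx["psi"]].copy()
        else:
            B, (z, m, tau, u, L, A) = self._region_coefs(theta)
            out["coefs"] = B
            out["m"] = m.copy()
            out["tau"] = tau
            out["Omega"] = L @ L.T
            out["eta"] = (
                theta[self.idx["eta"]].copy()
                if self.spec.include_group_means
                else np.zeros(3)
            )
            w, aux = self._period_term(theta)
            out["period_effect"] = np.asarray(w).copy()
            if aux is not None:
                zw, psi0, psi_lvl, sw = aux
                out["psi0"], out["psi_lvl"], out["sigma_w"] = psi0, psi_lvl.copy(), sw
        if self.spec.include_region_month_fe:
            out["omega"] = theta[self.idx["omega"]].copy()
        if self.spec.family == "negbin":
            out["Theta"] = float(np.exp(theta[self.idx["fam"]][0]))
        else:
            out["sigma"] = float(np.exp(theta[self.idx["fam"]][0]))
        return out

    def pointwise_loglik(self, thetas: np.ndarray, chunk: int = 400) -> np.ndarray:
        """(draws, n_obs) matrix of log-likelihood terms."""
        S = thetas.shape[0]
        out = np.empty((S, self.n))
        y = self.y
        for a in range(0, S, chunk):
            b = min(a + chunk, S)
            lps = np.stack([self.linear_predictor(thetas[s]) for s in range(a, b)])
            if self.spec.family == "negbin":
                th = np.exp(thetas[a:b, self.idx["fam"]])  # (chunk, 1)
                mu = np.exp(lps)
                out[a:b] = (
                    special.gammaln(y[None, :] + th)
                    - special.gammaln(th)
                    - special.gammaln(y + 1.0)[None, :]
                    + th * np.log(th)
                    + y[None, :] * lps
                    - (y[None, :] + th) * np.log(mu + th)
                )
            else:
                sig = np.exp(thetas[a:b, self.idx["fam"]])
                out[a:b] = (
                    -0.5 * np.log(2.0 * np.pi)
                    - np.log(sig)
                    - 0.5 * ((y[None, :] - lps) / sig) ** 2
                )
        return out

    def simulate(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One replicated outcome vector at a posterior draw."""
        lp = self.linear_predictor(theta)
        if self.spec.family == "negbin":
            th = float(np.exp(theta[self.idx["fam"]][0]))
            mu = np.exp(lp)
            lam = rng.gamma(shape=th, scale=mu / th)
            return rng.poisson(lam).astype(float)
        sig = float(np.exp(theta[self.idx["fam"]][0]))
        return rng.normal(lp, sig)

    # -- named scalar draws for diagnostics and summaries --------------------

    def named_draws(self, result: SamplerResult) -> dict:
        """Map parameter names to (chains, draws) arrays of constrained values."""
        C, S, _ = result.draws.shape
        names: dict = {}

        def collect(fn, keys):
            vals = {k: np.empty((C, S)) for k in keys}
            for c in range(C):
                for s in range(S):
                    d = fn(result.draws[c, s])
                    for k in keys:
                        vals[k][c, s] = d[k]
            names.update(vals)

        if self.spec.pooling == "none":
            def fn(theta):
                out = {}
                beta = theta[self.idx["beta"]]
                out["alpha"], out["gamma"], out["delta"] = beta
                out.update(self._fam_entry(theta))
                return out
            collect(fn, ["alpha", "gamma", "delta"] + self._fam_keys())
        else:
            def fn(theta):
                B, (z, m, tau, u, L, A) = self._region_coefs(theta)
                out = dict(zip(HYPER_NAMES, m))
                for k, nm in enumerate(COEF_NAMES):
                    out[f"tau_{nm}"] = tau[k]
                    for i in range(self.R):
                        out[f"{nm}[{self.panel.regions[i]}]"] = B[i, k]
                if self.spec.include_group_means:
                    out["eta1"], out["eta2"], out["eta3"] = theta[self.idx["eta"]]
                if self.spec.pooling == "region_time":
                    out["psi0"] = theta[self.idx["psi0"]][0]
                    p = theta[self.idx["psi_lvl"]]
                    out["psi1"], out["psi2"], out["psi3"] = p
                    out["sigma_w"] = float(np.exp(theta[self.idx["log_sigma_w"]][0]))
                out.update(self._fam_entry(theta))
                return out
            keys = list(HYPER_NAMES) + [f"tau_{nm}" for nm in COEF_NAMES]
            keys += [f"{nm}[{reg}]" for nm in COEF_NAMES for reg in self.panel.regions]
            if self.spec.include_group_means:
                keys += ["eta1", "eta2", "eta3"]
            if self.spec.pooling == "region_time":
                keys += ["psi0", "psi1", "psi2", "psi3", "sigma_w"]
            keys += self._fam_keys()
            collect(fn, keys)
        return names

    def _fam_keys(self):
        return ["Theta"] if self.spec.family == "negbin" else ["sigma"]

    def _fam_entry(self, theta):
        v = float(np.exp(theta[self.idx["fam"]][0]))
        return {"Theta": v} if self.spec.family == "negbin" else {"sigma": v}


def build_model(
    spec: HierModelSpec, panel: RegionalPanel, prior_only: bool = False
) -> HierModel:
    """Bind a model specification to a balanced panel."""
    if spec.pooling == "region_time" and spec.forcing_mode == "median-ratio":
        # fail early (rather than mid-sampling) if the forcing is undefined
        cf.climate_forcing(panel, spec.forcing_variable, spec.forcing_mode)
    return HierModel(spec, panel, prior_only=prior_only)


@dataclasses.dataclass
class PosteriorDraws:
    """MCMC output: named draws, pointwise log likelihood, diagnostics."""

    model: HierModel
    raw: SamplerResult
    names: dict  # name -> (chains, draws)
    loglik: np.ndarray  # (chains*draws, n_obs)
    rhat: dict
    ess_bulk: dict
    ess_tail: dict
    divergences: int
    flags: list

    @property
    def n_draws(self) -> int:
        return self.raw.draws.shape[0] * self.raw.draws.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.names[name].reshape(-1)

    def theta_stacked(self) -> np.ndarray:
        return self.raw.stacked

    def ok(self) -> bool:
        return not self.flags


def _diagnostics(names: dict) -> tuple[dict, dict, dict]:
    import arviz as az

    data = az.from_dict(posterior={k: v for k, v in names.items()})
    rhat_ds = az.rhat(data)
    essb_ds = az.ess(data, method="bulk")
    esst_ds = az.ess(data, method="tail")
    rhat = {k: float(rhat_ds[k].values) for k in names}
    essb = {k: float(essb_ds[k].values) for k in names}
    esst = {k: float(esst_ds[k].values) for k in names}
    return rhat, essb, esst


def fit_bayes(
    model: HierModel,
    sampler_cfg: SamplerConfig = SamplerConfig(),
    diagnose: bool = True,
) -> PosteriorDraws:
    """Sample the posterior with adaptive HMC and collect diagnostics.

    The fit is delivered regardless of diagnostic outcome; split R-hat >=
    1.01, bulk ESS <= 400 or any post-warmup divergence raise flags (with a
    remediation hint) rather than errors.
    """
    result = sample_hmc(model.logp_and_grad, model.init_vector(), sampler_cfg)
    names = model.named_draws(result)
    loglik = model.pointwise_loglik(result.stacked)

    flags: list = []
    if diagnose:
        rhat, essb, esst = _diagnostics(names)
        worst_rhat = max(rhat.values())
        min_ess = min(essb.values())
        if worst_rhat >= 1.01:
            worst = max(rhat, key=rhat.get)
            flags.append(
                f"split R-hat {worst_rhat:.3f} >= 1.01 ({worst}); consider more "
                "warmup or a smaller step size"
            )
        if min_ess <= 400:
            worst = min(essb, key=essb.get)
            flags.append(
                f"bulk ESS {min_ess:.0f} <= 400 ({worst}); consider more draws"
            )
    else:
        rhat, essb, esst = {}, {}, {}
    ndiv = int(result.divergences.sum())
    if ndiv > 0:
        flags.append(
            f"{ndiv} post-warmup divergence(s); consider a higher acceptance target"
        )
    return PosteriorDraws(model, result, names, loglik, rhat, essb, esst, ndiv, flags)


def posterior_from_draws(
    model: HierModel, theta: np.ndarray, diagnose: bool = True
) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from a saved (chains, draws, dim) array."""
    C, S, dim = theta.shape
    if dim != model.dim:
        raise ValueError(f"draw dimension {dim} does not match model dimension {model.dim}")
    result = SamplerResult(
        draws=np.asarray(theta, dtype=float),
        accept_rate=np.full(C, np.nan),
        divergences=np.zeros(C, dtype=int),
        step_size=np.full(C, np.nan),
        inv_mass=np.ones((C, dim)),
    )
    names = model.named_draws(result)
    loglik = model.pointwise_loglik(result.stacked)
    if diagnose:
        rhat, essb, esst = _diagnostics(names)
    else:
        rhat, essb, esst = {}, {}, {}
    return PosteriorDraws(model, result, names, loglik, rhat, essb, esst, 0, [])


def summarize_posterior(draws: PosteriorDraws, params: Sequence[str] | None = None):
    """Median, MAD-scaled SD (1.4826 * MAD) and central 95% interval.

    Mirrors the study's posterior reporting convention; requires >= 100
    draws for stable tail quantiles.
    """
    import pandas as pd

    if draws.n_draws < 100:
        raise ValueError("need at least 100 draws to summarize a posterior")
    rows = []
    for name in params or draws.names:
        v = draws.stacked(name)
        med = float(np.median(v))
        mad_sd = float(1.4826 * np.median(np.abs(v - med)))
        lo, hi = np.percentile(v, [2.5, 97.5])
        rows.append(
            {
                "param": name,
                "median": med,
                "mad_sd": mad_sd,
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": draws.rhat.get(name, float("nan")),
                "ess_bulk": draws.ess_bulk.get(name, float("nan")),
            }
        )
    return pd.DataFrame(rows).set_index("param")
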