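"""Adaptive Hamiltonian Monte Carlo (NUTS) for the hierarchical models.

A self-contained gradient-based MCMC engine: leapfrog integration with a
diagonal (or dense) mass matrix, dual-averaging step-size adaptation toward
a target acceptance rate, windowed estimation of the metric during warmup,
and No-U-Turn trajectory building (binary doubling with a slice variable,
so trajectory length adapts per iteration; a fixed-length jittered HMC mode
is also available). Models supply ``logp_and_grad(theta) -> (float,
ndarray)`` on an unconstrained parameter space; gradients are exact
(analytic), so the only stochasticity is the momentum refreshment, the
slice/Metropolis correction and the direction choices.

Leapfrog steps whose energy error exceeds :data:`DIVERGENCE_ENERGY` are
counted as divergent and their subtrees rejected, mirroring the usual
HMC/NUTS diagnostic.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import linalg as sla

__all__ = ["SamplerConfig", "SamplerResult", "sample_hmc"]

DIVERGENCE_ENERGY = 1000.0


@dataclasses.dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    algorithm: str = "nuts"  # {"nuts", "hmc"}
    max_treedepth: int = 9  # NUTS: at most 2^depth leapfrog steps
    max_leapfrog: int = 32  # fixed-length HMC mode
    init_jitter: float = 0.5
    metric: str = "diag"  # {"diag", "dense"}

    def __post_init__(self):
        if self.metric not in {"diag", "dense"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.algorithm not in {"nuts", "hmc"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclasses.dataclass
class SamplerResult:
    """Post-warmup draws of shape (chains, draws, dim) plus sampler stats."""

    draws: np.ndarray
    accept_rate: np.ndarray  # per chain, mean acceptance statistic
    divergences: np.ndarray  # per chain, post-warmup
    step_size: np.ndarray  # per chain, adapted
    inv_mass: np.ndarray  # per chain, diagonal of the inverse mass matrix

    @property
    def stacked(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


class _Metric:
    """Inverse-mass metric: kinetic energy, momentum draws, position step."""

    def __init__(self, dim: int, dense: bool):
        self.dense = dense
        self.cov = np.eye(dim) if dense else None  # inverse mass matrix
        self.var = np.ones(dim)
        self._chol = np.eye(dim) if dense else None  # cov = C C'

    def sample_momentum(self, rng) -> np.ndarray:
        xi = rng.standard_normal(len(self.var))
        if self.dense:
            # p ~ N(0, cov^-1): p = C^-T xi
            return sla.solve_triangular(self._chol, xi, lower=True, trans="T")
        return xi / np.sqrt(self.var)

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.apply(p))

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Velocity M^-1 p."""
        return self.cov @ p if self.dense else self.var * p

    def update(self, sample: np.ndarray) -> None:
        """Re-estimate from warmup draws with shrinkage regularization."""
        n = sample.shape[0]
        w = n / (n + 5.0)
        if self.dense:
            S = np.cov(sample.T)
            S = w * S + 1e-3 * (1.0 - w) * np.eye(S.shape[0])
            try:
                self._chol = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                S = S + 1e-6 * np.eye(S.shape[0])
                self._chol = np.linalg.cholesky(S)
            self.cov = S
            self.var = np.diag(S).copy()
        else:
            var = np.var(sample, axis=0)
            self.var = np.clip(w * var + 1e-3 * (1.0 - w), 1e-8, 1e8)


def _leapfrog(logp_grad, q, p, grad, eps, metric, n_steps):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * metric.apply(p)
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, lp, grad
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


class _NutsTree:
    """One No-U-Turn trajectory (binary doubling with a slice variable)."""

    def __init__(self, logp_grad, metric, eps, h0, log_u, rng):
        self.logp_grad = logp_grad
        self.metric = metric
        self.eps = eps
        self.h0 = h0
        self.log_u = log_u
        self.rng = rng
        self.n_div = 0
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def leaf(self, state, v):
        q, p, grad = state
        q1, p1, lp1, g1 = _leapfrog(self.logp_grad, q, p, grad, v * self.eps,
                                    self.metric, 1)
        if np.isfinite(lp1):
            h1 = lp1 - self.metric.kinetic(p1)
        else:
            h1 = -np.inf
        n1 = 1 if self.log_u <= h1 else 0
        divergent = not np.isfinite(h1) or (self.h0 - h1) > DIVERGENCE_ENERGY
        if divergent:
            self.n_div += 1
        self.alpha_sum += min(1.0, float(np.exp(min(h1 - self.h0, 0.0))))
        self.n_alpha += 1
        st = (q1, p1, g1)
        return st, st, (q1, lp1, g1), n1, not divergent

    def build(self, state, v, depth):
        """Returns (minus_state, plus_state, proposal, n, keep_going)."""
        if depth == 0:
            return self.leaf(state, v)
        sm, sp, prop, n, ok = self.build(state, v, depth - 1)
        if ok:
            if v == -1:
                sm, _, prop2, n2, ok2 = self.build(sm, v, depth - 1)
            else:
                _, sp, prop2, n2, ok2 = self.build(sp, v, depth - 1)
            if ok2 and n2 > 0 and self.rng.uniform() < n2 / max(n + n2, 1):
                prop = prop2
            n += n2
            ok = ok2 and self.no_uturn(sm, sp)
        return sm, sp, prop, n, ok

    def no_uturn(self, sm, sp) -> bool:
        dq = sp[0] - sm[0]
        return (dq @ self.metric.apply(sm[1])) >= 0 and (
            dq @ self.metric.apply(sp[1])
        ) >= 0


def _nuts_transition(logp_grad, q, lp, grad, eps, metric, rng, max_depth):
    p0 = metric.sample_momentum(rng)
    h0 = lp - metric.kinetic(p0)
    log_u = h0 + np.log(rng.uniform())
    tree = _NutsTree(logp_grad, metric, eps, h0, log_u, rng)
    sm = sp = (q, p0, grad)
    prop = (q, lp, grad)
    n = 1
    for depth in range(max_depth):
        v = -1 if rng.uniform() < 0.5 else 1
        if v == -1:
            sm, _, prop2, n2, ok = tree.build(sm, v, depth)
        else:
            _, sp, prop2, n2, ok = tree.build(sp, v, depth)
        if ok and n2 > 0 and rng.uniform() < min(1.0, n2 / n):
            prop = prop2
        n += n2
        if not ok or not tree.no_uturn(sm, sp):
            break
    accept_stat = tree.alpha_sum / max(tree.n_alpha, 1)
    return prop, tree.n_div > 0, accept_stat


def _hmc_transition(logp_grad, q, lp, grad, eps, metric, rng, max_leapfrog):
    p = metric.sample_momentum(rng)
    h0 = lp - metric.kinetic(p)
    n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
    q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, grad, eps, metric, n_steps)
    delta_h = (lp1 - metric.kinetic(p1)) - h0 if np.isfinite(lp1) else -np.inf
    divergent = (not np.isfinite(delta_h)) or (-delta_h > DIVERGENCE_ENERGY)
    accept_stat = 0.0 if divergent else min(1.0, float(np.exp(min(delta_h, 0.0))))
    if not divergent and np.log(rng.uniform()) < delta_h:
        return (q1, lp1, g1), divergent, accept_stat
    return (q, lp, grad), divergent, accept_stat


def _find_initial_step(logp_grad, q, rng, metric):
    """Double/halve the step until single-step acceptance crosses 0.5."""
    eps = 0.1
    lp0, grad0 = logp_grad(q)
    p = metric.sample_momentum(rng)
    h0 = lp0 - metric.kinetic(p)
    _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad0, eps, metric, 1)
    h1 = lp1 - metric.kinetic(p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad0, eps, metric, 1)
        h1 = lp1 - metric.kinetic(p1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def _mass_windows(warmup: int) -> list[tuple[int, int]]:
    """(start, end) warmup intervals whose draws feed metric updates."""
    start = int(0.15 * warmup)
    end = int(0.9 * warmup)
    windows = []
    size = max(25, (end - start) // 8)
    a = start
    while a < end:
        b = min(a + size, end)
        if end - b < size // 2:
            b = end
        windows.append((a, b))
        size *= 2
        a = b
    return windows


def _run_chain(logp_grad, init, cfg: SamplerConfig, rng: np.random.Generator):
    dim = len(init)
    q = init + cfg.init_jitter * rng.standard_normal(dim)
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        q = init.copy()
        lp, grad = logp_grad(q)
    metric = _Metric(dim, dense=cfg.metric == "dense")
    eps = _find_initial_step(logp_grad, q, rng, metric)

    # dual averaging state; da_m restarts whenever the metric changes
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _mass_windows(cfg.warmup)
    window_buf: list[np.ndarray] = []
    w_idx = 0

    n_total = cfg.warmup + cfg.draws
    draws = np.empty((cfg.draws, dim))
    accept_sum = 0.0
    n_div = 0

    for it in range(n_total):
        if cfg.algorithm == "nuts":
            (q, lp, grad), divergent, accept_stat = _nuts_transition(
                logp_grad, q, lp, grad, eps, metric, rng, cfg.max_treedepth
            )
        else:
            (q, lp, grad), divergent, accept_stat = _hmc_transition(
                logp_grad, q, lp, grad, eps, metric, rng, cfg.max_leapfrog
            )
        if it >= cfg.warmup:
            accept_sum += accept_stat
            if divergent:
                n_div += 1

        if it < cfg.warmup:
            # dual averaging toward the target acceptance rate
            da_m += 1
            h_bar = (1.0 - 1.0 / (da_m + t0)) * h_bar + (
                cfg.target_accept - accept_stat
            ) / (da_m + t0)
            log_eps = np.clip(mu - np.sqrt(da_m) / gamma * h_bar, -12.0, 4.0)
            w = da_m**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # windowed metric estimation
            if w_idx < len(windows):
                a, b = windows[w_idx]
                if a <= it < b:
                    window_buf.append(q.copy())
                if it == b - 1 and len(window_buf) >= 10:
                    metric.update(np.asarray(window_buf))
                    window_buf = []
                    w_idx += 1
                    eps = _find_initial_step(logp_grad, q, rng, metric)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
            if it == cfg.warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - cfg.warmup] = q

    return draws, accept_sum / max(cfg.draws, 1), n_div, eps, metric.var


def sample_hmc(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    cfg: SamplerConfig,
) -> SamplerResult:
    """Run ``cfg.chains`` independent NUTS/HMC chains from jittered ``init``.

    Chain randomness derives deterministically from ``cfg.seed`` via
    ``SeedSequence([seed, chain])``; identical configs give identical draws.
    """
    init = np.asarray(init, dtype=float)
    all_draws = np.empty((cfg.chains, cfg.draws, len(init)))
    acc = np.empty(cfg.chains)
    div = np.empty(cfg.chains, dtype=int)
    steps = np.empty(cfg.chains)
    inv_masses = np.empty((cfg.chains, len(init)))
    for c in range(cfg.chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), c]))
        d, a, nd, e, im = _run_chain(logp_grad, init, cfg, rng)
        all_draws[c], acc[c], div[c], steps[c], inv_masses[c] = d, a, nd, e, im
    return SamplerResult(all_draws, acc, div, steps, inv_masses)
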