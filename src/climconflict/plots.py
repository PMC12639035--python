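"""Diagnostic and posterior plots (QQ, posterior densities, PPC histogram)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .bayes_hier import PosteriorDraws  # noqa: E402
from .evaluation import PPCResult  # noqa: E402
from .fe_ols import DiagnosticsReport  # noqa: E402

__all__ = ["qq_plot", "posterior_density_plot", "ppc_histogram"]


def qq_plot(report: DiagnosticsReport, title: str, path: str | Path) -> Path:
    """Normal QQ plot of (standardized) residuals with the KS result."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.qq_theoretical, report.qq_sample, ".", ms=3, alpha=0.6)
    lim = [report.qq_theoretical.min(), report.qq_theoretical.max()]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("theoretical normal quantile")
    ax.set_ylabel("sample quantile")
    ax.set_title(f"{title}\nKS p = {report.ks_p:.2e}")
    return _save(fig, path)


def posterior_density_plot(
    draws: PosteriorDraws, params: Sequence[str], path: str | Path
) -> Path:
    """Kernel-free posterior densities (histograms) with 95% intervals."""
    n = len(params)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 2.8), squeeze=False)
    for ax, name in zip(axes[0], params):
        v = draws.stacked(name)
        ax.hist(v, bins=50, density=True, color="steelblue", alpha=0.7)
        lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5])
        ax.axvline(med, color="k", lw=1)
        ax.axvspan(lo, hi, color="steelblue", alpha=0.2)
        ax.set_title(name)
        ax.set_yticks([])
    return _save(fig, path)


def ppc_histogram(result: PPCResult, path: str | Path) -> Path:
    """Replicated test-statistic distribution with the observed value."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(result.replicated_stats, bins=40, color="lightblue", edgecolor="none")
    ax.axvline(result.observed_stat, color="darkblue", lw=2)
    ax.set_xlabel(result.statistic)
    ax.set_ylabel("replicates")
    ax.set_title(f"posterior predictive check (ppp = {result.ppp:.3f})")
    return _save(fig, path)


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
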