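"""Fit the Bayesian model ladder on the baseline panel.

Four rungs, fit by adaptive HMC: the Gaussian fixed-effects model, the
single-level NB model, the region-partial-pooling NB model with group-mean
correction, and the temporally pooled NB model with the climate forcing.
Posterior summaries (median, MAD-scaled SD, 95% credible interval) are
written per model, raw draws and pointwise log likelihoods are archived
for the comparison step.
"""

import sys
import time
from pathlib import Path

import numpy as np

from climconflict.bayes_hier import HierModelSpec, MODEL_LADDER, build_model, fit_bayes, summarize_posterior
from climconflict.panel_core import load_panel
from climconflict.pipeline import SUMMARY_PARAMS
from climconflict.sampling import SamplerConfig

DATA = Path("results/data/baseline")
OUT = Path("results/bayes")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260927


def main() -> None:
    panel = load_panel(DATA / "panel.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (name, family, pooling) in enumerate(MODEL_LADDER):
        model = build_model(HierModelSpec(family=family, pooling=pooling), panel)
        t0 = time.time()
        draws = fit_bayes(model, SamplerConfig(chains=2, warmup=700, draws=700,
                                               seed=SEED + i))
        summary = summarize_posterior(draws, SUMMARY_PARAMS.get(name))
        summary.to_csv(OUT / f"posterior_{name}.csv")
        np.savez_compressed(OUT / f"draws_{name}.npz", theta=draws.raw.draws)
        print(f"--- {name} ({model.dim} parameters, {time.time() - t0:.0f}s, "
              f"{draws.divergences} divergences) ---")
        print(summary.round(3).to_string())
        for flag in draws.flags:
            print(f"  note: {flag}")


if __name__ == "__main__":
    main()
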