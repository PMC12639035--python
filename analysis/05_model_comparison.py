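"""Compare the fitted ladder: PSIS-LOO ELPD and posterior predictive checks.

Reloads the archived draws, recomputes pointwise log likelihoods, ranks
the models by ELPD with paired-difference standard errors, and runs the
proportion-of-zeros posterior predictive check for every rung. The
expected picture: the Gaussian model is far behind and its replicated
panels contain almost no zeros; each pooling step improves ELPD.
"""

from pathlib import Path

import numpy as np

from climconflict.bayes_hier import HierModelSpec, MODEL_LADDER, build_model, posterior_from_draws
from climconflict.evaluation import elpd_compare, ppc_replicate, psis_loo
from climconflict.panel_core import load_panel
from climconflict.plots import posterior_density_plot, ppc_histogram

DATA = Path("results/data/baseline")
BAYES = Path("results/bayes")
OUT = Path("results/comparison")


def main() -> None:
    panel = load_panel(DATA / "panel.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    loos, ppc_rows = [], []
    for name, family, pooling in MODEL_LADDER:
        theta = np.load(BAYES / f"draws_{name}.npz")["theta"]
        model = build_model(HierModelSpec(family=family, pooling=pooling), panel)
        draws = posterior_from_draws(model, theta, diagnose=False)
        loos.append(psis_loo(draws.loglik, label=name))
        ppc = ppc_replicate(draws, n_rep=2000, seed=11)
        ppc_rows.append((name, ppc.observed_stat, float(np.median(ppc.replicated_stats)), ppc.ppp))
        ppc_histogram(ppc, OUT / f"ppc_zeros_{name}.png")
        if pooling != "none":
            posterior_density_plot(draws, ["alpha0", "gamma0", "delta0"],
                                   OUT / f"posterior_slopes_{name}.png")

    table = elpd_compare(loos).to_frame()
    table.to_csv(OUT / "elpd_comparison.csv")
    print(table.round(1).to_string())
    print("\nPPC, proportion of zeros (observed vs replicated median, two-sided ppp):")
    for name, obs, med, ppp in ppc_rows:
        print(f"  {name:16s} obs {obs:.3f}  rep {med:.3f}  ppp {ppp:.3f}")


if __name__ == "__main__":
    main()
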