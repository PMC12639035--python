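"""Generate the study panels.

Produces two synthetic region x month panels at the study scale (18
regions, 156 months starting 1997) with known generating truth:

* ``baseline`` -- the default Somalia-like configuration;
* ``confounded`` -- the same process with the region-intercept component
  deliberately correlated with the region-mean temperature anomaly, the
  condition under which the group-mean (within-between) correction earns
  its keep.

Artifacts (panel.csv, geometry.csv, truth.json per scenario) go to
``results/data/``.
"""

import sys
from pathlib import Path

from climconflict.panel_core import write_geometry, write_panel
from climconflict.synthetic_data import SyntheticConfig, simulate_panel

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260927


def main() -> None:
    for name, kappa in (("baseline", 0.0), ("confounded", 1.0)):
        cfg = SyntheticConfig(confounding_strength=kappa, seed=SEED)
        panel, geometry, truth = simulate_panel(cfg)
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        write_panel(panel, d / "panel.csv")
        write_geometry(geometry, d / "geometry.csv")
        truth.to_json(d / "truth.json")
        y = panel.counts()
        print(
            f"{name}: {panel.n_obs} rows, zero share {(y == 0).mean():.2f}, "
            f"mean count {y.mean():.2f}, max {y.max()}"
        )


if __name__ == "__main__":
    main()
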