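"""Construct and inspect the derived climate features.

Attaches region- and period-level group means to the baseline panel,
builds the country-wide climate forcing from the precipitation anomaly
(standardized-deviation mode; the median-ratio form is undefined for
anomaly series whose per-region medians are ~0), and reports summary
statistics of every regressor. Output: results/features/panel_features.csv.
"""

from pathlib import Path

from climconflict import climate_features as cf
from climconflict.panel_core import load_panel

DATA = Path("results/data/baseline")
OUT = Path("results/features")


def main() -> None:
    panel = load_panel(DATA / "panel.csv")
    panel = cf.attach_group_means(panel)
    forcing = cf.climate_forcing(panel, "PA", "mean-deviation")
    lookup = dict(zip(panel.periods, forcing.values))
    panel = panel.with_column("C_t", panel.data["period"].map(lookup).to_numpy())

    OUT.mkdir(parents=True, exist_ok=True)
    panel.data.to_csv(OUT / "panel_features.csv", index=False)

    desc = panel.data[["conflict", "TA", "DL", "PA", "C_t"]].describe().T
    desc.to_csv(OUT / "feature_summary.csv")
    print(desc[["mean", "std", "min", "max"]].round(3))
    dl = panel.column("DL")
    print(f"\ndrought spells: share of months in drought {(dl > 0).mean():.2f}, "
          f"longest spell {int(dl.max())} months")


if __name__ == "__main__":
    main()
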