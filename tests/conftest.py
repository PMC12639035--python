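import numpy as np
import pandas as pd
import pytest

from climconflict.panel_core import panel_from_frame
from climconflict.synthetic_data import SyntheticConfig, simulate_panel


def make_panel_frame(n_regions, n_periods, seed=0, first_year=2000, counts=None):
    """Hand-rolled balanced panel frame with random regressors."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_regions):
        for t in range(n_periods):
            year, month = first_year + t // 12, t % 12 + 1
            rows.append(
                {
                    "region": f"G{i}",
                    "year": year,
                    "month": month,
                    "conflict": 0,
                    "TA": rng.normal(),
                    "DL": float(rng.integers(0, 5)),
                    "PA": rng.normal(),
                }
            )
    df = pd.DataFrame(rows)
    if counts is None:
        counts = rng.poisson(2.0, size=len(df))
    df["conflict"] = counts
    return df


@pytest.fixture
def toy_panel():
    """3 regions x 4 periods, Poisson counts."""
    return panel_from_frame(make_panel_frame(3, 4, seed=1))


@pytest.fixture(scope="session")
def small_synthetic():
    """6 regions x 36 months synthetic panel with truth and geometry."""
    return simulate_panel(SyntheticConfig(n_regions=6, n_years=3, seed=11))


@pytest.fixture(scope="session")
def medium_synthetic():
    """10 regions x 72 months panel used by the directional-claims checks."""
    return simulate_panel(SyntheticConfig(n_regions=10, n_years=6, seed=3))


@pytest.fixture(scope="session")
def study_synthetic():
    """Study-scale panel: 18 regions x 156 months (1997-2009)."""
    return simulate_panel(SyntheticConfig(seed=1))
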