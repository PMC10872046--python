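import numpy as np
import pandas as pd
import pytest

from edgeshift.grid import GridSpec

MASTER_SEED = 20260920  # suite-wide seed for heavy simulations

PERIODS = {"T1": (1992, 1996), "T2": (2013, 2017)}


@pytest.fixture
def periods():
    return dict(PERIODS)


@pytest.fixture
def small_grid():
    """A 4 x 6 toy grid of 10-km cells."""
    return GridSpec(0.0, 0.0, 40_000.0, 60_000.0, 10_000.0)


@pytest.fixture
def study_grid():
    from edgeshift.synthetic import STUDY_GRID

    return STUDY_GRID


def make_records(rows):
    """Occurrence table from (species, easting, northing, year) tuples."""
    return pd.DataFrame(
        rows, columns=["species_id", "easting_m", "northing_m", "year"]
    )


@pytest.fixture
def regression_table():
    """Small deterministic table with known linear structure."""
    rng = np.random.default_rng(42)
    n = 80
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    f = rng.choice(["a", "b", "c"], n)
    y = 3.0 + 2.0 * x1 - 1.0 * x2 + (f == "b") * 1.5 + rng.normal(0, 0.5, n)
    return pd.DataFrame(
        {
            "shift_km": y,
            "weight": rng.uniform(0.5, 2.0, n),
            "x1": x1,
            "x2": x2,
            "f": f,
        }
    )
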