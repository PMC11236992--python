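import numpy as np
import pandas as pd
import pytest

from thermoshift.io_formats import CensusSeries, ClimateGrid
from thermoshift.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def ramp_grid():
    """10x10 grid whose cell (r, c) holds 10*r + c, origin (0, 0), cell 0.5."""
    values = np.arange(100, dtype=float).reshape(10, 10)
    return ClimateGrid(variable="MAT", origin_lon=0.0, origin_lat=0.0, cell_size=0.5, values=values)


@pytest.fixture(scope="session")
def const_grid():
    return ClimateGrid(
        variable="MAT", origin_lon=0.0, origin_lat=0.0, cell_size=0.5,
        values=np.full((10, 10), 17.3),
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_plots=6, n_species=40, stems_per_plot=100, n_height_measured=30)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    return simulate_bundle(small_cfg, 7)


def build_series(records, dates, plot_id="T1"):
    """CensusSeries from (tag, species, census_index, diameter, alive) tuples."""
    dates = np.asarray(dates, dtype=float)
    rows = [
        {
            "plot_id": plot_id,
            "tag": tag,
            "species": sp,
            "census_index": ci,
            "census_date": dates[ci],
            "diameter_cm": diam,
            "alive": alive,
            "height_m": np.nan,
        }
        for tag, sp, ci, diam, alive in records
    ]
    return CensusSeries(plot_id=plot_id, stems=pd.DataFrame(rows), censuses=dates)


@pytest.fixture(scope="session")
def two_species_series():
    """First census {A(10) x2, B(20) x2}; one A dies, one B recruits."""
    records = [
        ("a1", "A", 0, 12.0, True),
        ("a2", "A", 0, 12.0, True),
        ("b1", "B", 0, 12.0, True),
        ("b2", "B", 0, 12.0, True),
        ("a1", "A", 1, 12.0, False),  # death
        ("a2", "A", 1, 12.5, True),
        ("b1", "B", 1, 12.5, True),
        ("b2", "B", 1, 12.5, True),
        ("b3", "B", 1, 11.0, True),  # recruit
    ]
    return build_series(records, [2010.0, 2020.0])


@pytest.fixture(scope="session")
def ab_optima():
    return pd.Series({"A": 10.0, "B": 20.0})
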