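"""Shared fixtures: a hand-tabulated miniature dataset and a simulated one."""

import pandas as pd
import pytest
from hypothesis import settings

from resurvey.data_model import assemble_dataset
from resurvey.synthetic import SimulationConfig, simulate_surveys

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_survey_frame(rows):
    """rows: (plot, transect, block, year, species, cover)."""
    return pd.DataFrame(
        rows,
        columns=["plot_id", "transect_id", "block_id", "year", "species_id", "cover"],
    )


@pytest.fixture
def mini_traits():
    return pd.DataFrame(
        {
            "species_id": ["a", "b", "c", "d", "ann"],
            "altitudinal_rank": [1, 2, 3, 4, 3],
            "moisture_rank": [4, 3, 2, 1, 2],
            "is_annual": [False, False, False, False, True],
        }
    ).set_index("species_id")


@pytest.fixture
def mini_attrs():
    plots = ["p1", "p2", "p3", "p4"]
    return pd.DataFrame(
        {
            "plot_id": plots,
            "transect_id": ["t1", "t1", "t2", "t2"],
            "block_id": ["A", "A", "B", "B"],
            "elevation_m": [3000.0, 3050.0, 3200.0, 3250.0],
            "aspect_deg": [180.0, 170.0, 190.0, 200.0],
            "slope_deg": [25.0, 30.0, 35.0, 28.0],
            "rock_pct": [30.0, 40.0, 50.0, 45.0],
            "scree_pct": [30.0, 20.0, 20.0, 25.0],
            "soil_pct": [10.0, 10.0, 5.0, 5.0],
            "veg_pct": [30.0, 30.0, 25.0, 25.0],
            "disturbed_years": [frozenset()] * 4,
        }
    ).set_index("plot_id")


@pytest.fixture
def mini_records():
    # hand-tabulated: p1 {a:10, b:5, c:1} → {b:5, c:2, d:1}
    #                 p2 {a:2}            → {}        (all species vanish)
    #                 p3 {}               → {a:1, b:1, c:1}
    #                 p4 {a:4, b:4}       → {a:4, b:4} (unchanged)
    rows = []
    for plot, tr, bl, year, sp, cov in [
        ("p1", "t1", "A", 1994, "a", 10.0),
        ("p1", "t1", "A", 1994, "b", 5.0),
        ("p1", "t1", "A", 1994, "c", 1.0),
        ("p1", "t1", "A", 2004, "b", 5.0),
        ("p1", "t1", "A", 2004, "c", 2.0),
        ("p1", "t1", "A", 2004, "d", 1.0),
        ("p2", "t1", "A", 1994, "a", 2.0),
        ("p3", "t2", "B", 2004, "a", 1.0),
        ("p3", "t2", "B", 2004, "b", 1.0),
        ("p3", "t2", "B", 2004, "c", 1.0),
        ("p4", "t2", "B", 1994, "a", 4.0),
        ("p4", "t2", "B", 1994, "b", 4.0),
        ("p4", "t2", "B", 2004, "a", 4.0),
        ("p4", "t2", "B", 2004, "b", 4.0),
    ]:
        rows.append((plot, tr, bl, year, sp, cov))
    return make_survey_frame(rows)


@pytest.fixture
def mini_dataset(mini_records, mini_traits, mini_attrs):
    return assemble_dataset(mini_records, mini_traits, mini_attrs, (1994, 2004))


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(plots_per_block=25, seed=7)


@pytest.fixture(scope="session")
def sim_outputs(sim_config):
    return simulate_surveys(sim_config)


@pytest.fixture(scope="session")
def sim_dataset(sim_config, sim_outputs):
    records, traits, attrs, _ = sim_outputs
    return assemble_dataset(records, traits, attrs, sim_config.years)
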