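import pandas as pd
import pytest

import lucarbon as lc


@pytest.fixture(scope="session")
def landscape_config():
    return lc.gen_national_like(n_pixels=250, seed=3)


@pytest.fixture(scope="session")
def landscape(landscape_config):
    """(grid, biomass table, admin stats) for a national-like synthetic run."""
    return lc.gen_landscape(landscape_config)


@pytest.fixture(scope="session")
def params(landscape):
    _, biomass, _ = landscape
    return lc.build_params({}, biomass)


@pytest.fixture(scope="session")
def baseline_result(landscape, params):
    grid, _, _ = landscape
    return lc.run_grid(grid, params)


@pytest.fixture(scope="session")
def scenario_table(landscape):
    grid, biomass, admin = landscape
    return lc.run_all(grid, biomass, admin)


@pytest.fixture(scope="session")
def cap114():
    """A forest type calibrated exactly to the headline curve: CAP=114,
    baseline 5 tC/ha at age 0, 99% of CAP at 40 years, no root carbon."""
    alpha, beta = lc.calibrate_logistic(114.0, 5.0, 0.99, 40.0)
    return lc.ForestTypeParams("cap114", 114.0, 40.0, alpha, beta, 0.0)


def make_pixel_row(
    pixel_id="p0",
    area_ha=10_000.0,
    forest_type="amazon",
    soc_ref=100.0,
    covers=("forest", "forest", "forest"),
    department="dept",
    municipality="dept_m1",
):
    return {
        "pixel_id": pixel_id,
        "area_ha": area_ha,
        "forest_type": forest_type,
        "agb_biomass_t_ha": 0.0,
        "soc_ref": soc_ref,
        "department": department,
        "municipality": municipality,
        "cover_1990": covers[0],
        "cover_2000": covers[1],
        "cover_2010": covers[2],
    }


def make_grid(*rows):
    return pd.DataFrame(list(rows))
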