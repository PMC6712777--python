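import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from prevadjust import default_design, default_scenario, generate_population
from prevadjust.datamodel import (
    AGE_GROUPS_DEFAULT,
    MEMBER_AUX_PREFIX,
    NATIONAL_AUX_PREFIX,
    CellTable,
    build_cell_grid,
)


@pytest.fixture(scope="session")
def small_pop():
    """One reference synthetic population at desk scale (2 x 4 districts)."""
    scn = default_scenario(districts_per_region=(4, 4), seed=0)
    return generate_population(scn, seed=123)


@pytest.fixture(scope="session")
def design():
    return default_design()


def build_tiny_frame(
    districts_per_region=(2, 2),
    aux_labels=("E11_secondary", "K29_secondary"),
    with_truth=True,
) -> pd.DataFrame:
    """Deterministic small dense cell table for structural tests."""
    grid = build_cell_grid(districts_per_region, AGE_GROUPS_DEFAULT)
    n = len(grid)
    f = grid.copy()
    i = np.arange(n)
    f["n_national"] = 1000 + 10 * i + (i * 11) % 13
    f["n_member"] = 400 + 3 * i + (i * 5) % 7
    f["y_member"] = 30 + i + (i * 13) % 7
    if with_truth:
        f["y_national_true"] = 90 + 2 * i + (i * 13) % 7
    for k, lab in enumerate(aux_labels):
        f[NATIONAL_AUX_PREFIX + lab] = 200.0 + 5 * i + 17 * k + (i * (7 + 3 * k)) % 11
        f[MEMBER_AUX_PREFIX + lab] = 80.0 + 2 * i + 5 * k + (i * (3 + 2 * k)) % 5
    return f


@pytest.fixture
def tiny_frame():
    return build_tiny_frame()


@pytest.fixture
def tiny_table(tiny_frame):
    return CellTable(tiny_frame)
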