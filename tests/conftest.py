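import math

import pytest

from snakerisk.synthetic import SyntheticConfig, generate_country, records_to_frames


@pytest.fixture(scope="session")
def small_country():
    """10x10 lattice, 4 states: fast fixture shared by downstream-stage tests."""
    cfg = SyntheticConfig(n_states=4, grid_rows=10, grid_cols=10, seed=7)
    records, polygons, truth = generate_country(cfg)
    return cfg, records, polygons, truth


@pytest.fixture(scope="session")
def small_frames(small_country):
    _, records, _, _ = small_country
    return records_to_frames(records)


@pytest.fixture(scope="session")
def medium_country():
    """30x30 lattice, 9 states: used where quartiles need fuller states."""
    cfg = SyntheticConfig(n_states=9, grid_rows=30, grid_cols=30, seed=11)
    records, polygons, truth = generate_country(cfg)
    return cfg, records, polygons, truth


@pytest.fixture(scope="session")
def recovery_config():
    """Two-driver generator settings with known coefficients for recovery tests."""
    return dict(
        n_states=4,
        grid_rows=50,
        grid_cols=100,
        beta={"temperature": 0.6, "urban_pct": -0.7},
        beta0=math.log(20),
        theta=1.2,
    )
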