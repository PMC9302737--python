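"""Shared fixtures: a scaled-down synthetic world (~1/12 of the full region)
so unit tests run in seconds; structural properties do not depend on size."""

import pytest

from gridpopsim import GridSpec, SimulationConfig, simulate_households

SMALL_YEAR_COUNTS = {
    "urban_slum": {2001: 1096, 2006: 1502, 2011: 2382, 2016: 2917},
    "urban_nonslum": {2001: 3475, 2006: 4145, 2011: 4640, 2016: 4820},
    "rural": {2001: 311, 2006: 346, 2011: 402, 2016: 402},
}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        grid=GridSpec(n_rows=120, n_cols=120),
        year_counts={s: dict(c) for s, c in SMALL_YEAR_COUNTS.items()},
        n_slum_patches=2,
        slum_patch_radius=5.0,
        n_small=60,
        n_large=4,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    households, strata = simulate_households(small_config, seed=11)
    return small_config, households, strata
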