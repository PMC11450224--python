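import numpy as np
import pytest

from pollenda import (
    GridSpec,
    LinearTransport,
    NoiseConfig,
    RunConfig,
    build_year_scenario,
    gen_landscape,
    gen_meteo,
    load_taxon,
    run_first_guess,
)


@pytest.fixture(scope="session")
def grid_small() -> GridSpec:
    return GridSpec(0.0, 8.0, 47.0, 53.0, 8, 6)


@pytest.fixture(scope="session")
def birch():
    return load_taxon("birch")


@pytest.fixture(scope="session")
def meteo_small(grid_small):
    return gen_meteo(grid_small, 60, seed=42, start="2000-03-01")


@pytest.fixture(scope="session")
def landscape_small(grid_small, birch):
    return gen_landscape(grid_small, birch, seed=7)


@pytest.fixture(scope="session")
def transport_small(meteo_small, birch):
    return LinearTransport.from_meteo(meteo_small, birch)


@pytest.fixture(scope="session")
def scenario_small():
    """A complete small noisy birch scenario with its first guess."""
    cfg = RunConfig(
        grid=GridSpec(0.0, 8.0, 47.0, 53.0, 8, 6),
        n_stations=8,
        clustering=0.0,
        station_layout="stratified",
        noise=NoiseConfig(lognormal_sigma=0.2, missing_prob=0.05),
        seed=11,
    )
    scen = build_year_scenario(cfg, 2000)
    fg = run_first_guess(scen)
    return cfg, scen, fg
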