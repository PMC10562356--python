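import numpy as np
import pytest

import forcarb_uq as f


@pytest.fixture(scope="session")
def landscape():
    return f.generate_landscape(seed=1)


@pytest.fixture(scope="session")
def pools():
    return f.generate_parameter_pools(300, 11)


@pytest.fixture(scope="session")
def harvest_stats():
    return f.generate_harvest_statistics(12)


@pytest.fixture(scope="session")
def default_params():
    return f.ParameterSet()


@pytest.fixture(scope="session")
def scenario_grid(landscape, pools, harvest_stats):
    """Test-scale ensemble grid: 4 regions, <=500 pixels, n_sim=50, RCP4.5
    x all four harvest scenarios. Shared across the ensemble-level tests."""
    cfg = f.SimulationConfig(n_sim=50, n_pixels=500)
    return {
        h: f.run_monte_carlo(landscape, h, cfg, pools=pools, stats=harvest_stats,
                             rcp="RCP4.5", master_seed=3)
        for h in ("NoHarv", "LowHarv", "BaseHarv", "MaxHarv")
    }


def make_stand_state(n, rng=None, **overrides):
    """A valid random StandState for property-style tests."""
    rng = rng or np.random.default_rng(0)
    species = rng.dirichlet(np.ones(3), size=n)
    dbh = rng.uniform(1.0, 35.0, n)
    state = f.StandState(
        tree_c=rng.uniform(0.0, 90000.0, n),
        gv_c=rng.uniform(0.0, 2500.0, n),
        basal_area=rng.uniform(0.0, 35.0, n),
        dbh=dbh,
        height=2.2 * dbh ** 0.68,
        age=rng.uniform(0.0, 140.0, n),
        species=species,
        volume=rng.uniform(0.0, 300.0, n),
        stems=rng.uniform(100.0, 3000.0, n),
        crown_height=rng.uniform(0.0, 10.0, n),
        site_type=rng.integers(1, 6, n),
        soil_class=rng.integers(0, 2, n).astype(np.int8),
        land_class=np.zeros(n, dtype=np.int8),
    )
    for k, v in overrides.items():
        setattr(state, k, v)
    return state
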