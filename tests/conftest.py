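import numpy as np
import pytest

from beecorridors.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def tiny_scenario():
    """A small but complete study bundle shared across integration tests."""
    cfg = ScenarioConfig(
        seed=11, n_rows=300, n_cols=300, cell_size=20.0,
        n_sites_per_country=8, min_separation_m=500.0,
    )
    return generate_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
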