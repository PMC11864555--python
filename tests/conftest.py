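import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixed_scenario():
    from chumrun.simulate import make_scenario_preset

    return make_scenario_preset("mixed-13yr", seed=11)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free mixed-13yr dataset, shared across tests (read-only)."""
    from chumrun.simulate import make_scenario_preset, simulate_dataset

    scenario = make_scenario_preset("mixed-13yr", seed=11).without_noise()
    return scenario, simulate_dataset(scenario)


@pytest.fixture(scope="session")
def noisy_phenology():
    """One noisy mixed-13yr phenology table with labels."""
    from chumrun.phenology import phenology_table
    from chumrun.regimes import label_years
    from chumrun.simulate import make_scenario_preset, simulate_dataset

    scenario = make_scenario_preset("mixed-13yr", seed=23)
    ds = simulate_dataset(scenario)
    sst = ds.data[ds.data["location"] == "sst"]
    _, labels = label_years(sst)
    phen = phenology_table(
        ds.data[ds.data["location"] == "coast"],
        ds.data[ds.data["location"] == "river"],
        labels,
    )
    return scenario, ds, labels, phen
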