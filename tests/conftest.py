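import pytest

from gravitr import refet, synthetic as syn


@pytest.fixture(scope="session")
def weather_day():
    """One simulated day of weather with derived columns."""
    cfg = syn.SimulationConfig(seed=7, n_days=1)
    return refet.derive_weather(syn.simulate_weather(cfg).set_index("timestamp"))


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic experiment: 3 clusters x 4 genotypes x 2 reps."""
    cfg = syn.SimulationConfig(seed=42, n_days=6, irrigation_days=(2,))
    return syn.make_population(cfg, n_genotypes_per_cluster=4, n_replicates=2)


@pytest.fixture(scope="session")
def default_bundle():
    """The default-size experiment (3 x 16 genotypes x 4 reps, 15 days)."""
    return syn.make_population(syn.SimulationConfig(seed=11))
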