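import pytest

from heatrhythm import FarmConfig, HeatwaveEvent, generate_study, join_with_stress


@pytest.fixture(scope="session")
def small_study():
    """Cheap 4-day farm for IO and pipeline plumbing tests."""
    cfg = FarmConfig(n_sensors=3, n_animals=6, n_days=4,
                     heatwave_schedule=(HeatwaveEvent(2, 3, 5.0),), seed=123)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full default study: 15 sensors, 40 animals, 14 days, second-half heatwave."""
    return generate_study(FarmConfig(seed=7))


@pytest.fixture(scope="session")
def default_labelled(default_study):
    return join_with_stress(default_study.behavior, default_study.heat_load)
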