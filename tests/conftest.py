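import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishcards import CohortSpec, GameConfig
from fishcards._rng import child_rng

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def game():
    return GameConfig()


@pytest.fixture(scope="session")
def open_water():
    """Config with abundant, slow fish: strikes are never availability-bound."""
    return GameConfig(fish_spawn_interval_s=0.5, fish_transit_s=300.0,
                     max_concurrent_fish=5)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    return CohortSpec(n_teens=2, n_adults=3)


@pytest.fixture()
def rng():
    return child_rng(12345, 0)


@pytest.fixture(scope="session")
def default_records():
    """One full default cohort run, shared across analysis tests."""
    from fishcards import generate_cohort, run_experiment
    spec, game = CohortSpec(), GameConfig()
    policies = generate_cohort(spec, 42)
    with np.errstate(all="ignore"):
        records, events, infos = run_experiment(policies, game, 42,
                                                max_attempts=spec.max_attempts)
    return records, events, infos
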