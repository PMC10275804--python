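import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnvflow import GatingModel, SimulationConfig, sample_events
from cnvflow.simulate import sample_timecourse

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_control(config: SimulationConfig, copies: int, seed, generation: int = 0):
    """Pure control-strain sample with the given reporter copy number."""
    return sample_events(
        np.array([1.0]), config, seed, copy_numbers=(copies,),
        role=f"control_{min(copies, 2)}", generation=generation,
    )


def make_controls(config: SimulationConfig, seed_base: int = 100, generation: int = 0):
    return {
        f"control_{c}": make_control(config, c, seed_base + c, generation=generation)
        for c in (0, 1, 2)
    }


@pytest.fixture(scope="session")
def fast_config():
    """Default-noise config at a reduced event count for unit tests."""
    return SimulationConfig(events_per_sample=4000, generations=100, seed=11)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free observation model: exact proportionality checks."""
    return SimulationConfig(
        events_per_sample=2000, fluor_cv=0.0, autofluor_mu=0.0,
        doublet_frac=0.0, debris_frac=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def controls(fast_config):
    return make_controls(fast_config)


@pytest.fixture(scope="session")
def fitted_model(controls):
    return GatingModel().fit(controls)


@pytest.fixture(scope="session")
def wf_timecourse():
    """One seeded Wright–Fisher timecourse with samples and truth."""
    config = SimulationConfig(
        mode="wright_fisher", s=(0.0, 0.0, 0.12), generations=150,
        events_per_sample=4000, seed=21,
    )
    tables, trajectory = sample_timecourse(config)
    return config, tables, trajectory
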