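import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishnav import ArenaConfig, model_trajectories
from fishnav.arena import displaced_chamber_position

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def models_lateral(config):
    return model_trajectories(config, "lateral")


@pytest.fixture(scope="session")
def door_lateral(config):
    return displaced_chamber_position(config, "lateral")


def axial_vonmises(rng: np.random.Generator, mode_deg: float, kappa: float, n: int) -> np.ndarray:
    """Axial von Mises sample: draw on the doubled circle, halve back."""
    return (np.degrees(rng.vonmises(np.radians(2.0 * mode_deg), kappa, n)) % 360.0) / 2.0
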