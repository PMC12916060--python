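import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from visnet import (
    LayerSpec,
    LearningConfig,
    TrainingSchedule,
    build_gabor_bank,
    build_network,
    generate_synthetic_objects,
    train_network,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_RETINA = 32


def tiny_specs(**kw):
    """Four 8x8 Layers with 20 afferents each — fast enough for unit tests."""
    defaults = dict(sparseness=0.05, beta=10.0)
    defaults.update(kw)
    return [
        LayerSpec(8, 20, 3.0, **defaults),
        LayerSpec(8, 20, 3.0, **defaults),
        LayerSpec(8, 20, 3.0, **defaults),
        LayerSpec(8, 20, 3.0, **defaults),
    ]


@pytest.fixture(scope="session")
def tiny_bank():
    return build_gabor_bank(base_wavelength=16.0)


@pytest.fixture(scope="session")
def tiny_stimuli():
    return generate_synthetic_objects(3, 2, size=TINY_RETINA, seed=5)


@pytest.fixture()
def tiny_network():
    return build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=0)


@pytest.fixture(scope="session")
def tiny_trained(tiny_bank, tiny_stimuli):
    """One quickly trained tiny network shared by read-only tests."""
    net = build_network(tiny_specs(), input_size=TINY_RETINA, input_channels=32, seed=3)
    schedule = TrainingSchedule(epochs_per_layer=2, rng_seed=3)
    config = LearningConfig(rule="competitive_standard", learning_rate=0.5)
    train_network(net, tiny_stimuli, schedule, config, bank=tiny_bank)
    return net


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
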