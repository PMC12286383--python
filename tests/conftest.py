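import numpy as np
import pytest

from camsda.synthetic import (
    DomainShift,
    ScenarioSpec,
    generate_feature_scenario,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_scenario(seed: int = 7, samples_per_class: int = 60):
    """Small, fast 2-source / 4-class scenario for training smoke tests."""
    spec = ScenarioSpec(
        n_domains=2,
        n_classes=4,
        shared_classes=(0, 1),
        private_classes={0: (2,), 1: (3,)},
        samples_per_class=samples_per_class,
        feature_dim=8,
        domain_shift=(
            DomainShift(translation=(), scale=1.0),
            DomainShift(translation=(1.5,) + (0.0,) * 7, scale=1.0),
        ),
        noise_sd=0.4,
        prototype_scale=2.5,
        seed=seed,
    )
    return generate_feature_scenario(spec)


@pytest.fixture
def small_scenario():
    return tiny_scenario()
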