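import numpy as np
import pytest

from fedcpi.synth import CenterSpec, generate_center, generate_federation, split_train_test


@pytest.fixture(scope="session")
def tiny_center():
    """One small center with both classes and a visible class signal."""
    spec = CenterSpec(center_id="T", n_samples=40, prevalence=0.3,
                      image_size=16, effect_size=2.0, seed=7)
    return generate_center(spec)


@pytest.fixture(scope="session")
def tiny_federation():
    """Two small heterogeneous centers, split 50/50, for fast training runs."""
    specs = [
        CenterSpec("A", 36, 0.25, image_size=16, intensity_offset=-0.08,
                   gamma=0.9, effect_size=2.0),
        CenterSpec("B", 28, 0.25, image_size=16, intensity_offset=0.08,
                   gamma=1.2, blur_sigma=0.5, noise_sigma=0.05, effect_size=2.0),
    ]
    datasets = generate_federation(specs, master_seed=11)
    return [split_train_test(d, 0.5, 5 + i) for i, d in enumerate(datasets)]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
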