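import numpy as np
import pytest

from cardiosynth.networks import CriticNet, GeneratorNet, toy_config
from cardiosynth.phantom import (PhantomConfig, generate_samples,
                                 sample_phantom, toy_phantom_config)


@pytest.fixture(scope="session")
def toy_nets():
    """Freshly initialized small generator/critic pair (32^2 images)."""
    cfg = toy_config(32, 8)
    rng = np.random.default_rng(7)
    return GeneratorNet(cfg, rng), CriticNet(cfg, rng), cfg


@pytest.fixture(scope="session")
def phantom_batch32():
    """Eight noiseless 32^2 phantoms with ages spread over the range."""
    ages = np.linspace(46, 81, 8)
    samples = [sample_phantom(a, 27.0, "F", i, image_size=32, noise_sd=0.0)
               for i, a in enumerate(ages)]
    return np.stack([s.image for s in samples]), ages


@pytest.fixture(scope="session")
def noiseless_config():
    return PhantomConfig(jitter=False)


@pytest.fixture(scope="session")
def small_cohort_samples():
    """In-memory noisy training cohort at 32^2 (toy phantom law)."""
    return generate_samples(60, "uniform", "age", 11,
                            config=toy_phantom_config(32), image_size=32,
                            noise_sd=0.01)
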