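import numpy as np
import pytest

from nemaphene.synthetic import WormSpec, render_movie


@pytest.fixture(scope="session")
def bent_movie():
    """Noiseless 30-degree head-bend worm, 4 frames, translating."""
    spec = WormSpec(head_bend_angle=30.0, n_frames=4, noise_sd=0.0,
                    speed=100.0, seed=0)
    return spec, render_movie(spec)


@pytest.fixture(scope="session")
def noisy_movie():
    """Same worm with noise at 10% of contrast."""
    spec = WormSpec(head_bend_angle=30.0, n_frames=4, noise_sd=40.0,
                    speed=100.0, seed=1)
    return spec, render_movie(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
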