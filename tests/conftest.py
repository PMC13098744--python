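import numpy as np
import pytest

from momix.synthetic import PhantomParams, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """A very small sampled study for plumbing tests (fast to generate)."""
    params = PhantomParams(
        preset="random",
        n_patients=4,
        af_shape=(12, 12),
        hsi_shape=(10, 10),
        oct_shape=(30, 30, 60),
        mm_shape=(6, 6),
        seed=7,
    )
    return generate_study(params)
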