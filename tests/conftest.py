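import numpy as np
import pytest

import cinesync as cs


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small default-condition phantom (noise, jitter, breathing all on)."""
    params = cs.PhantomParams(n_slices=4, n_frames=200, seed=7)
    stack, truth = cs.generate_phantom(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Jitter-free, noise-free phantom for exact phase-recovery checks."""
    params = cs.PhantomParams(n_slices=3, n_frames=200, seed=3,
                              hr_jitter_frac=0.0, noise_sd=0.0)
    stack, truth = cs.generate_phantom(params)
    return params, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
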