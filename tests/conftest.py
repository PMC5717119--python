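import numpy as np
import pytest

from petprog.io import BinaryMask, PETVolume
from petprog.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two-valued phantom (background 1, tumour 8) with its ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """Moderate-noise heterogeneous phantom at TBR 8."""
    spec = PhantomSpec(noise_sd=0.4, heterogeneity_sd=0.8, seed=5)
    return generate_phantom(spec)


def random_roi(rng, max_shape=(5, 5, 5), n_bins=4):
    """A random small volume + non-empty random mask for oracle sweeps."""
    shape = tuple(int(rng.integers(2, s + 1)) for s in max_shape)
    suv = rng.uniform(0, n_bins * 0.5, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(int(rng.integers(0, s)) for s in shape)] = True
    return (
        PETVolume(suv, (2.0, 2.0, 2.0)),
        BinaryMask(mask.astype(np.uint8), (2.0, 2.0, 2.0)),
    )
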