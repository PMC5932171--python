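import numpy as np
import pytest

from ivote import GradientField, PhantomSpec, generate_phantom


def random_gradient_field(rng, shape, spacing=None, zero_fraction=0.1):
    """A random voter field: uniform magnitudes (a fraction zeroed) with
    uniformly distributed unit directions."""
    ndim = len(shape)
    spacing = (1.0,) * ndim if spacing is None else spacing
    mag = rng.uniform(0.1, 1.0, size=shape)
    mag[rng.random(shape) < zero_fraction] = 0.0
    vec = rng.normal(size=shape + (ndim,))
    norms = np.linalg.norm(vec, axis=-1, keepdims=True)
    vec = vec / norms
    vec[mag == 0] = 0.0
    return GradientField(magnitude=mag, vectors=vec, spacing=spacing)


@pytest.fixture(scope="session")
def single_ball_phantom():
    """Noiseless dark ball, radius 4 px, centered in a 32**3 volume."""
    spec = PhantomSpec(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0), n_cells=1,
                       radius_range_um=(4.0, 4.0), polarity="dark_cells",
                       noise_sigma=0.0, hollow_fraction=0.0, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def single_disk_phantom():
    """Noiseless dark disk, radius 5 px, in a 64x64 image."""
    spec = PhantomSpec(shape=(64, 64), spacing=(1.0, 1.0), n_cells=1,
                       radius_range_um=(5.0, 5.0), polarity="dark_cells",
                       noise_sigma=0.0, hollow_fraction=0.0, seed=5)
    return generate_phantom(spec)
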