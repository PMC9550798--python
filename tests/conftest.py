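import numpy as np
import pytest

from daunet import PhantomSpec, PreprocessConfig, generate_phantom, preprocess_pair


@pytest.fixture(scope="session")
def small_phantom():
    """A 16x32x32 phantom with neighbor organ, lobes and a vessel."""
    spec = PhantomSpec(
        grid_shape=(16, 32, 32), spacing_mm=(1.0, 1.0, 1.0),
        organ_center=(7.5, 15.5, 15.5), organ_radii=(5.0, 10.0, 10.0),
        n_lobes=2, neighbor_offset=(0, 0, 20), neighbor_radii=(4.0, 7.0, 7.0),
        vessel_count=1, noise_sd=10.0, seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_case(small_phantom):
    """The same phantom preprocessed to a network-ready (image, mask) pair."""
    vol, mask = small_phantom
    pv, pm, _ = preprocess_pair(vol, mask, PreprocessConfig(inplane_size=32), crop=False)
    return pv, pm


def random_mask_pair(rng, max_side=12):
    """A seeded pair of random, guaranteed-nonempty blobby masks."""
    shape = tuple(int(rng.integers(4, max_side + 1)) for _ in range(3))
    a = rng.random(shape) < 0.35
    b = rng.random(shape) < 0.35
    a[tuple(int(rng.integers(0, s)) for s in shape)] = True
    b[tuple(int(rng.integers(0, s)) for s in shape)] = True
    return a, b
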