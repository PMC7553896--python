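import numpy as np
import pytest

from radharm import PhantomSpec, VolumeWithMask, generate_phantom


def make_volume(values, mask=None, spacing=(1.0, 1.0, 1.0)):
    """Small helper: wrap an array (any dims <= 3) as a VolumeWithMask."""
    arr = np.asarray(values, dtype=float)
    while arr.ndim < 3:
        arr = arr[np.newaxis]
    if mask is None:
        mask = np.ones_like(arr, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        while mask.ndim < 3:
            mask = mask[np.newaxis]
    return VolumeWithMask(image=arr, mask=mask, spacing=spacing)


@pytest.fixture(scope="session")
def textured_phantom():
    """One CT-like textured ellipsoid phantom, fixed seed."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def flat_phantom():
    """Uniform-intensity phantom: every texture degeneracy path at once."""
    return generate_phantom(PhantomSpec(texture_sd=0.0, noise_sd=0.0, seed=0))
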