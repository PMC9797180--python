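from __future__ import annotations

import numpy as np
import pytest

from featuniq.core import ImageVolume, RoiMask
from featuniq.phantom import PhantomSpec, generate_phantom


def volume_from(arr, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Wrap a (possibly 2D) array as an ImageVolume; 2D becomes one slice."""
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2:
        a = a[None, :, :]
    return ImageVolume(a, spacing)


def full_mask(volume: ImageVolume) -> RoiMask:
    return RoiMask(np.ones(volume.shape, dtype=bool))


@pytest.fixture(scope="session")
def small_phantom():
    """A compact phantom reused across tests (16 slices, 64x64 in-plane)."""
    spec = PhantomSpec(shape=(16, 64, 64), nodule_diameter_mm=8.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
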