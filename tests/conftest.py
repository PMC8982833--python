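import numpy as np
import pytest

from thoraseg.volume_core import VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grid(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    return VolumeGrid(data=np.asarray(data), spacing=spacing, origin=origin, **kw)


@pytest.fixture
def sphere_mask():
    """Digital sphere of radius 5 voxels centred at (20, 20, 20) in a 41^3 grid."""
    n = 41
    idx = np.indices((n, n, n))
    d2 = sum((a - 20) ** 2 for a in idx)
    return grid((d2 <= 25).astype(np.uint8))


def random_mask(rng, shape=(16, 16, 16), p=0.1):
    return (rng.random(shape) < p).astype(np.uint8)
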