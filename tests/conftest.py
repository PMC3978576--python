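import numpy as np
import pytest

import enthesomorph as em


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask(rng):
    """A small random binary mask with both phases present."""
    bits = rng.random((40, 50)) < 0.45
    bits[0, 0], bits[1, 1] = True, False
    return em.BinaryMask(bits=bits, pixel_size_mm=0.05)


def stripe_mask(bone_px: int, marrow_px: int, shape=(60, 120),
                pixel_size_mm: float = 0.05) -> em.BinaryMask:
    """Vertical bone stripes of known width — the analytic texture."""
    cols = np.arange(shape[1]) % (bone_px + marrow_px) < bone_px
    return em.BinaryMask(bits=np.broadcast_to(cols, shape).copy(),
                         pixel_size_mm=pixel_size_mm)
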