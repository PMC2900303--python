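import numpy as np
import pytest

from furatrack import RatioStack


def make_ratio_stack(ratio: np.ndarray, dt_s: float = 15.0, valid=None) -> RatioStack:
    """Wrap a raw ratio array (all-valid by default) for detector tests."""
    ratio = np.asarray(ratio, dtype=np.float64)
    if valid is None:
        valid = np.ones_like(ratio, dtype=bool)
    return RatioStack(ratio=ratio, valid=valid, dt_s=dt_s)


def block_scene(
    shape=(6, 8, 8),
    block=(slice(2, 4), slice(2, 4), slice(2, 4)),
    baseline=1.0,
    amplitude=1.0,
) -> np.ndarray:
    """Noise-free baseline stack with one elevated space-time block."""
    ratio = np.full(shape, baseline)
    ratio[block] += amplitude
    return ratio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
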