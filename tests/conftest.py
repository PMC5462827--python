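import numpy as np
import pytest

from prmtopo.io_geometry import HUVolume, LungMask, PairedStudy


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def full_mask_64():
    return LungMask(np.ones((64, 64, 64), dtype=bool), (1.0, 1.0, 1.0))


def make_study(insp_hu: float, exp_hu: float, shape=(8, 8, 8),
               spacing=(1.0, 1.0, 1.0)) -> PairedStudy:
    """Uniform paired study with a full mask (helper for classifier tests)."""
    return PairedStudy(
        inspiration=HUVolume(np.full(shape, float(insp_hu)), spacing, "inspiration"),
        expiration=HUVolume(np.full(shape, float(exp_hu)), spacing, "expiration"),
        mask=LungMask(np.ones(shape, dtype=bool), spacing),
    )


def random_grids(seed: int, n: int, max_edge: int = 10):
    """Random binary grids of varied size/density, including near-degenerate."""
    gen = np.random.default_rng(seed)
    for i in range(n):
        shape = tuple(int(x) for x in gen.integers(1, max_edge + 1, size=3))
        if i % 7 == 0:
            p = gen.choice([0.02, 0.98])
        else:
            p = gen.uniform(0.05, 0.95)
        yield gen.random(shape) < p
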