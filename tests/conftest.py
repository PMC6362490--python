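import numpy as np
import pytest

from lfcdmap import BrainMask, FunctionalImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def identity_affine():
    return np.eye(4)


def make_image(data, affine=None, tr_sec=2.0):
    return FunctionalImage(
        data=np.asarray(data, dtype=float),
        affine=np.eye(4) if affine is None else affine,
        tr_sec=tr_sec,
    )


def make_mask(shape_or_data, affine=None):
    arr = np.asarray(shape_or_data)
    if arr.ndim == 1:  # a shape was passed
        arr = np.ones(tuple(int(s) for s in arr), dtype=bool)
    return BrainMask(data=arr.astype(bool), affine=np.eye(4) if affine is None else affine)


@pytest.fixture
def random_image(rng):
    """5x5x5 grid, 60 time points, independent standard-normal series."""
    return make_image(rng.standard_normal((5, 5, 5, 60)))


@pytest.fixture
def full_mask_5():
    return make_mask(np.ones((5, 5, 5), dtype=bool))
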