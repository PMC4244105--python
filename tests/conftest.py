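"""Shared fixtures: phantoms and their segmentations are expensive, so the
default phantom and its step-1 result are computed once per session."""

import numpy as np
import pytest

from breastdens import PhantomSpec, generate_phantom
from breastdens.bias_levelset import run_volume
from breastdens.phantom import breast_slice_range


@pytest.fixture(scope="session")
def truth1():
    """Default phantom, seed 1."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def seg1(truth1):
    """Step-1 segmentation of the default phantom over its breast slice range."""
    return run_volume(truth1.volume, breast_slice_range(truth1))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
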