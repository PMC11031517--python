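import numpy as np
import pytest

from panospec import PhantomParams, generate_head_phantom


@pytest.fixture(scope="session")
def default_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def default_phantom(default_params):
    """Full-size noise-free phantom (HU volume, ground-truth labels)."""
    return generate_head_phantom(default_params)


@pytest.fixture(scope="session")
def fast_params():
    """Coarse phantom (2 mm voxels) for tests that only need the structure."""
    return PhantomParams(shape=(80, 80, 60), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def fast_phantom(fast_params):
    return generate_head_phantom(fast_params)


def clip_segment_to_box(origin, direction, lo, hi):
    """Analytic slab clipping of a line against an axis-aligned box.

    Independent oracle for chord lengths: returns (t_enter, t_exit) or None.
    """
    tmin, tmax = -np.inf, np.inf
    for k in range(3):
        if direction[k] != 0.0:
            t1 = (lo[k] - origin[k]) / direction[k]
            t2 = (hi[k] - origin[k]) / direction[k]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
        elif not (lo[k] < origin[k] < hi[k]):
            return None
    if tmax <= tmin:
        return None
    return tmin, tmax


def chord_length(origin, direction, lo, hi):
    seg = clip_segment_to_box(np.asarray(origin, float), np.asarray(direction, float),
                              np.asarray(lo, float), np.asarray(hi, float))
    return 0.0 if seg is None else seg[1] - seg[0]
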