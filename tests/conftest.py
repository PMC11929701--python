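import numpy as np
import pytest

from usnav.phantom import VesselTree
from usnav.study import make_case, merge_config


@pytest.fixture(scope="session")
def default_cfg():
    return merge_config(None)


@pytest.fixture(scope="session")
def noisy_case(default_cfg):
    """One full phantom case at the default (noisy, deformed) study conditions."""
    return make_case(1, default_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced problem size for smoke/determinism tests."""
    return {
        "phantom": {"tree": {"depth": 2, "root_radius": 3.0,
                             "root_length": 25.0,
                             "branch_angle_range": [25.0, 45.0]},
                    "n_frames": 30, "pixel_spacing": 0.3,
                    "surface_density": 2.0},
    }


@pytest.fixture
def make_segment_tree():
    """Factory for hand-built trees of explicit segments."""

    def build(segments, parents=None):
        starts = np.array([s[0] for s in segments], dtype=float)
        ends = np.array([s[1] for s in segments], dtype=float)
        radii = np.array([s[2] for s in segments], dtype=float)
        if parents is None:
            parents = [-1] + [0] * (len(segments) - 1)
        return VesselTree(starts, ends, radii, np.asarray(parents))

    return build
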