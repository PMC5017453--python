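import numpy as np
import pytest

from defringe import (HoneycombSpec, SceneSpec, make_two_tissue_cube,
                      render_honeycomb)


@pytest.fixture(scope="session")
def flat_honeycomb():
    """Seeded 256 x 256 honeycomb rendering of a flat scene + ground truth."""
    scene = np.full((256, 256), 2000.0)
    rendered, truth = render_honeycomb(scene, HoneycombSpec(seed=1))
    return rendered, truth


@pytest.fixture(scope="session")
def small_cube():
    """Seeded 48 x 48 two-tissue cube with lesion and specular masks."""
    cube, lesion, sr = make_two_tissue_cube(SceneSpec(shape=(48, 48), seed=2))
    return cube, lesion, sr


@pytest.fixture
def rng():
    return np.random.default_rng(42)
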