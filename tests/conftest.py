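import numpy as np
import pytest

from greenview.synthetic import NetworkSpec, SceneSpec, make_scene, make_street_grid


@pytest.fixture(scope="session")
def small_scene():
    """A 160x100 scene with ~30% vegetation, clutter and jitter."""
    spec = SceneSpec(width=160, height=100, green_fraction=0.30, seed=42)
    image, mask = make_scene(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def grid_3x3():
    """Clean 3x3-node street grid, 200 m spacing (12 segments)."""
    return make_street_grid(NetworkSpec(grid_rows=3, grid_cols=3, spacing=200.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
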