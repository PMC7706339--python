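import numpy as np
import pytest

from microplots import SyntheticFieldSpec, generate_cameras, generate_field


@pytest.fixture(scope="session")
def small_spec():
    """A compact 3x4 field, tilted, with weeds: fast but non-trivial."""
    return SyntheticFieldSpec(n_columns=3, n_rows=4, rotation_deg=5.0,
                              weed_density=0.5, seed=1)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_field(small_spec)


@pytest.fixture(scope="session")
def camera_scene():
    """A scene with three nadir cameras and a nonzero SfM offset."""
    scene = generate_field(SyntheticFieldSpec(n_columns=3, n_rows=4,
                                              rotation_deg=5.0, seed=2))
    generate_cameras(scene, n_cameras=3, altitude_m=30.0)
    return scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
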