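import numpy as np
import pytest

import fluorosynth as fs


@pytest.fixture(scope="session")
def mask3():
    return fs.make_mask_triple(256, 256, n_lumen_branches=2, n_devices=1, seed=11)


@pytest.fixture(scope="session")
def background(mask3):
    return fs.render_background(mask3, seed=2)


@pytest.fixture(scope="session")
def blob_sprite():
    contour = fs.generate_spline_contour(
        fs.SplineShapeParams(n=10, centre=(0, 0), l_min=8, l_max=14, seed=4)
    )
    return fs.contour_to_sprite(contour, intensity=50, class_id=0)


@pytest.fixture(scope="session")
def short_sequence(mask3, background, blob_sprite):
    """60-frame constant-velocity sequence, no occlusion, fixed appearance."""
    traj = fs.TrajectorySpec(waypoints=((40, 128), (216, 128)), speed=2.0, n_frames=60)
    cfg = fs.RandomizationConfig(seed=9, target_height=20, height_jitter=0.0, rotation_range=0.0)
    return fs.make_sequence(background, mask3, blob_sprite, traj, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
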