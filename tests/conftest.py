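import numpy as np
import pytest

from clcfm3.synthetic import (
    build_plant_scene,
    build_turntable_rig,
    render_depth,
    render_mask,
)


@pytest.fixture(scope="session")
def scene():
    """Default parametric plant with disc, pillars and coded targets."""
    return build_plant_scene(seed=7)


@pytest.fixture(scope="session")
def rig24():
    """Single-row, 24-stop ring at 700 mm for a desk-scale plant."""
    return build_turntable_rig(
        n_rotations=24, step_deg=15.0, camera_rows=1, distance=700.0,
        target_height_range=(0.0, 400.0),
    )


@pytest.fixture(scope="session")
def rig8():
    return build_turntable_rig(
        n_rotations=8, step_deg=45.0, camera_rows=1, distance=700.0,
        target_height_range=(0.0, 400.0),
    )


@pytest.fixture(scope="session")
def masks24(scene, rig24):
    """Ground-truth plant silhouettes for every view of the 24-stop rig."""
    return {v.view_id: render_mask(scene, rig24.gt_view(v)) for v in rig24.views}


@pytest.fixture(scope="session")
def depths24(scene, rig24):
    return {v.view_id: render_depth(scene, rig24.gt_view(v)) for v in rig24.views}
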