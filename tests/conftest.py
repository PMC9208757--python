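import numpy as np
import pytest

from hcmotion import simgen
from hcmotion.segment import Contour


def circle_contour(radius_um: float = 10.0, n: int = 360, center=(0.0, 0.0),
                   frame: int = 0) -> Contour:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    verts = np.column_stack(
        [center[0] + radius_um * np.cos(theta), center[1] + radius_um * np.sin(theta)]
    )
    return Contour(frame=frame, vertices=verts)


def ellipse_contour(a_um: float, b_um: float, n: int = 360, angle: float = 0.0,
                    center=(0.0, 0.0), frame: int = 0) -> Contour:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x, y = a_um * np.cos(theta), b_um * np.sin(theta)
    ca, sa = np.cos(angle), np.sin(angle)
    verts = np.column_stack([center[0] + x * ca - y * sa, center[1] + x * sa + y * ca])
    return Contour(frame=frame, vertices=verts)


@pytest.fixture(scope="session")
def small_dataset():
    """Short default-condition movie with a mitotic-rounding frame."""
    cfg = simgen.SimConfig(n_frames=12, rounding_frame=6, seed=11)
    return simgen.build_dataset(cfg)


@pytest.fixture(scope="session")
def segmented_series(small_dataset):
    from hcmotion import segment as seg

    return seg.segment_series(
        small_dataset.stack, small_dataset.truth_cell_track.xy_um[0], channel="cell"
    )


@pytest.fixture(scope="session")
def kinematics_run():
    """Kinematics-only simulation (no rendering) with many protrusion tips."""
    cfg = simgen.SimConfig(
        n_frames=500, protrusion_rate=3.0, kappa_low=0.3, kappa_high=6.0, seed=5
    )
    track, tips, tip_angles, contours, centrosome = simgen.simulate_kinematics(cfg)
    return cfg, track, tips, tip_angles, contours, centrosome
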