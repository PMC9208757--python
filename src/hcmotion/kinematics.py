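"""Track kinematics: velocities, speed stratification, layer depth, centrosome offset.

Instantaneous velocity is the raw finite difference of consecutive centroid
positions (no smoothing by default, mirroring per-frame manual tracking).
Per-cell speed percentiles (25th/75th, linear interpolation between order
statistics) stratify frames into low/mid/high-speed classes — the reference
conditions for the protrusion-angle histograms.  Depth is the signed
distance from a named tissue layer (positive = basal); the centrosome
offset is the per-frame distance between centrosome and cell centre with a
front/back label relative to the movement direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hcmotion.imgio import PointTrack, TissueGeometry

log = logging.getLogger(__name__)

#: displacements below this are treated as stationary (direction undefined);
#: 0.04 µm is 0.1 px at the generator's default 0.4 µm/px calibration
DEFAULT_MIN_DISPLACEMENT_UM = 0.04


@dataclass
class VelocitySample:
    frame: int  # interval start
    direction: np.ndarray  # unit 2-vector (meaningful only when valid)
    speed_um_min: float
    valid: bool

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.speed_um_min < 0:
            raise ValueError("speed must be >= 0")
        if self.valid and abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("valid samples need a unit direction")


@dataclass
class SpeedThresholds:
    p25_um_min: float
    p75_um_min: float

    def __post_init__(self) -> None:
        if self.p25_um_min > self.p75_um_min:
            raise ValueError("p25 must be <= p75")


def velocities(
    track: PointTrack,
    interval_min: float,
    min_displacement_um: float = DEFAULT_MIN_DISPLACEMENT_UM,
) -> list[VelocitySample]:
    """Finite-difference velocity samples over consecutive frame pairs.

    Frame gaps split the track into uniform subsequences; no velocity
    spans a gap.  Samples whose displacement is below
    ``min_displacement_um`` are flagged invalid (direction undefined).
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    if len(track) < 2:
        raise ValueError("velocity needs at least 2 track samples")
    samples: list[VelocitySample] = []
    frames, xy = track.frames, track.xy_um
    for i in range(len(frames) - 1):
        dframes = frames[i + 1] - frames[i]
        if dframes != 1:
            continue  # gap: no sample spans it
        disp = xy[i + 1] - xy[i]
        norm = float(np.linalg.norm(disp))
        speed = norm / interval_min
        if norm < min_displacement_um:
            samples.append(
                VelocitySample(int(frames[i]), np.zeros(2), speed, valid=False)
            )
        else:
            samples.append(
                VelocitySample(int(frames[i]), disp / norm, speed, valid=True)
            )
    return samples


def speed_thresholds(
    samples: list[VelocitySample], q_low: float = 25.0, q_high: float = 75.0
) -> tuple[SpeedThresholds, dict[int, str]]:
    """Per-cell speed percentiles and a per-frame class map.

    Percentiles use linear interpolation between order statistics of the
    *valid* speeds.  A frame is ``low`` iff its speed is strictly below the
    low percentile, ``high`` iff strictly above the high one, else ``mid``.
    Invalid samples receive no class.
    """
    valid = [s for s in samples if s.valid]
    if len(valid) < 4:
        raise ValueError(
            f"speed stratification needs >= 4 valid samples, got {len(valid)}"
        )
    speeds = np.array([s.speed_um_min for s in valid])
    p25, p75 = np.percentile(speeds, [q_low, q_high])
    thresholds = SpeedThresholds(float(p25), float(p75))
    classes: dict[int, str] = {}
    for s in valid:
        if s.speed_um_min < p25:
            classes[s.frame] = "low"
        elif s.speed_um_min > p75:
            classes[s.frame] = "high"
        else:
            classes[s.frame] = "mid"
    return thresholds, classes


@dataclass
class DepthSample:
    frame: int
    depth_um: float  # signed; positive = basal


def _signed_distance_to_layer(
    xy: np.ndarray, layer_geom: np.ndarray, basal_sign: int
) -> float:
    geom = np.atleast_2d(np.asarray(layer_geom, dtype=float))
    if geom.size == 1:  # horizontal line at constant y
        return basal_sign * float(xy[1] - geom.ravel()[0])
    from shapely.geometry import LineString, Point

    line = LineString(geom)
    p = Point(xy)
    dist = float(line.distance(p))
    # sign from y relative to the layer at the projected position
    proj = line.interpolate(line.project(p))
    sign = 1.0 if xy[1] >= proj.y else -1.0
    return basal_sign * sign * dist


def depth_relative_to_layer(
    track: PointTrack,
    geometry: TissueGeometry,
    layer: str = "opl",
    max_gap: int = 2,
) -> tuple[list[DepthSample], dict[str, float]]:
    """Signed distance from a tissue layer per frame, positive basal.

    Frames where the layer is undefined within ``max_gap`` frames are
    dropped with a warning.  The summary reports the final-frame depth and
    the maximum basal depth reached over the track.
    """
    samples: list[DepthSample] = []
    for f, xy in zip(track.frames, track.xy_um):
        geom = geometry.layer_at(layer, int(f), max_gap=max_gap)
        if geom is None:
            log.warning("layer %r undefined near frame %d; sample dropped", layer, f)
            continue
        samples.append(
            DepthSample(int(f), _signed_distance_to_layer(xy, geom, geometry.basal_sign))
        )
    if not samples:
        raise ValueError(f"layer {layer!r} undefined for every track frame")
    depths = np.array([s.depth_um for s in samples])
    summary = {
        "final_depth_um": float(depths[-1]),
        "max_basal_depth_um": float(depths.max()),
    }
    return samples, summary


def centrosome_offset(
    cell_track: PointTrack,
    centrosome_track: PointTrack,
    interval_min: float | None = None,
    min_displacement_um: float = DEFAULT_MIN_DISPLACEMENT_UM,
) -> pd.DataFrame:
    """Per-frame centrosome-to-centre distance with a front/back label.

    The label is the sign of the centrosome offset projected onto the
    instantaneous movement direction: ``front`` (toward movement), ``back``,
    or ``undefined`` when the offset is ~0 or the frame has no valid
    velocity.
    """
    shared = np.intersect1d(cell_track.frames, centrosome_track.frames)
    if shared.size == 0:
        raise ValueError("cell and centrosome tracks share no frames")
    vel_by_frame: dict[int, VelocitySample] = {}
    if interval_min is not None and len(cell_track) >= 2:
        vel_by_frame = {
            v.frame: v
            for v in velocities(cell_track, interval_min, min_displacement_um)
        }
    rows = []
    for f in shared:
        c = cell_track.position_at(int(f))
        s = centrosome_track.position_at(int(f))
        offset = s - c
        dist = float(np.linalg.norm(offset))
        label = "undefined"
        v = vel_by_frame.get(int(f))
        if v is not None and v.valid and dist > 1e-9:
            proj = float(np.dot(offset, v.direction))
            if proj > 1e-9:
                label = "front"
            elif proj < -1e-9:
                label = "back"
        rows.append((int(f), dist, label))
    return pd.DataFrame(rows, columns=["frame", "distance_um", "position"])


def path_length(track: PointTrack) -> float:
    """Total path length (µm); always >= the net displacement."""
    return float(np.sum(np.linalg.norm(np.diff(track.xy_um, axis=0), axis=1)))


def net_displacement(track: PointTrack) -> float:
    return float(np.linalg.norm(track.xy_um[-1] - track.xy_um[0]))


def velocities_table(samples: list[VelocitySample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [s.frame for s in samples],
            "speed_um_min": [s.speed_um_min for s in samples],
            "dir_x": [s.direction[0] if s.valid else np.nan for s in samples],
            "dir_y": [s.direction[1] if s.valid else np.nan for s in samples],
            "valid": [s.valid for s in samples],
        }
    )
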