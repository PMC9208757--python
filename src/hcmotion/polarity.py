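"""Front-to-rear axial fluorescence profiling of a migrating cell.

Amoeboid migrators keep a contractile rear (uropod) enriched in stable
F-actin; imaged with a cortical marker this reads out as higher intensity
at the cell back.  The measurement is a line scan: a 3-px-wide line through
the cell centroid along the instantaneous movement direction, clipped to
the cell contour and oriented front (s=0) to back (s=1).  Per-frame
profiles are length-normalized and averaged across frames; the
rear-enrichment index is the ratio of the mean intensity over the back
third to the front third of the averaged profile (> 1 = rear-polarized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import LineString, Polygon

from hcmotion.segment import Contour

log = logging.getLogger(__name__)


@dataclass
class IntensityProfile:
    """Mean intensity vs normalized axial position (0 = front, 1 = back)."""

    s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None = None
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("positions must be strictly increasing")

    def to_frame_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"s": self.s, "mean_intensity": self.mean})
        if self.sd is not None:
            df["sd_intensity"] = self.sd
        df["n_frames"] = self.n_frames
        return df


def _central_max_projection(image: np.ndarray) -> np.ndarray:
    """Max projection of exactly the three central z planes of a z-stack."""
    if image.ndim == 2:
        return image
    if image.ndim != 3:
        raise ValueError("expected a 2D frame or a (Z, Y, X) z-stack")
    nz = image.shape[0]
    if nz < 3:
        return image.max(axis=0)
    mid = nz // 2
    return image[mid - 1 : mid + 2].max(axis=0)


def axial_profile(
    image: np.ndarray,
    contour: Contour,
    direction: np.ndarray,
    pixel_size_um: float,
    line_width_px: int = 3,
    n_positions: int = 50,
) -> IntensityProfile | None:
    """Line-scan profile along the movement axis for one frame.

    The sampling line is the contour-clipped segment through the centroid
    along ``direction``; intensity at each of ``n_positions`` equally
    spaced axial positions is the mean over ``line_width_px`` perpendicular
    pixel offsets (bilinear sampling).  Returns ``None`` (with a log
    message) when the direction is invalid or the clipped line is shorter
    than 4 px.
    """
    direction = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(direction))
    if not np.isfinite(norm) or norm < 1e-9:
        log.info("frame %d: invalid direction, profile skipped", contour.frame)
        return None
    d = direction / norm
    img = _central_max_projection(np.asarray(image, dtype=float))

    poly = Polygon(contour.vertices)
    c = contour.centroid
    reach = 2.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    probe = LineString([c - reach * d, c + reach * d])
    clipped = probe.intersection(poly)
    if clipped.is_empty:
        return None
    if clipped.geom_type == "MultiLineString":
        # take the piece containing (or nearest to) the centroid
        from shapely.geometry import Point

        clipped = min(clipped.geoms, key=lambda g: g.distance(Point(c)))
    (x0, y0), (x1, y1) = clipped.coords[0], clipped.coords[-1]
    ends = np.array([[x0, y0], [x1, y1]])
    # orient front -> back: the front end projects furthest along d
    if np.dot(ends[0] - c, d) < np.dot(ends[1] - c, d):
        ends = ends[::-1]
    front, back = ends
    length_px = np.linalg.norm(back - front) / pixel_size_um
    if length_px < 4.0:
        log.info("frame %d: clipped line shorter than 4 px, skipped", contour.frame)
        return None

    s = np.linspace(0.0, 1.0, n_positions)
    pts = front[None, :] + s[:, None] * (back - front)[None, :]
    normal = np.array([-d[1], d[0]])
    offsets = (np.arange(line_width_px) - (line_width_px - 1) / 2.0) * pixel_size_um
    vals = np.empty((n_positions, line_width_px))
    for j, off in enumerate(offsets):
        sample = (pts + off * normal) / pixel_size_um  # px (x, y)
        vals[:, j] = ndi.map_coordinates(
            img, [sample[:, 1], sample[:, 0]], order=1, mode="constant", cval=0.0
        )
    return IntensityProfile(s=s, mean=vals.mean(axis=1))


def rear_enrichment(
    profiles: list[IntensityProfile],
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
    mean_normalize: bool = False,
) -> tuple[IntensityProfile, float, tuple[float, float] | None]:
    """Average per-frame profiles and compute the rear-enrichment index.

    Index = (mean intensity over the back third, s >= 2/3) / (mean over the
    front third, s <= 1/3) of the frame-averaged profile; > 1 indicates
    rear polarization.  With ``n_boot > 0``, frames are bootstrap-resampled
    to a 95% confidence interval.  ``mean_normalize`` divides each
    per-frame profile by its own mean before averaging (cell brightness
    varies frame to frame).
    """
    profiles = [p for p in profiles if p is not None]
    if len(profiles) < 3:
        raise ValueError(f"rear_enrichment needs >= 3 profiles, got {len(profiles)}")
    s = profiles[0].s
    mat = np.vstack([np.interp(s, p.s, p.mean) for p in profiles])
    if mean_normalize:
        row_means = mat.mean(axis=1, keepdims=True)
        row_means[row_means == 0] = 1.0
        mat = mat / row_means

    def index_of(rows: np.ndarray) -> float:
        prof = rows.mean(axis=0)
        front = prof[s <= 1.0 / 3.0].mean()
        back = prof[s >= 2.0 / 3.0].mean()
        return float(back / front) if front > 0 else np.inf

    avg = IntensityProfile(
        s=s, mean=mat.mean(axis=0), sd=mat.std(axis=0, ddof=0), n_frames=len(profiles)
    )
    index = index_of(mat)
    ci = None
    if n_boot > 0:
        rng = rng or np.random.default_rng(0)
        reps = np.array(
            [
                index_of(mat[rng.integers(0, len(mat), len(mat))])
                for _ in range(n_boot)
            ]
        )
        ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return avg, index, ci


def profiles_for_movie(
    channel_frames: np.ndarray,
    contours: dict[int, Contour],
    directions: dict[int, np.ndarray],
    pixel_size_um: float,
    line_width_px: int = 3,
    n_positions: int = 50,
) -> tuple[list[IntensityProfile], int]:
    """Per-frame profiles over a movie; returns (profiles, n_skipped)."""
    out: list[IntensityProfile] = []
    skipped = 0
    for f, contour in sorted(contours.items()):
        d = directions.get(f)
        if d is None:
            skipped += 1
            continue
        prof = axial_profile(
            channel_frames[f], contour, d, pixel_size_um, line_width_px, n_positions
        )
        if prof is None:
            skipped += 1
        else:
            out.append(prof)
    return out, skipped
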