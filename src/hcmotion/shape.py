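"""Per-frame contour shape descriptors and mitotic-rounding detection.

Descriptors follow the conventions of the Icy-style morphodynamic readout
for 2D projections of migrating cells:

* **perimeter** (µm): polygon arc length of the contour as segmented.
* **area** (µm²): shoelace area.
* **sphericity** (%): realized as 2D circularity, ``100 · 4π·A / P²`` —
  100% for a perfect circle, lower for any other simple closed shape
  (isoperimetric inequality).  The analysis runs on 2D projections, so a 2D
  roundness measure is the appropriate realization; this choice is
  documented rather than assumed to match any particular tool's internals.
* **elongation ratio** (a.u., ≥ 1): ratio of the first to second diameters
  of the second-central-moment equivalent ellipse; 1 for a round object.

During interphase migration an amoeboid cell is elongated and deforms
constantly; on entering mitosis it rounds up, so the rounding frame is the
joint extremum — maximal sphericity and minimal elongation (and minimal
perimeter at fixed area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hcmotion.segment import Contour, ContourSeries, polygon_centroid

__all__ = [
    "ShapeRecord",
    "shape_descriptors",
    "shape_series_stats",
    "polygon_second_moments",
]


@dataclass
class ShapeRecord:
    frame: int
    perimeter_um: float
    area_um2: float
    sphericity_pct: float
    elongation_ratio: float

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("degenerate polygon: area must be > 0")
        if not 0 < self.sphericity_pct <= 100.0 + 1e-9:
            raise ValueError(f"sphericity out of (0, 100]: {self.sphericity_pct}")
        if self.elongation_ratio < 1.0 - 1e-9:
            raise ValueError(f"elongation ratio must be >= 1: {self.elongation_ratio}")


def polygon_second_moments(vertices: np.ndarray) -> np.ndarray:
    """Normalized second central moments (covariance) of a polygon's interior.

    Returns the 2×2 matrix ``[[µxx, µxy], [µxy, µyy]]`` with
    ``µxx = ∫(x−cx)² dA / A`` etc., computed by the exact Green's-theorem
    sums over edges (no rasterization).
    """
    v = np.asarray(vertices, dtype=float)
    c = polygon_centroid(v)
    x, y = v[:, 0] - c[0], v[:, 1] - c[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a <= 0:
        raise ValueError("polygon must be counter-clockwise with positive area")
    sxx = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0
    syy = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0
    sxy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    return np.array([[sxx, sxy], [sxy, syy]]) / a


def shape_descriptors(contour: Contour) -> ShapeRecord:
    """Perimeter, area, sphericity and elongation ratio of one contour.

    Elongation is the square-rooted eigenvalue ratio of the second-moment
    matrix, i.e. the major/minor diameter ratio of the equivalent ellipse;
    for a moment-degenerate shape (perfect circle) the eigenvalues coincide
    and the ratio is exactly 1.
    """
    v = contour.vertices
    closed = np.vstack([v, v[:1]])
    perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    area = contour.area
    if area <= 0:
        raise ValueError("degenerate polygon: area <= 0")
    sphericity = 100.0 * 4.0 * np.pi * area / perimeter**2
    mom = polygon_second_moments(v)
    lam = np.linalg.eigvalsh(mom)  # ascending, both > 0 for a 2D region
    lam = np.clip(lam, 1e-300, None)
    elongation = float(np.sqrt(lam[1] / lam[0]))
    return ShapeRecord(
        frame=contour.frame,
        perimeter_um=perimeter,
        area_um2=area,
        sphericity_pct=min(float(sphericity), 100.0),
        elongation_ratio=max(elongation, 1.0),
    )


def shape_series_stats(
    series: ContourSeries,
    rounding_threshold_pct: float = 95.0,
    window: int = 5,
) -> tuple[pd.DataFrame, int | None, pd.DataFrame]:
    """Per-frame descriptors, detected rounding frame, and a summary table.

    The rounding (mitosis) event is the frame jointly attaining maximal
    sphericity and minimal elongation: the sphericity argmax is reported
    only if the elongation argmin falls within ``window`` frames of it and
    sphericity there reaches ``rounding_threshold_pct``.  A persistently
    elongated cell therefore reports no event.

    Returns ``(records, rounding_frame_or_None, summary)``.
    """
    ok = series.ok_entries
    if len(ok) < 3:
        raise ValueError(
            f"shape series needs >= 3 ok frames, got {len(ok)} "
            f"(flags: {[e.flag for e in series.entries]})"
        )
    records = [shape_descriptors(e.contour) for e in ok]
    df = pd.DataFrame(
        {
            "frame": [r.frame for r in records],
            "perimeter_um": [r.perimeter_um for r in records],
            "area_um2": [r.area_um2 for r in records],
            "sphericity_pct": [r.sphericity_pct for r in records],
            "elongation_ratio": [r.elongation_ratio for r in records],
        }
    )

    i_sph = int(df["sphericity_pct"].idxmax())
    i_elo = int(df["elongation_ratio"].idxmin())
    rounding_frame: int | None = None
    if (
        df.loc[i_sph, "sphericity_pct"] >= rounding_threshold_pct
        and abs(df.loc[i_sph, "frame"] - df.loc[i_elo, "frame"]) <= window
    ):
        rounding_frame = int(df.loc[i_sph, "frame"])

    summary = df.drop(columns="frame").agg(["min", "max", "mean"]).T
    summary.index.name = "descriptor"
    summary = summary.reset_index()
    return df, rounding_frame, summary
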