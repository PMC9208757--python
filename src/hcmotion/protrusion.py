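"""Protrusion orientation statistics conditioned on migration speed.

For every tracked protrusion tip, the statistic is the unsigned angle
between the unit vector of instantaneous cell movement and the unit vector
from the cell centroid to the tip: 0° means the protrusion points exactly
along the movement direction (cell front), 180° exactly opposite (cell
back).  Samples are binned into angular histograms for three conditions —
all frames, low-speed frames (below the cell's 25th speed percentile) and
high-speed frames (above the 75th) — and each histogram is normalized so
its frequencies sum to 1.  Because several protrusions can coexist in one
frame, both the sample count and the frame count per condition are
reported, so a frames-denominator normalization can be recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hcmotion.imgio import PointTrack
from hcmotion.kinematics import SpeedThresholds, VelocitySample

log = logging.getLogger(__name__)

CONDITIONS = ("all", "low", "high")


def protrusion_angle(direction: np.ndarray, centroid: np.ndarray, tip: np.ndarray) -> float:
    """Unsigned angle (degrees, [0, 180]) between movement direction and
    the centroid-to-tip vector."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    radial = np.asarray(tip, dtype=float) - np.asarray(centroid, dtype=float)
    norm = float(np.linalg.norm(radial))
    if norm == 0.0:
        raise ValueError("undefined angle: tip coincides with centroid")
    cosang = float(np.dot(direction, radial / norm))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class AngleSample:
    frame: int
    angle_deg: float
    speed_class: str
    protrusion_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError(f"angle out of [0, 180]: {self.angle_deg}")


@dataclass
class AngleHistogram:
    """Normalized angular frequency per bin under one speed condition."""

    bin_edges: np.ndarray
    normalized_frequency: np.ndarray
    counts: np.ndarray
    condition: str
    n_samples: int
    n_frames_condition: int
    empty: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.normalized_frequency = np.asarray(self.normalized_frequency, dtype=float)
        if self.n_samples > 0:
            total = float(self.normalized_frequency.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies must sum to 1, got {total}")
        if np.any(self.normalized_frequency < 0):
            raise ValueError("frequencies must be >= 0")

    @property
    def modal_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.normalized_frequency))
        return (float(self.bin_edges[i]), float(self.bin_edges[i + 1]))

    def to_frame_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "bin_lo_deg": self.bin_edges[:-1],
                "bin_hi_deg": self.bin_edges[1:],
                "frequency": self.normalized_frequency,
                "count": self.counts,
                "n_samples": self.n_samples,
                "n_frames_condition": self.n_frames_condition,
            }
        )


@dataclass
class AngleAnalysis:
    samples: list[AngleSample]
    histograms: dict[str, AngleHistogram]
    n_dropped_invalid_velocity: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    def samples_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [s.frame for s in self.samples],
                "protrusion_id": [s.protrusion_id for s in self.samples],
                "angle_deg": [s.angle_deg for s in self.samples],
                "speed_class": [s.speed_class for s in self.samples],
            }
        )

    def histograms_table(self) -> pd.DataFrame:
        return pd.concat(
            [self.histograms[c].to_frame_table() for c in CONDITIONS],
            ignore_index=True,
        )


def collect_angle_samples(
    cell_track: PointTrack,
    tip_tracks: list[PointTrack],
    velocity_samples: list[VelocitySample],
    speed_classes: dict[int, str],
) -> tuple[list[AngleSample], int, list[str]]:
    """One AngleSample per (tip, frame) at frames with a valid velocity.

    Tips at frames without a valid velocity (stationary cell: direction
    undefined) are dropped and counted, never binned.
    """
    vel_by_frame = {v.frame: v for v in velocity_samples if v.valid}
    samples: list[AngleSample] = []
    dropped = 0
    dropped_ids: list[str] = []
    for tip in tip_tracks:
        for f, xy in zip(tip.frames, tip.xy_um):
            v = vel_by_frame.get(int(f))
            centroid = cell_track.position_at(int(f))
            if v is None or centroid is None:
                dropped += 1
                dropped_ids.append(tip.track_id)
                continue
            samples.append(
                AngleSample(
                    frame=int(f),
                    angle_deg=protrusion_angle(v.direction, centroid, xy),
                    speed_class=speed_classes.get(int(f), "mid"),
                    protrusion_id=tip.track_id,
                )
            )
    if dropped:
        log.info("dropped %d tip samples at frames without valid velocity", dropped)
    return samples, dropped, dropped_ids


def _histogram(
    samples: list[AngleSample], condition: str, bin_edges: np.ndarray,
    n_frames_condition: int,
) -> AngleHistogram:
    angles = np.array([s.angle_deg for s in samples], dtype=float)
    counts, _ = np.histogram(angles, bins=bin_edges)  # last bin closed at 180
    n = int(counts.sum())
    if n == 0:
        return AngleHistogram(
            bin_edges=bin_edges,
            normalized_frequency=np.zeros(len(bin_edges) - 1),
            counts=counts,
            condition=condition,
            n_samples=0,
            n_frames_condition=n_frames_condition,
            empty=True,
        )
    return AngleHistogram(
        bin_edges=bin_edges,
        normalized_frequency=counts / n,
        counts=counts,
        condition=condition,
        n_samples=n,
        n_frames_condition=n_frames_condition,
    )


def angle_histograms(
    cell_track: PointTrack,
    tip_tracks: list[PointTrack],
    velocity_samples: list[VelocitySample],
    thresholds: SpeedThresholds,
    speed_classes: dict[int, str],
    bin_width_deg: float = 20.0,
) -> AngleAnalysis:
    """Speed-conditioned angular histograms (conditions: all, low, high).

    Bins are half-open ``[a, b)`` over [0°, 180°] with the last bin closed;
    the default 20° width gives 9 bins.  An empty condition (e.g. no
    high-speed frames) yields a flagged all-zero histogram, never a
    fabricated distribution.
    """
    if bin_width_deg <= 0 or 180.0 % bin_width_deg > 1e-9:
        raise ValueError("bin_width_deg must evenly divide 180")
    edges = np.arange(0.0, 180.0 + bin_width_deg / 2, bin_width_deg)
    samples, dropped, dropped_ids = collect_angle_samples(
        cell_track, tip_tracks, velocity_samples, speed_classes
    )
    frames_per_class: dict[str, int] = {c: 0 for c in CONDITIONS}
    for f, cls in speed_classes.items():
        if cls in ("low", "high"):
            frames_per_class[cls] += 1
        frames_per_class["all"] += 1
    hists = {
        "all": _histogram(samples, "all", edges, frames_per_class["all"]),
        "low": _histogram(
            [s for s in samples if s.speed_class == "low"], "low", edges,
            frames_per_class["low"],
        ),
        "high": _histogram(
            [s for s in samples if s.speed_class == "high"], "high", edges,
            frames_per_class["high"],
        ),
    }
    return AngleAnalysis(
        samples=samples,
        histograms=hists,
        n_dropped_invalid_velocity=dropped,
        dropped_ids=dropped_ids,
    )


def histogram_entropy(hist: AngleHistogram) -> float:
    """Shannon entropy (nats) of the normalized bin frequencies; higher =
    flatter (less front-biased) angular distribution."""
    p = hist.normalized_frequency[hist.normalized_frequency > 0]
    return float(-(p * np.log(p)).sum())


def plot_rose(hist: AngleHistogram, path: str) -> None:
    """Polar rose plot of one histogram (display mirrors the unsigned
    angles across the movement axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    centers = np.deg2rad((hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0)
    width = np.deg2rad(np.diff(hist.bin_edges))
    for sign in (1, -1):  # mirror for display only
        ax.bar(sign * centers, hist.normalized_frequency, width=width, alpha=0.6,
               color="tab:blue")
    ax.set_title(f"{hist.condition} (n={hist.n_samples})")
    fig.savefig(path, dpi=120)
    plt.close(fig)
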