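"""Automated XY drift estimation and correction for time-lapse stacks.

Long light-sheet movies (tens of hours) accumulate slow stage/sample drift.
Drift is estimated between *consecutive* frames by subpixel
cross-correlation and composed into a cumulative series relative to a
reference frame — pairwise estimation is robust to the gradual content
change of a developing tissue, where all-to-reference correlation decays.
Only XY translation is handled; rotation/scale are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from hcmotion.imgio import ImageStack, PointTrack

log = logging.getLogger(__name__)


@dataclass
class DriftSeries:
    """Cumulative content translation (µm) per frame, zero at the reference."""

    dx_um: np.ndarray
    dy_um: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.dx_um = np.asarray(self.dx_um, dtype=float)
        self.dy_um = np.asarray(self.dy_um, dtype=float)
        if self.dx_um.shape != self.dy_um.shape:
            raise ValueError("dx and dy series must align")
        r = self.reference_frame
        if not (0 <= r < len(self.dx_um)):
            raise ValueError("reference frame outside series")
        if abs(self.dx_um[r]) > 1e-9 or abs(self.dy_um[r]) > 1e-9:
            raise ValueError("translation at the reference frame must be (0, 0)")

    def __len__(self) -> int:
        return len(self.dx_um)

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.dx_um, self.dy_um])

    def to_frame_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "dx_um": self.dx_um, "dy_um": self.dy_um}
        )


def estimate_drift(
    stack: ImageStack,
    channel: str | int = 0,
    reference_frame: int = 0,
    upsample_factor: int = 20,
) -> DriftSeries:
    """Estimate per-frame cumulative XY translation of the image content.

    Consecutive frame pairs are registered by cross-correlation with
    subpixel (upsampled-DFT) refinement and the increments are summed, then
    re-referenced so the series is zero at ``reference_frame``.  On content
    that is a pure translation of the reference the recovered shift is
    within 0.5 px.  A zero-variance (flat) frame inherits the previous
    frame's cumulative drift with a warning.
    """
    if stack.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    imgs = stack.channel(channel)
    if imgs.ndim == 4:
        imgs = imgs.max(axis=1)
    T = stack.n_frames
    inc = np.zeros((T, 2))  # (dx, dy) px increments
    for t in range(1, T):
        prev, cur = imgs[t - 1], imgs[t]
        if float(cur.std()) == 0.0 or float(prev.std()) == 0.0:
            log.warning("frame %d flat (zero variance); inheriting previous drift", t)
            inc[t] = 0.0
            continue
        # returned shift moves `cur` onto `prev`; content drift is its negative
        shift, _err, _phase = phase_cross_correlation(
            prev, cur, upsample_factor=upsample_factor, normalization=None
        )
        inc[t] = np.array([-shift[1], -shift[0]])  # (row, col) -> (dx, dy)
    cum = np.cumsum(inc, axis=0)
    cum = cum - cum[reference_frame]
    px = stack.pixel_size_um
    return DriftSeries(
        dx_um=cum[:, 0] * px, dy_um=cum[:, 1] * px, reference_frame=reference_frame
    )


def apply_drift_correction(
    target: ImageStack | PointTrack | list[PointTrack],
    drift: DriftSeries,
) -> ImageStack | PointTrack | list[PointTrack]:
    """Undo the estimated drift.

    Stacks are resampled by the inverse translation (linear interpolation,
    constant-zero padding); point tracks are shifted exactly, with no
    interpolation, so correcting a track with the drift that corrupted it
    restores the original to numerical precision.
    """
    if isinstance(target, ImageStack):
        if len(drift) != target.n_frames:
            raise ValueError(
                f"drift covers {len(drift)} frames, stack has {target.n_frames}"
            )
        px = target.pixel_size_um
        out = np.empty_like(target.pixels)
        for t in range(target.n_frames):
            sx, sy = drift.dx_um[t] / px, drift.dy_um[t] / px
            for c in range(target.pixels.shape[-1]):
                plane = target.pixels[t, ..., c]
                # content sits at +drift; move it back by -drift
                if plane.ndim == 3:  # z-mode
                    shift_vec = (0.0, -sy, -sx)
                else:
                    shift_vec = (-sy, -sx)
                out[t, ..., c] = ndi.shift(
                    plane, shift_vec, order=1, mode="constant", cval=0.0
                )
        return ImageStack(
            pixels=np.clip(out, 0.0, None),
            pixel_size_um=target.pixel_size_um,
            frame_interval_min=target.frame_interval_min,
            channel_names=target.channel_names,
        )
    if isinstance(target, PointTrack):
        if len(target) and (target.frames.min() < 0 or target.frames.max() >= len(drift)):
            raise ValueError("track has frames outside the drift series domain")
        shift = drift.as_array()[target.frames]
        return PointTrack(
            track_id=target.track_id,
            frames=target.frames.copy(),
            xy_um=target.xy_um - shift,
            role=target.role,
        )
    if isinstance(target, list):
        return [apply_drift_correction(t, drift) for t in target]
    raise TypeError(f"cannot drift-correct {type(target).__name__}")


def frame_alignment_error(stack: ImageStack, channel: str | int = 0,
                          reference_frame: int = 0) -> np.ndarray:
    """Mean absolute difference of each frame against the reference frame
    (diagnostic: drift correction should reduce it on rigidly drifted data)."""
    imgs = stack.channel(channel)
    if imgs.ndim == 4:
        imgs = imgs.max(axis=1)
    ref = imgs[reference_frame]
    return np.array([float(np.abs(f - ref).mean()) for f in imgs])
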