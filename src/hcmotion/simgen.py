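"""Synthetic time-lapse generator with full ground truth.

Emulates the imaging data the analysis chain was designed for: a single
deformable cell migrating amoeboid-fashion through a crowded neuroepithelium
(correlated random walk, frequent direction changes), imaged every 1–5 min
at ~0.2–0.5 µm/px.  Three channels are rendered:

* **cell** — the filled cell-body contour (membrane/cytoplasmic label);
* **polarity** — a cortical band whose intensity rises linearly from the
  cell front to the cell back (a stable-F-actin / uropod-style marker);
* **nuclei** — static neighbor nuclei providing crowded visual context.

The protrusion model is the key statistical structure: tip directions are
offset from the instantaneous movement direction by a symmetric unimodal
(von Mises) deviation whose concentration interpolates from ``kappa_low``
below the cell's 25th speed percentile to ``kappa_high`` above the 75th,
i.e. protrusions are more front-biased the faster the cell moves.  Angles
are folded to the unsigned [0°, 180°] convention.

Everything is driven by a single integer seed: identical (config, seed)
pairs give bit-identical stacks and truth tables.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage import draw as skdraw

from hcmotion.imgio import ImageStack, PointTrack, TissueGeometry, write_stack
from hcmotion.segment import Contour

__all__ = ["SimConfig", "SyntheticDataset", "simulate_kinematics", "render_frames",
           "generate_dataset", "load_dataset"]

CHANNELS = ("cell", "polarity", "nuclei")


class InvalidConfig(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic migration movie.

    Defaults emulate the protrusion-imaging regime: 1 min frame interval,
    per-cell speeds drawn so that the 25th/75th percentiles land near
    0.4/0.9 µm/min, a ~6 µm cell radius at 0.4 µm/px.
    """

    field_size_px: tuple[int, int] = (200, 200)  # (width, height)
    pixel_size_um: float = 0.4
    frame_interval_min: float = 1.0
    n_frames: int = 40
    path_persistence: float = 0.7
    mean_speed_um_min: float = 0.7
    protrusion_rate: float = 2.0
    kappa_low: float = 0.5
    kappa_high: float = 4.0
    rear_polarity_strength: float = 3.0
    rounding_frame: int | None = None
    drift_per_frame_px: tuple[float, float] = (0.0, 0.0)
    neighbor_density: float = 3.0  # nuclei per 100x100 px
    noise_sd: float = 4.0
    seed: int = 0
    # cell geometry
    cell_radius_um: float = 6.0
    elongation: float = 2.0
    deform_amp: float = 0.06
    n_contour_vertices: int = 100
    centrosome_offset_um: float = 1.5
    n_z: int = 1  # set 3 for the small z-stack mode
    cell_intensity: float = 100.0
    nucleus_intensity: float = 80.0
    cortex_width_px: float = 3.0  # must exceed the 3-px line-scan width

    def validate(self) -> None:
        w, h = self.field_size_px
        if w < 8 or h < 8:
            raise InvalidConfig("field_size_px too small")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise InvalidConfig("physical scales must be strictly positive")
        if self.n_frames < 2:
            raise InvalidConfig("n_frames must be >= 2")
        if not 0 <= self.path_persistence < 1:
            raise InvalidConfig("path_persistence must be in [0, 1)")
        if self.mean_speed_um_min < 0 or self.protrusion_rate < 0:
            raise InvalidConfig("rates and speeds must be >= 0")
        if self.kappa_low < 0 or self.kappa_high < 0:
            raise InvalidConfig("kappa parameters must be >= 0")
        if self.kappa_low > self.kappa_high:
            raise InvalidConfig("kappa_low must be <= kappa_high (stronger front bias at high speed)")
        if self.rear_polarity_strength < 1:
            raise InvalidConfig("rear_polarity_strength must be >= 1")
        if self.rounding_frame is not None and not 0 <= self.rounding_frame < self.n_frames:
            raise InvalidConfig("rounding_frame outside movie")
        if self.cell_radius_um <= 0 or self.elongation < 1:
            raise InvalidConfig("cell geometry invalid")
        if self.n_z not in (1, 3):
            raise InvalidConfig("n_z must be 1 or 3")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_size_px"] = list(self.field_size_px)
        d["drift_per_frame_px"] = list(self.drift_per_frame_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "field_size_px" in d:
            d["field_size_px"] = tuple(d["field_size_px"])
        if "drift_per_frame_px" in d:
            d["drift_per_frame_px"] = tuple(d["drift_per_frame_px"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Rendered stack plus every ground-truth table the analyses consume."""

    config: SimConfig
    stack: ImageStack | None
    truth_cell_track: PointTrack
    truth_contours: list[Contour]
    truth_protrusions: list[PointTrack]
    truth_tip_angles_deg: dict[str, float]
    truth_centrosome_track: PointTrack
    truth_drift_px: np.ndarray  # (T, 2) cumulative (dx, dy)
    truth_geometry: TissueGeometry
    frame_flags: list[str] = field(default_factory=list)

    def check_invariants(self) -> None:
        T = self.config.n_frames
        assert list(self.truth_cell_track.frames) == list(range(T))
        assert len(self.truth_contours) == T
        assert self.truth_drift_px.shape == (T, 2)
        tol = 0.5 * self.config.pixel_size_um
        for f, c in enumerate(self.truth_contours):
            d = np.linalg.norm(c.centroid - self.truth_cell_track.xy_um[f])
            assert d <= tol, f"frame {f}: contour centroid off track by {d:.3f} µm"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _sample_offsets(kappa: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Signed angular offsets (radians) from a von Mises centred at 0."""
    if kappa < 1e-9:
        return rng.uniform(-np.pi, np.pi, size)
    return rng.vonmises(0.0, kappa, size)


def _cell_contour(
    center_um: np.ndarray,
    axis_angle: float,
    radius_um: float,
    elongation: float,
    deform: np.ndarray | None,
    n_vertices: int,
) -> np.ndarray:
    """Smoothed star-convex polygon: area-preserving ellipse plus low-order
    Fourier radius perturbation (harmonics >= 2 leave the centroid fixed)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a = radius_um * np.sqrt(elongation)
    b = radius_um / np.sqrt(elongation)
    x = a * np.cos(theta)
    y = b * np.sin(theta)
    if deform is not None:
        r_scale = np.ones_like(theta)
        for k, (amp, phase) in enumerate(deform, start=2):
            r_scale += amp * np.cos(k * theta + phase)
        x *= r_scale
        y *= r_scale
    ca, sa = np.cos(axis_angle), np.sin(axis_angle)
    rot = np.column_stack([x * ca - y * sa, x * sa + y * ca])
    return rot + center_um


def simulate_kinematics(
    config: SimConfig,
) -> tuple[PointTrack, list[PointTrack], dict[str, float], list[Contour], PointTrack]:
    """Simulate the migrating cell: track, protrusion tips, contours, centrosome.

    The centroid follows a correlated random walk (direction blended with a
    fresh random unit vector by ``path_persistence``); per-step speeds are
    gamma-distributed (shape 2) around ``mean_speed_um_min`` so the realized
    speed distribution has genuine low/high-speed tails to stratify.
    Protrusion counts per frame are Poisson; tip offsets from the movement
    direction are von Mises with speed-interpolated concentration.  The
    centrosome alternates between a fore and an aft placement along the
    movement axis.

    Returns ``(cell_track, tip_tracks, tip_true_angles, contours,
    centrosome_track)``; all positions in µm.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_path, rng_tips, rng_shape, _rng_render = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    T = config.n_frames
    dt = config.frame_interval_min
    w_um = config.field_size_px[0] * config.pixel_size_um
    h_um = config.field_size_px[1] * config.pixel_size_um

    # --- centroid path: correlated random walk --------------------------
    pos = np.zeros((T, 2))
    pos[0] = np.array([w_um / 2.0, h_um * 0.35])  # start apical-of-centre
    if config.mean_speed_um_min > 0:
        speeds = rng_path.gamma(2.0, config.mean_speed_um_min / 2.0, T - 1)
    else:
        speeds = np.zeros(T - 1)
    ang0 = rng_path.uniform(0.0, 2.0 * np.pi)
    d = np.array([np.cos(ang0), np.sin(ang0)])
    directions = np.zeros((T - 1, 2))
    p = config.path_persistence
    for t in range(T - 1):
        ang = rng_path.uniform(0.0, 2.0 * np.pi)
        fresh = np.array([np.cos(ang), np.sin(ang)])
        d = _unit(p * d + (1.0 - p) * fresh)
        directions[t] = d
        step = speeds[t] * dt * d
        nxt = pos[t] + step
        # soft reflection keeps the cell inside the field margin
        margin = config.cell_radius_um * 2.0
        for k, lim in enumerate((w_um, h_um)):
            if nxt[k] < margin:
                nxt[k] = 2.0 * margin - nxt[k]
                d[k] = abs(d[k])
            elif nxt[k] > lim - margin:
                nxt[k] = 2.0 * (lim - margin) - nxt[k]
                d[k] = -abs(d[k])
        pos[t + 1] = nxt
    realized = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt

    track = PointTrack("cell", np.arange(T), pos, role="cell_centroid")

    # --- per-frame movement axis (last frame inherits the previous one) --
    axis_dirs = np.zeros((T, 2))
    last = np.array([1.0, 0.0])
    for t in range(T):
        if t < T - 1 and realized[t] > 0:
            last = _unit(pos[t + 1] - pos[t])
        axis_dirs[t] = last

    # --- contours ---------------------------------------------------------
    contours = []
    for t in range(T):
        if config.rounding_frame is not None and t == config.rounding_frame:
            verts = _cell_contour(
                pos[t], 0.0, config.cell_radius_um, 1.0, None, config.n_contour_vertices
            )
        else:
            deform = [
                (config.deform_amp * rng_shape.uniform(0.3, 1.0),
                 rng_shape.uniform(0.0, 2.0 * np.pi))
                for _ in range(3)  # harmonics 2..4
            ]
            angle = float(np.arctan2(axis_dirs[t][1], axis_dirs[t][0]))
            verts = _cell_contour(
                pos[t], angle, config.cell_radius_um, config.elongation,
                deform, config.n_contour_vertices,
            )
        contours.append(Contour(frame=t, vertices=verts, object_role="cell_body"))

    # --- protrusion tips --------------------------------------------------
    if realized.size and realized.max() > 0:
        p25, p75 = np.percentile(realized, [25, 75])
    else:
        p25 = p75 = 0.0

    def kappa_at(s: float) -> float:
        if p75 <= p25:
            return 0.5 * (config.kappa_low + config.kappa_high)
        if s < p25:
            return config.kappa_low
        if s > p75:
            return config.kappa_high
        return config.kappa_low + (config.kappa_high - config.kappa_low) * (
            (s - p25) / (p75 - p25)
        )

    tips: list[PointTrack] = []
    tip_angles: dict[str, float] = {}
    tip_id = 0
    tip_dist = 1.4 * config.cell_radius_um
    for t in range(T - 1):
        if realized[t] == 0:
            continue  # no valid movement direction at this frame
        n_tips = rng_tips.poisson(config.protrusion_rate)
        if n_tips == 0:
            continue
        offsets = _sample_offsets(kappa_at(realized[t]), n_tips, rng_tips)
        base = np.arctan2(axis_dirs[t][1], axis_dirs[t][0])
        for off in offsets:
            ang = base + off
            xy = pos[t] + tip_dist * np.array([np.cos(ang), np.sin(ang)])
            tid = f"tip{tip_id:05d}"
            tips.append(PointTrack(tid, [t], [xy], role="protrusion_tip"))
            tip_angles[tid] = float(np.degrees(abs(((off + np.pi) % (2 * np.pi)) - np.pi)))
            tip_id += 1

    # --- centrosome: alternate fore/aft along the movement axis ----------
    signs = np.where(np.arange(T) % 2 == 0, 1.0, -1.0)
    cent_xy = pos + signs[:, None] * config.centrosome_offset_um * axis_dirs
    centrosome = PointTrack("centrosome", np.arange(T), cent_xy, role="centrosome")

    return track, tips, tip_angles, contours, centrosome


def _truth_geometry(config: SimConfig) -> TissueGeometry:
    h_um = config.field_size_px[1] * config.pixel_size_um
    layers = {
        "apical_surface": {f: np.array(0.05 * h_um) for f in range(config.n_frames)},
        "opl": {f: np.array(0.40 * h_um) for f in range(config.n_frames)},
        "ipl": {f: np.array(0.85 * h_um) for f in range(config.n_frames)},
    }
    return TissueGeometry(layers=layers, basal_sign=1)


def _neighbor_nuclei(config: SimConfig, track: PointTrack, rng: np.random.Generator):
    """Static neighbor nuclei: ellipses that never overlap the cell's path."""
    w, h = config.field_size_px
    n = int(round(config.neighbor_density * (w * h) / 1e4))
    keepout = (config.cell_radius_um * np.sqrt(config.elongation) + 4.0 * config.pixel_size_um)
    nuclei = []
    attempts = 0
    while len(nuclei) < n and attempts < 50 * max(n, 1):
        attempts += 1
        cx = rng.uniform(0, w) * config.pixel_size_um
        cy = rng.uniform(0, h) * config.pixel_size_um
        a = rng.uniform(4.0, 7.0) * config.pixel_size_um
        b = rng.uniform(3.0, 5.0) * config.pixel_size_um
        ang = rng.uniform(0, np.pi)
        dmin = np.min(np.linalg.norm(track.xy_um - np.array([cx, cy]), axis=1))
        if dmin < keepout + a:
            continue
        nuclei.append((cx, cy, a, b, ang))
    return nuclei


def render_frames(
    config: SimConfig,
    track: PointTrack,
    contours: list[Contour],
) -> tuple[ImageStack, np.ndarray, list[str]]:
    """Rasterize the truth into a calibrated 3-channel stack.

    Returns ``(stack, cumulative_drift_px, frame_flags)``.  Cumulative drift
    at frame t is ``t * drift_per_frame_px`` (zero at the reference frame 0)
    and is applied to every channel; a frame whose drifted contour leaves
    the field is flagged ``"out_of_field"`` rather than silently cropped.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_render = np.random.default_rng(ss.spawn(4)[3])
    T = config.n_frames
    w, h = config.field_size_px
    px = config.pixel_size_um
    drift = np.outer(np.arange(T), np.asarray(config.drift_per_frame_px, dtype=float))

    nuclei = _neighbor_nuclei(config, track, rng_render)
    # rasterize at 2x and block-average: antialiased edges keep downstream
    # subpixel sampling unbiased at object boundaries
    ss_f = 2
    W, H = w * ss_f, h * ss_f
    frames = np.zeros((T, h, w, 3), dtype=np.float64)
    flags = []
    from scipy import ndimage as ndi

    for t in range(T):
        shift_um = drift[t] * px
        verts_px = (contours[t].vertices + shift_um) / px  # (x, y) px
        flag = "ok"
        if (verts_px.min() < 0 or verts_px[:, 0].max() >= w or verts_px[:, 1].max() >= h):
            flag = "out_of_field"
        flags.append(flag)

        hi = np.zeros((H, W, 3), dtype=np.float64)
        vss = verts_px * ss_f
        rr, cc = skdraw.polygon(vss[:, 1], vss[:, 0], shape=(H, W))
        hi[rr, cc, 0] = config.cell_intensity

        # polarity channel: cortical band with front->back linear ramp
        mask = np.zeros((H, W), dtype=bool)
        mask[rr, cc] = True
        band = mask & ~ndi.binary_erosion(
            mask, iterations=int(config.cortex_width_px * ss_f)
        )
        br, bc = np.nonzero(band)
        if br.size:
            d = _frame_direction(track, t)
            proj = (bc * px / ss_f - (track.xy_um[t, 0] + shift_um[0])) * d[0] + (
                br * px / ss_f - (track.xy_um[t, 1] + shift_um[1])
            ) * d[1]
            span = proj.max() - proj.min()
            u = (proj.max() - proj) / span if span > 0 else np.zeros_like(proj)
            hi[br, bc, 1] = config.cell_intensity * (
                1.0 + (config.rear_polarity_strength - 1.0) * u
            )

        # neighbor nuclei channel (static content, drifts with the field)
        for cx, cy, a, b, ang in nuclei:
            rr2, cc2 = skdraw.ellipse(
                (cy + shift_um[1]) / px * ss_f, (cx + shift_um[0]) / px * ss_f,
                b / px * ss_f, a / px * ss_f, shape=(H, W), rotation=ang,
            )
            hi[rr2, cc2, 2] = config.nucleus_intensity

        frames[t] = hi.reshape(h, ss_f, w, ss_f, 3).mean(axis=(1, 3))

    if config.noise_sd > 0:
        frames = frames + rng_render.normal(0.0, config.noise_sd, frames.shape)
        frames = np.clip(frames, 0.0, None)
    # float32 is the on-disk dtype; render in it so TIFF round-trips exactly
    frames = frames.astype(np.float32)

    if config.n_z == 3:
        # small z-stack mode: dimmed flanking planes, crisp central plane
        zs = np.stack([0.6 * frames, frames, 0.6 * frames], axis=1)
        frames = zs

    stack = ImageStack(
        pixels=frames,
        pixel_size_um=px,
        frame_interval_min=config.frame_interval_min,
        channel_names=CHANNELS,
    )
    return stack, drift, flags


def _frame_direction(track: PointTrack, t: int) -> np.ndarray:
    """Instantaneous movement direction at frame t; falls back to the most
    recent non-zero step (last frame has no forward step of its own)."""
    xy = track.xy_um
    candidates = list(range(min(t, len(xy) - 2), -1, -1))
    if t < len(xy) - 1:
        candidates.insert(0, t)
    for s in candidates:
        step = xy[s + 1] - xy[s]
        if np.linalg.norm(step) > 0:
            return _unit(step)
    return np.array([1.0, 0.0])


def build_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate and render in memory (no files)."""
    track, tips, tip_angles, contours, centrosome = simulate_kinematics(config)
    stack, drift, flags = render_frames(config, track, contours)
    ds = SyntheticDataset(
        config=config,
        stack=stack,
        truth_cell_track=track,
        truth_contours=contours,
        truth_protrusions=tips,
        truth_tip_angles_deg=tip_angles,
        truth_centrosome_track=centrosome,
        truth_drift_px=drift,
        truth_geometry=_truth_geometry(config),
        frame_flags=flags,
    )
    ds.check_invariants()
    return ds


def _contours_table(contours: list[Contour]) -> pd.DataFrame:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append((c.frame, i, x, y))
    return pd.DataFrame(rows, columns=["frame", "vertex_index", "x_um", "y_um"])


def generate_dataset(config: SimConfig, out_dir: str | os.PathLike) -> SyntheticDataset:
    """Generate, render and persist a dataset (TIFF + CSV truth + YAML config).

    The same (config, seed) written twice produces byte-identical files;
    :func:`load_dataset` round-trips the tables exactly.
    """
    ds = build_dataset(config)
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        write_stack(ds.stack, os.path.join(out_dir, "stack.tif"))

        def save(df: pd.DataFrame, name: str) -> None:
            df.to_csv(os.path.join(out_dir, name), index=False, float_format="%.6f")

        save(ds.truth_cell_track.to_frame_table(), "truth_track.csv")
        tips_df = pd.concat(
            [t.to_frame_table() for t in ds.truth_protrusions], ignore_index=True
        ) if ds.truth_protrusions else pd.DataFrame(
            columns=["track_id", "frame", "x_um", "y_um"]
        )
        tips_df["angle_true_deg"] = tips_df["track_id"].map(ds.truth_tip_angles_deg)
        save(tips_df, "truth_protrusions.csv")
        save(ds.truth_centrosome_track.to_frame_table(), "truth_centrosome.csv")
        save(_contours_table(ds.truth_contours), "truth_contours.csv")
        drift_df = pd.DataFrame(
            {
                "frame": np.arange(config.n_frames),
                "dx_px": ds.truth_drift_px[:, 0],
                "dy_px": ds.truth_drift_px[:, 1],
                "flag": ds.frame_flags,
            }
        )
        save(drift_df, "truth_drift.csv")
        save(ds.truth_geometry.to_frame_table(), "truth_geometry.csv")
        with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    except OSError as exc:
        raise OSError(f"cannot persist dataset under {out_dir}: {exc}") from exc
    return ds


def load_dataset(out_dir: str | os.PathLike) -> SyntheticDataset:
    """Reload a persisted dataset; truth tables round-trip bit-exactly."""
    from hcmotion.imgio import read_stack, read_tracks

    out_dir = os.fspath(out_dir)
    with open(os.path.join(out_dir, "config.yaml")) as fh:
        config = SimConfig.from_dict(yaml.safe_load(fh))
    stack = read_stack(
        os.path.join(out_dir, "stack.tif"),
        pixel_size_um=config.pixel_size_um,
        frame_interval_min=config.frame_interval_min,
        channel_names=CHANNELS,
    )
    track = read_tracks(os.path.join(out_dir, "truth_track.csv"), role="cell_centroid")[0]
    tips_df = pd.read_csv(os.path.join(out_dir, "truth_protrusions.csv"))
    tips, tip_angles = [], {}
    for tid, grp in tips_df.groupby("track_id", sort=True):
        tips.append(
            PointTrack(
                str(tid), grp["frame"].to_numpy(int),
                grp[["x_um", "y_um"]].to_numpy(float), role="protrusion_tip",
            )
        )
        tip_angles[str(tid)] = float(grp["angle_true_deg"].iloc[0])
    centrosome = read_tracks(os.path.join(out_dir, "truth_centrosome.csv"), role="centrosome")[0]
    cont_df = pd.read_csv(os.path.join(out_dir, "truth_contours.csv"))
    contours = [
        Contour(frame=int(f), vertices=grp[["x_um", "y_um"]].to_numpy(float))
        for f, grp in cont_df.groupby("frame", sort=True)
    ]
    drift_df = pd.read_csv(os.path.join(out_dir, "truth_drift.csv"))
    geometry = TissueGeometry.from_frame_table(
        pd.read_csv(os.path.join(out_dir, "truth_geometry.csv"))
    )
    ds = SyntheticDataset(
        config=config,
        stack=stack,
        truth_cell_track=track,
        truth_contours=contours,
        truth_protrusions=tips,
        truth_tip_angles_deg=tip_angles,
        truth_centrosome_track=centrosome,
        truth_drift_px=drift_df[["dx_px", "dy_px"]].to_numpy(float),
        truth_geometry=geometry,
        frame_flags=list(drift_df["flag"]),
    )
    ds.check_invariants()
    return ds
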