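"""Image, track and geometry I/O plus the core in-memory containers.

Conventions used throughout the package:

* image coordinates: origin top-left, x rightward (columns), y downward
  (rows); after calibration every coordinate is in micrometres (µm).
* time: minutes; speeds in µm/min.
* frames are 0-based internally.  Track tables exported by MTrackJ are
  1-based; pass ``frames_one_based=True`` to :func:`read_tracks`.
* stacks are stored frame-major: ``(T, Y, X, C)`` or, for the optional
  small-z mode, ``(T, Z, Y, X, C)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

#: decimal places at which µm coordinates round-trip losslessly through CSV
COORD_DECIMALS = 6

TRACK_ROLES = ("cell_centroid", "protrusion_tip", "centrosome")


class FormatError(ValueError):
    """Raised when a file cannot be interpreted in the declared format."""


@dataclass
class ImageStack:
    """Calibrated multi-channel image stack.

    Parameters
    ----------
    pixels
        Array shaped ``(T, Y, X, C)`` (or ``(T, Z, Y, X, C)``), finite and
        non-negative.
    pixel_size_um
        Lateral calibration, µm per pixel (> 0).  Light-sheet acquisitions
        do not embed this reliably, so it is always an explicit input.
    frame_interval_min
        Time between frames in minutes (> 0).
    channel_names
        One label per channel.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (4, 5):
            raise FormatError(
                f"stack must be (T, Y, X, C) or (T, Z, Y, X, C); got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_interval_min <= 0:
            raise ValueError(f"frame_interval_min must be > 0, got {self.frame_interval_min}")
        if self.pixels.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("stack intensities must be finite and >= 0")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.pixels.shape[-1]))
        if len(self.channel_names) != self.pixels.shape[-1]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 5

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Single-channel view, shape ``(T, [Z,] Y, X)``."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"channel {name_or_index!r} not in {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.pixels[..., idx]


@dataclass
class PointTrack:
    """Time-indexed point positions (cell centroid, protrusion tip, centrosome).

    ``frames`` are strictly increasing; gaps are permitted and preserved.
    Positions are in µm, image coordinates.
    """

    track_id: str
    frames: np.ndarray
    xy_um: np.ndarray
    role: str = "cell_centroid"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_um = np.asarray(self.xy_um, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.xy_um):
            raise ValueError("frames and xy_um must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frames must be strictly increasing")
        if self.role not in TRACK_ROLES:
            raise ValueError(f"role must be one of {TRACK_ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.frames)

    def position_at(self, frame: int) -> np.ndarray | None:
        hits = np.nonzero(self.frames == frame)[0]
        return self.xy_um[hits[0]] if hits.size else None

    def to_frame_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.frames,
                "x_um": self.xy_um[:, 0],
                "y_um": self.xy_um[:, 1],
            }
        )


@dataclass
class TissueGeometry:
    """Per-frame positions of tissue landmarks along the apico-basal axis.

    Layers (``apical_surface``, ``opl``, ``ipl``) are each either a scalar y
    (a horizontal line at that depth) or a polyline ``(N, 2)`` array per
    frame.  ``basal_sign = +1`` means basal points toward increasing image y
    (the default when the apical surface is at the top of the field).
    """

    layers: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    basal_sign: int = 1

    def __post_init__(self) -> None:
        if self.basal_sign not in (-1, 1):
            raise ValueError("basal_sign must be +1 or -1")
        for name, per_frame in self.layers.items():
            for f, geom in per_frame.items():
                arr = np.atleast_2d(np.asarray(geom, dtype=float))
                if arr.shape[-1] != 2 and arr.size != 1:
                    raise ValueError(f"layer {name!r} frame {f}: expected scalar y or (N,2)")
        self._check_ordering()

    def _check_ordering(self) -> None:
        # where both plexiform layers exist, the OPL must sit apical to the IPL
        def mean_y(name: str, f: int) -> float:
            g = np.atleast_2d(np.asarray(self.layers[name][f], dtype=float))
            return float(g[..., -1].mean())

        opl = self.layers.get("opl", {})
        ipl = self.layers.get("ipl", {})
        apical = self.layers.get("apical_surface", {})
        for f in set(opl) & set(ipl) & set(apical):
            a, o, i = mean_y("apical_surface", f), mean_y("opl", f), mean_y("ipl", f)
            if not min(a, i) <= o <= max(a, i):
                raise ValueError(
                    f"frame {f}: OPL (y={o}) must lie between apical surface (y={a}) "
                    f"and IPL (y={i})"
                )

    def frames_for(self, layer: str) -> list[int]:
        return sorted(self.layers.get(layer, {}))

    def layer_at(self, layer: str, frame: int, max_gap: int = 2) -> np.ndarray | None:
        """Layer geometry at ``frame``, nearest-frame filled up to ``max_gap``."""
        per_frame = self.layers.get(layer)
        if not per_frame:
            return None
        if frame in per_frame:
            return np.asarray(per_frame[frame], dtype=float)
        frames = np.array(sorted(per_frame))
        nearest = frames[np.argmin(np.abs(frames - frame))]
        if abs(int(nearest) - frame) > max_gap:
            return None
        return np.asarray(per_frame[int(nearest)], dtype=float)

    def to_frame_table(self) -> pd.DataFrame:
        rows = []
        for name, per_frame in self.layers.items():
            for f in sorted(per_frame):
                geom = np.atleast_2d(np.asarray(per_frame[f], dtype=float))
                if geom.size == 1:
                    rows.append((f, name, np.nan, float(geom.ravel()[0])))
                else:
                    for x, y in geom:
                        rows.append((f, name, float(x), float(y)))
        return pd.DataFrame(rows, columns=["frame", "layer", "x_um", "y_um"])

    @classmethod
    def from_frame_table(cls, df: pd.DataFrame, basal_sign: int = 1) -> "TissueGeometry":
        layers: dict[str, dict[int, np.ndarray]] = {}
        for (f, name), grp in df.groupby(["frame", "layer"], sort=True):
            entry = layers.setdefault(str(name), {})
            if len(grp) == 1 and (("x_um" not in grp) or grp["x_um"].isna().all()):
                entry[int(f)] = np.array(float(grp["y_um"].iloc[0]))
            else:
                entry[int(f)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        return cls(layers=layers, basal_sign=basal_sign)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_stack(
    path: str | os.PathLike,
    pixel_size_um: float,
    frame_interval_min: float,
    channel_names: tuple[str, ...] = (),
) -> ImageStack:
    """Read a TIFF stack and normalize axes to ``(T, [Z,] Y, X, C)``.

    Calibration is always explicit: the acquisitions this targets do not
    carry trustworthy pixel-size metadata.
    """
    try:
        arr = tifffile.imread(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:  # single frame, single channel
        arr = arr[None, :, :, None]
    elif arr.ndim == 3:  # (T, Y, X) single channel
        arr = arr[:, :, :, None]
    elif arr.ndim == 4:  # written frame-major (T, C, Y, X)
        arr = np.moveaxis(arr, 1, -1)
    elif arr.ndim == 5:  # (T, Z, C, Y, X)
        arr = np.moveaxis(arr, 2, -1)
    else:
        raise FormatError(
            f"cannot interpret TIFF with {arr.ndim} axes (shape {arr.shape}): "
            "expected 2-5 axes with frame-major layout"
        )
    return ImageStack(
        pixels=arr.astype(np.float64),
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
        channel_names=channel_names,
    )


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack frame-major: (T, C, Y, X) or (T, Z, C, Y, X)."""
    arr = np.moveaxis(stack.pixels, -1, 1 if not stack.has_z else 2)
    tifffile.imwrite(
        os.fspath(path), arr.astype(np.float32),
        photometric="minisblack", planarconfig="separate",
    )


_COL_ALIASES = {
    "track_id": ("track_id", "tid", "track", "trackid", "nr"),
    "frame": ("frame", "t", "t [frame]", "slice", "time"),
    "x": ("x", "x_um", "x [pixel]", "x_px"),
    "y": ("y", "y_um", "y [pixel]", "y_px"),
    "angle_true_deg": ("angle_true_deg",),
}


def _match_columns(df: pd.DataFrame) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in df.columns}
    out = {}
    for canon, aliases in _COL_ALIASES.items():
        for a in aliases:
            if a in lower:
                out[canon] = lower[a]
                break
    missing = {"track_id", "frame", "x", "y"} - set(out)
    if missing:
        raise FormatError(
            f"track CSV must contain columns for {sorted(missing)}; found {list(df.columns)}"
        )
    return out


def read_tracks(
    path: str | os.PathLike,
    role: str = "cell_centroid",
    units: str = "um",
    pixel_size_um: float | None = None,
    frames_one_based: bool = False,
) -> list[PointTrack]:
    """Read an MTrackJ-style track table into µm, 0-based frames.

    Parameters
    ----------
    units
        ``"um"`` if coordinates are already micrometres, ``"px"`` to convert
        using ``pixel_size_um``.
    frames_one_based
        MTrackJ exports number frames from 1; set this flag to shift to the
        package's 0-based convention.  A silent off-by-one here is the
        classic tracking bug, so the shift is never guessed from the data.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("track file %s contains a header but no rows", path)
        return []
    cols = _match_columns(df)
    if units == "px":
        if pixel_size_um is None or pixel_size_um <= 0:
            raise ValueError("units='px' requires a positive pixel_size_um")
        scale = pixel_size_um
    elif units == "um":
        scale = 1.0
    else:
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")

    dup = df.duplicated(subset=[cols["track_id"], cols["frame"]], keep=False)
    if dup.any():
        offenders = df.loc[dup, [cols["track_id"], cols["frame"]]].drop_duplicates()
        raise FormatError(
            "duplicate (track, frame) rows: "
            + ", ".join(f"({t}, {f})" for t, f in offenders.itertuples(index=False))
        )

    tracks: list[PointTrack] = []
    for tid, grp in df.groupby(cols["track_id"], sort=True):
        frames = grp[cols["frame"]].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            raise FormatError(f"track {tid!r}: frame column is not strictly increasing")
        if frames_one_based:
            frames = frames - 1
        xy = grp[[cols["x"], cols["y"]]].to_numpy(dtype=float) * scale
        tracks.append(PointTrack(track_id=str(tid), frames=frames, xy_um=xy, role=role))
    return tracks


def tracks_to_table(tracks: list[PointTrack]) -> pd.DataFrame:
    if not tracks:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    return pd.concat([t.to_frame_table() for t in tracks], ignore_index=True)


def read_geometry(path: str | os.PathLike, basal_sign: int = 1) -> TissueGeometry:
    df = pd.read_csv(path)
    needed = {"frame", "layer", "y_um"}
    if not needed <= set(df.columns):
        raise FormatError(f"geometry CSV needs columns {sorted(needed)}; found {list(df.columns)}")
    if "x_um" not in df.columns:
        df = df.assign(x_um=np.nan)
    return TissueGeometry.from_frame_table(df, basal_sign=basal_sign)


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _atomic_write_csv(df: pd.DataFrame, path: str) -> None:
    tmp = path + ".tmp"
    df.to_csv(tmp, index=False, float_format=f"%.{COORD_DECIMALS}f")
    os.replace(tmp, path)  # write-then-rename: no truncated file on failure


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    manifest_extra: dict | None = None,
) -> str:
    """Write one CSV per table plus a run manifest; return the manifest path.

    Column order is taken from each DataFrame as given, so reruns on the
    same inputs produce byte-identical files.
    """
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        written = {}
        for name, df in tables.items():
            path = os.path.join(out_dir, f"{name}.csv")
            _atomic_write_csv(df, path)
            written[name] = os.path.basename(path)
        manifest = {
            "tool": "hcmotion",
            "version": _version(),
            "tables": written,
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        mpath = os.path.join(out_dir, "manifest.json")
        tmp = mpath + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, mpath)
    except OSError as exc:
        raise OSError(f"cannot write results under {out_dir}: {exc}") from exc
    return mpath


def _version() -> str:
    from hcmotion import __version__

    return __version__
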