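"""Shared domain types, coordinate conventions and file I/O.

Conventions used throughout the package:

* image arrays are ordered ``(t, z, y, x)``;
* voxel indexing is 0-based and half-open;
* positions and lengths are in µm, volumes in µm³, time in minutes,
  rates per hour;
* in simulated dorsal views +x points lateral→medial and +y
  caudal→rostral; angles are measured counter-clockwise from +x in
  degrees on ``(-180, 180]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VoxelGeometry",
    "ImageSequence",
    "ROIBox",
    "TRACK_COLUMNS_2D",
    "TRACK_COLUMNS_3D",
    "validate_track_table",
    "read_image_sequence",
    "write_image_sequence",
    "read_tracks",
    "write_tracks",
    "DEFAULT_CONFIG",
    "load_config",
    "wrap_angle_deg",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical sampling of a 4D acquisition.

    Defaults match two-photon stacks sampled at 250 nm laterally,
    510 nm axially and one stack every 20 minutes.

    Parameters
    ----------
    dx, dy : float
        µm per pixel along x and y.
    dz : float
        µm per z step.
    dt : float
        minutes per frame.
    """

    dx: float = 0.25
    dy: float = 0.25
    dz: float = 0.51
    dt: float = 20.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz", "dt"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz


@dataclass
class ImageSequence:
    """A 4D intensity array ``(t, z, y, x)`` with its voxel geometry."""

    data: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D (t,z,y,x) array, got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int) -> np.ndarray:
        """3D stack ``(z, y, x)`` at frame index ``t``."""
        return self.data[t]

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes."""
        return np.arange(self.n_frames) * self.geometry.dt


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned voxel box, 0-based and half-open on every axis."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1 and self.z0 < self.z1):
            raise ValueError(f"degenerate ROI box {self}")
        if min(self.x0, self.y0, self.z0) < 0:
            raise ValueError(f"ROI box has negative origin {self}")

    def check_fits(self, stack_shape: tuple[int, int, int]) -> None:
        """Raise if the box does not fit inside a ``(z, y, x)`` stack."""
        nz, ny, nx = stack_shape
        if self.z1 > nz or self.y1 > ny or self.x1 > nx:
            raise ValueError(f"ROI box {self} exceeds stack shape {stack_shape}")

    def crop(self, stack: np.ndarray) -> np.ndarray:
        self.check_fits(stack.shape)
        return stack[self.z0 : self.z1, self.y0 : self.y1, self.x0 : self.x1]

    @classmethod
    def from_um(
        cls,
        geometry: VoxelGeometry,
        x0_um: float,
        y0_um: float,
        z0_um: float,
        width_um: float,
        length_um: float,
        depth_um: float,
    ) -> "ROIBox":
        """Build a box from a physical origin and extent (µm)."""
        x0 = int(round(x0_um / geometry.dx))
        y0 = int(round(y0_um / geometry.dy))
        z0 = int(round(z0_um / geometry.dz))
        return cls(
            x0=x0,
            x1=x0 + max(1, int(round(width_um / geometry.dx))),
            y0=y0,
            y1=y0 + max(1, int(round(length_um / geometry.dy))),
            z0=z0,
            z1=z0 + max(1, int(round(depth_um / geometry.dz))),
        )


TRACK_COLUMNS_2D = ["track_id", "frame", "x_um", "y_um"]
TRACK_COLUMNS_3D = TRACK_COLUMNS_2D + ["z_um"]


def validate_track_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a track table and return it sorted by (track_id, frame).

    A track table holds one row per (cell, frame) with columns
    ``track_id, frame, x_um, y_um[, z_um]``. Within a track, frame
    indices must be strictly increasing and positions finite.
    """
    cols = list(table.columns)
    if cols[: len(TRACK_COLUMNS_2D)] != TRACK_COLUMNS_2D or cols not in (
        TRACK_COLUMNS_2D,
        TRACK_COLUMNS_3D,
    ):
        raise ValueError(f"track table columns must be {TRACK_COLUMNS_2D} or {TRACK_COLUMNS_3D}, got {cols}")
    pos_cols = [c for c in cols if c.endswith("_um")]
    if len(table) and not np.all(np.isfinite(table[pos_cols].to_numpy(float))):
        raise ValueError("track positions must be finite")
    out = table.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    if len(out) and out.duplicated(["track_id", "frame"]).any():
        dup = out[out.duplicated(["track_id", "frame"])].iloc[0]
        raise ValueError(f"duplicate (track_id, frame) pair: ({dup.track_id}, {dup.frame})")
    return out


def read_image_sequence(
    path: str | Path,
    geometry: VoxelGeometry,
    n_slices: int | None = None,
    z_major: bool = False,
) -> ImageSequence:
    """Read a multi-page TIFF as a ``(t, z, y, x)`` sequence.

    Pages are assumed t-major (all z slices of frame 0, then frame 1,
    ...); pass ``z_major=True`` for the transposed page order. If the
    file carries 4D shape metadata (as written by
    :func:`write_image_sequence`) it is used directly; otherwise
    ``n_slices`` must be given and must divide the page count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 4:
        seq = ImageSequence(data, geometry)
        return seq
    if data.ndim == 2:
        data = data[None]
    if n_slices is None:
        raise ValueError("n_slices is required for files without 4D shape metadata")
    n_pages = data.shape[0]
    if n_slices <= 0 or n_pages % n_slices:
        raise ValueError(f"page count {n_pages} is not divisible by z depth {n_slices}")
    n_frames = n_pages // n_slices
    if z_major:
        data = data.reshape(n_slices, n_frames, *data.shape[1:]).swapaxes(0, 1)
    else:
        data = data.reshape(n_frames, n_slices, *data.shape[1:])
    return ImageSequence(data, geometry)


def write_image_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page TIFF (t-major page order).

    Integer data round-trips bit-exactly through
    :func:`read_image_sequence`.
    """
    if seq.data.size == 0:
        raise ValueError("refusing to write an empty sequence")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, seq.data, photometric="minisblack", metadata={"axes": "TZYX"}
    )


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track CSV (``track_id,frame,x_um,y_um[,z_um]``)."""
    table = pd.read_csv(path, float_precision="round_trip")
    table["track_id"] = table["track_id"].astype(int)
    table["frame"] = table["frame"].astype(int)
    return validate_track_table(table)


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated track table to CSV (lossless round-trip)."""
    table = validate_track_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


#: Pipeline defaults. Detection gates (12 µm minimum rounded-cell
#: diameter, 0.85 circularity) and the 20-minute frame interval follow
#: the published analysis; the rest are package defaults.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "min_diameter_um": 12.0,
    "circularity_min": 0.85,
    "link_radius_um": 6.0,
    "max_link_distance_um": 5.0,
    "spot_diameter_um": 8.0,
    "rolling_ball_radius_px": 20,
    "min_track_len": 3,
    "depth_fractions": [0.25, 0.5, 0.75],
}

_CONFIG_RANGES = {
    "circularity_min": (0.0, 1.0),
    "min_diameter_um": (0.0, np.inf),
    "link_radius_um": (0.0, np.inf),
    "max_link_distance_um": (0.0, np.inf),
    "spot_diameter_um": (0.0, np.inf),
    "rolling_ball_radius_px": (1, np.inf),
    "min_track_len": (2, np.inf),
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Load a YAML parameter file, fill defaults, reject unknown keys.

    The returned dict always records the ``seed`` so that every derived
    artifact can carry the configuration that produced it.
    """
    cfg = dict(DEFAULT_CONFIG)
    loaded: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        loaded.update(raw or {})
    loaded.update(overrides or {})
    unknown = set(loaded) - set(cfg)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg.update(loaded)
    for key, (lo, hi) in _CONFIG_RANGES.items():
        v = cfg[key]
        if not (lo <= v <= hi):
            raise ValueError(f"{key}={v} outside [{lo}, {hi}]")
    return cfg


def wrap_angle_deg(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees onto ``(-180, 180]``."""
    wrapped = -np.mod(-np.asarray(theta, float) + 180.0, 360.0) + 180.0
    return wrapped if np.ndim(theta) else float(wrapped)
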