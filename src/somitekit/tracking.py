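"""Cell tracking: preprocessing, spot detection, LAP linking and
directionality statistics.

The pipeline mirrors a TrackMate-style workflow on a single dorsal
slice: frames are inverted (dark cell interiors become bright spots),
band-pass filtered and rolling-ball background subtracted; spots are
found by Laplacian-of-Gaussian detection with sub-pixel refinement;
frame-to-frame links are the solution of a linear assignment problem
(simple LAP, no merges or splits); per-track statistics include the
circular-mean heading, net displacement, path length and mean speed.
Directionality of a population is the mean resultant length
R = |Σ_k u(θ̄_k)| / N of per-track unit heading vectors: R → 1 for
concerted movement, R → 0 when opposite tracks cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage import feature, restoration

from .io import ImageSequence, VoxelGeometry, validate_track_table, wrap_angle_deg

__all__ = [
    "Spot",
    "CellTrack",
    "DirectionalityResult",
    "preprocess_for_tracking",
    "detect_spots",
    "link_spots_lap",
    "track_metrics",
    "directionality_index",
    "angle_distribution",
    "tracks_to_table",
    "track_movie",
]


@dataclass(frozen=True)
class Spot:
    """One detection in one frame, in physical coordinates."""

    frame: int
    x_um: float
    y_um: float
    intensity: float = 0.0
    quality: float = 0.0


@dataclass
class CellTrack:
    """An ordered sequence of linked spots for one cell."""

    spots: list[Spot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> list[int]:
        return [s.frame for s in self.spots]

    def positions(self) -> np.ndarray:
        return np.array([(s.x_um, s.y_um) for s in self.spots])


@dataclass
class DirectionalityResult:
    """Mean resultant length of per-track headings."""

    angles_deg: np.ndarray
    resultant_length: float
    mean_angle_deg: float
    n_tracks: int


def preprocess_for_tracking(
    seq: ImageSequence,
    rolling_ball_radius_px: int = 20,
    band_sigma_px: tuple[float, float] = (2.0, 16.0),
) -> ImageSequence:
    """Invert, band-pass filter and background-subtract a 2D+t movie.

    Operates on a one-slice sequence (the chosen dorsal slice).
    Inversion turns dark membrane-bounded interiors into bright
    blobs; the difference-of-Gaussians band-pass keeps structures
    between the two sigmas; the rolling-ball step (radius in pixels)
    removes any remaining smooth background. Output is non-negative.
    """
    if rolling_ball_radius_px <= 0:
        raise ValueError("rolling ball radius must be positive")
    lo, hi = band_sigma_px
    if not 0 < lo < hi:
        raise ValueError("band sigmas must satisfy 0 < low < high")
    if seq.n_slices != 1:
        raise ValueError("preprocessing expects a single-slice (2D+t) sequence")
    frames = seq.data[:, 0].astype(float)
    vmax = float(frames.max())
    out = np.empty_like(frames)
    for t, img in enumerate(frames):
        inv = vmax - img
        band = ndi.gaussian_filter(inv, lo) - ndi.gaussian_filter(inv, hi)
        band = np.clip(band, 0.0, None)
        background = restoration.rolling_ball(band, radius=rolling_ball_radius_px)
        out[t] = np.clip(band - background, 0.0, None)
    return ImageSequence(out[:, None], seq.geometry)


def detect_spots(
    frame: np.ndarray,
    geometry: VoxelGeometry,
    frame_index: int = 0,
    expected_diameter_um: float = 8.0,
    quality_threshold: float = 0.02,
    smooth_sigma_px: float = 1.5,
) -> list[Spot]:
    """Laplacian-of-Gaussian blob detection with sub-pixel refinement.

    The LoG scale is matched to ``expected_diameter_um`` (blob radius
    ≈ σ√2); ``quality_threshold`` is the minimum scale-normalized LoG
    response on the max-normalized frame. Positions are refined by an
    intensity-weighted centroid in a window around each peak on the
    lightly smoothed frame; detections closer than 0.6× the expected
    diameter are merged (highest quality wins). Positions in µm.
    """
    img = np.asarray(frame, float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a 2D frame")
    if geometry.dx != geometry.dy:
        raise ValueError("spot detection assumes square pixels")
    if not np.isfinite(quality_threshold):
        return []
    if smooth_sigma_px > 0:
        img = ndi.gaussian_filter(img, smooth_sigma_px)
    if np.ptp(img) == 0:
        return []
    sigma0 = (expected_diameter_um / 2.0) / np.sqrt(2.0) / geometry.dx
    blobs = feature.blob_log(
        img / img.max(),
        min_sigma=0.7 * sigma0,
        max_sigma=1.4 * sigma0,
        num_sigma=4,
        threshold=quality_threshold,
        overlap=0.3,
    )
    log_response = -(sigma0**2) * ndi.gaussian_laplace(img / img.max(), sigma0)
    raw: list[Spot] = []
    win = max(2, int(round(sigma0)))
    ny, nx = img.shape
    for y, x, sigma in blobs:
        yi, xi = min(int(round(y)), ny - 1), min(int(round(x)), nx - 1)
        y0, y1 = max(0, yi - win), min(ny, yi + win + 1)
        x0, x1 = max(0, xi - win), min(nx, xi + win + 1)
        patch = img[y0:y1, x0:x1]
        w = np.clip(patch - np.median(patch), 0.0, None)
        tot = w.sum()
        if tot > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            yc = float((w * yy).sum() / tot)
            xc = float((w * xx).sum() / tot)
        else:
            yc, xc = float(y), float(x)
        raw.append(
            Spot(
                frame=frame_index,
                x_um=xc * geometry.dx,
                y_um=yc * geometry.dy,
                intensity=float(img[yi, xi]),
                quality=float(log_response[yi, xi]),
            )
        )
    # merge near-duplicate detections (multi-scale responses of one cell)
    raw.sort(key=lambda s: -s.quality)
    min_sep = 0.6 * expected_diameter_um
    spots: list[Spot] = []
    for s in raw:
        if all(np.hypot(s.x_um - k.x_um, s.y_um - k.y_um) >= min_sep for k in spots):
            spots.append(s)
    return spots


def _lap_pairs(
    src: np.ndarray, dst: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Optimal frame-to-frame links via the augmented LAP matrix.

    Cost of a link is the squared distance (∞ beyond ``max_dist``);
    the alternative cost of leaving a spot unlinked (track end or
    start) is ``max_dist²``. The Jaqaman-style block matrix makes the
    assignment always feasible.
    """
    n, m = len(src), len(dst)
    if n == 0 or m == 0:
        return []
    d2 = ((src[:, None, :] - dst[None, :, :]) ** 2).sum(-1)
    big = 1e12
    link = np.where(d2 <= max_dist**2, d2, big)
    alt = max_dist**2
    top = np.hstack([link, np.full((n, n), big) + np.diag(np.full(n, alt - big))])
    # lower-right zeros make the matrix objective exactly
    # Σ_link d² + alt·(#unlinked source + #unlinked destination)
    bottom = np.hstack(
        [np.full((m, m), big) + np.diag(np.full(m, alt - big)), np.zeros((m, n))]
    )
    cost = np.vstack([top, bottom])
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] <= max_dist**2
    ]


def link_spots_lap(
    spots_by_frame: list[list[Spot]],
    max_link_distance_um: float = 5.0,
    allow_gap: int = 0,
) -> list[CellTrack]:
    """Simple-LAP linking of spots into tracks.

    Per consecutive frame pair the linear assignment problem over
    squared distances is solved with non-link cost
    ``max_link_distance²``; unlinked spots terminate or start tracks.
    ``allow_gap=1`` additionally closes single-frame gaps by linking
    track ends to track starts two frames later within the same
    distance gate. No merging or splitting.
    """
    if max_link_distance_um < 0:
        raise ValueError("max link distance must be non-negative")
    if allow_gap not in (0, 1):
        raise ValueError("allow_gap must be 0 or 1")
    tracks: list[CellTrack] = []
    open_by_spot: dict[int, CellTrack] = {}  # id(last spot) -> track
    for f, spots in enumerate(spots_by_frame):
        for s in spots:
            if s.frame != f:
                raise ValueError("spots_by_frame groups must match frame indices")
        if f == 0:
            for s in spots:
                tr = CellTrack([s])
                tracks.append(tr)
                open_by_spot[id(s)] = tr
            continue
        prev = spots_by_frame[f - 1]
        pairs = _lap_pairs(
            np.array([(s.x_um, s.y_um) for s in prev]).reshape(-1, 2),
            np.array([(s.x_um, s.y_um) for s in spots]).reshape(-1, 2),
            max_link_distance_um,
        )
        linked_dst = set()
        for i, j in pairs:
            tr = open_by_spot.pop(id(prev[i]), None)
            if tr is None:  # spot already consumed (should not happen)
                continue
            tr.spots.append(spots[j])
            open_by_spot[id(spots[j])] = tr
            linked_dst.add(j)
        for j, s in enumerate(spots):
            if j not in linked_dst:
                tr = CellTrack([s])
                tracks.append(tr)
                open_by_spot[id(s)] = tr
    if allow_gap == 1:
        tracks = _close_single_frame_gaps(tracks, max_link_distance_um)
    return tracks


def _close_single_frame_gaps(
    tracks: list[CellTrack], max_dist: float
) -> list[CellTrack]:
    changed = True
    while changed:
        changed = False
        for a in tracks:
            for b in tracks:
                if a is b or not a.spots or not b.spots:
                    continue
                if b.spots[0].frame - a.spots[-1].frame != 2:
                    continue
                d = np.hypot(
                    a.spots[-1].x_um - b.spots[0].x_um,
                    a.spots[-1].y_um - b.spots[0].y_um,
                )
                if d <= max_dist:
                    a.spots.extend(b.spots)
                    b.spots = []
                    changed = True
        tracks = [t for t in tracks if t.spots]
    return tracks


def track_metrics(
    track: CellTrack, dt_min: float, direction_mode: str = "circular_mean"
) -> tuple[float, float, float, float]:
    """Per-track (θ̄, net displacement, path length, mean speed).

    θ̄ is the circular mean of per-step heading angles in degrees on
    (−180, 180] (``direction_mode="net"`` uses the net-displacement
    bearing instead); net displacement is |last − first| in µm; path
    length the summed step lengths; mean speed the path length divided
    by the elapsed minutes.
    """
    if len(track) < 2:
        raise ValueError("track metrics require at least 2 spots")
    pos = track.positions()
    steps = np.diff(pos, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    path = float(lengths.sum())
    total_min = (track.frames[-1] - track.frames[0]) * dt_min
    speed = path / total_min if total_min > 0 else 0.0
    if direction_mode == "net":
        delta = pos[-1] - pos[0]
        theta = float(np.degrees(np.arctan2(delta[1], delta[0]))) if net > 0 else np.nan
    elif direction_mode == "circular_mean":
        moving = lengths > 0
        if not moving.any():
            theta = np.nan
        else:
            headings = np.arctan2(steps[moving, 1], steps[moving, 0])
            mean_vec = np.exp(1j * headings).mean()
            theta = float(np.degrees(np.angle(mean_vec)))
    else:
        raise ValueError(f"unknown direction mode {direction_mode!r}")
    if np.isfinite(theta):
        theta = float(wrap_angle_deg(theta))
    return theta, net, path, speed


def directionality_index(
    tracks: list[CellTrack],
    dt_min: float = 20.0,
    min_track_len: int = 3,
    direction_mode: str = "circular_mean",
) -> DirectionalityResult:
    """Mean resultant length R of per-track headings.

    Tracks shorter than ``min_track_len`` spots are excluded as noise.
    R = 1 when all tracks share one heading; R = 0 when headings
    cancel (e.g. two opposite tracks). The population's unnormalized
    resultant is recoverable as R·N.
    """
    angles = []
    for tr in tracks:
        if len(tr) < min_track_len:
            continue
        theta, *_ = track_metrics(tr, dt_min, direction_mode)
        if np.isfinite(theta):
            angles.append(theta)
    if not angles:
        raise ValueError("no track with a defined mean direction")
    ang = np.asarray(angles)
    vec = np.exp(1j * np.radians(ang)).mean()
    return DirectionalityResult(
        angles_deg=ang,
        resultant_length=float(np.abs(vec)),
        mean_angle_deg=float(wrap_angle_deg(np.degrees(np.angle(vec)))),
        n_tracks=len(ang),
    )


def angle_distribution(angles_deg: np.ndarray, n_bins: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Radial histogram of track angles over (−180, 180].

    Returns (counts, bin_edges); bins are half-open with the final
    bin closed at 180 so counts always sum to N.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    ang = wrap_angle_deg(np.asarray(angles_deg, float))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(ang, bins=edges)
    return counts, edges


def tracks_to_table(tracks: list[CellTrack]) -> pd.DataFrame:
    """Convert tracks to the standard track-table CSV schema."""
    rows = [
        (tid, s.frame, s.x_um, s.y_um)
        for tid, tr in enumerate(tracks)
        for s in tr.spots
    ]
    return validate_track_table(
        pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    )


def track_movie(
    seq: ImageSequence,
    expected_diameter_um: float = 8.0,
    quality_threshold: float = 0.02,
    max_link_distance_um: float = 5.0,
    min_track_len: int = 3,
    preprocess: bool = True,
    rolling_ball_radius_px: int = 20,
) -> tuple[list[CellTrack], dict]:
    """End-to-end tracking of a single-slice movie.

    Returns the tracks and a statistics dict (per-track angles, net
    displacements, path lengths, speeds, directionality R and mean
    angle).
    """
    work = (
        preprocess_for_tracking(seq, rolling_ball_radius_px) if preprocess else seq
    )
    spots_by_frame = [
        detect_spots(
            work.data[t, 0],
            seq.geometry,
            frame_index=t,
            expected_diameter_um=expected_diameter_um,
            quality_threshold=quality_threshold,
        )
        for t in range(work.n_frames)
    ]
    tracks = link_spots_lap(spots_by_frame, max_link_distance_um)
    kept = [t for t in tracks if len(t) >= min_track_len]
    metrics = [track_metrics(t, seq.geometry.dt) for t in kept]
    stats: dict = {
        "n_tracks": len(kept),
        "angles_deg": [m[0] for m in metrics],
        "net_displacements_um": [m[1] for m in metrics],
        "path_lengths_um": [m[2] for m in metrics],
        "speeds_um_per_min": [m[3] for m in metrics],
    }
    if kept:
        direction = directionality_index(kept, seq.geometry.dt, min_track_len)
        stats["resultant_length"] = direction.resultant_length
        stats["mean_angle_deg"] = direction.mean_angle_deg
    return kept, stats
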