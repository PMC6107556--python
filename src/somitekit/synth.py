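"""Ground-truthed synthetic 4D membrane-labelled tissue.

Emulates two-photon movies of memGFP somite tissue: packed cells with
bright membrane outlines, random / sink-directed / inward motion at
µm-per-minute scale, transient rounded dividing cells, and linear
volume growth — together with the true tracks, division times and
volumes needed to score every pipeline stage against a known answer.

All randomness flows through a single integer seed; identical seeds
produce bit-identical images and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .io import (
    ImageSequence,
    VoxelGeometry,
    read_tracks,
    validate_track_table,
    write_tracks,
)

__all__ = [
    "MotionModel",
    "TissueModel",
    "GroundTruth",
    "generate_cell_packing",
    "simulate_motion",
    "simulate_divisions",
    "render_membrane_frame",
    "render_membrane_plane",
    "render_solid_sphere",
    "simulate_movie",
    "export_ground_truth",
    "load_ground_truth",
    "stage_preset",
    "STAGE_PRESETS",
]

#: Rendered diameter of a rounding (dividing) cell, µm. Dividing cells
#: appear as large bright filled disks for ~25 min before splitting.
ROUNDED_DIAMETER_UM = 14.0

#: Membrane shell thickness, µm.
SHELL_THICKNESS_UM = 0.5


@dataclass(frozen=True)
class MotionModel:
    """Per-step cell motion model.

    Step magnitudes are drawn from a Normal(mean_speed·dt, speed_sd·dt)
    truncated at zero. Step directions depend on ``mode``:

    * ``random`` — uniform on the circle (early-stage-like motion);
    * ``directed`` — a ``drift_weight``-weighted mix of the unit vector
      toward ``sink`` and a uniform random unit vector, renormalized
      (mid-stage rostro-medial drift);
    * ``inward`` — as ``directed`` but with the sink at the domain
      centre (late-stage centripetal motion).
    """

    mode: str = "random"
    mean_speed: float = 0.14  # µm/min
    speed_sd: float = 0.08  # µm/min
    sink: tuple[float, float] | None = None
    drift_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "directed", "inward"):
            raise ValueError(f"unknown motion mode {self.mode!r}")
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if not 0.0 <= self.drift_weight <= 1.0:
            raise ValueError("drift_weight must lie in [0, 1]")
        if (self.sink is None) == (self.mode == "directed"):
            raise ValueError("sink must be given exactly when mode='directed'")


@dataclass(frozen=True)
class TissueModel:
    """Static tissue parameters for packing, division and growth.

    ``radius_*`` describe the main (small-cell) population; an optional
    second mixture component models the discretely larger cells seen in
    the medial somite domain. Division rate is for the simulated volume
    as a whole, in events per hour; each rounding phase lasts
    ``division_duration_min`` (about 25 minutes in somites) before the
    cell splits into two daughters of half volume.
    """

    domain_um: tuple[float, float, float] = (32.0, 41.0, 20.0)  # (x, y, z)
    n_cells: int = 212
    radius_mean_um: float = 1.5
    radius_sd_um: float = 0.15
    large_fraction: float = 0.0
    large_radius_mean_um: float = 3.0
    large_radius_sd_um: float = 0.3
    division_rate_per_hr: float = 0.0
    division_duration_min: float = 25.0
    growth_rate_um3_per_hr: float = 0.0
    proliferation_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if min(self.radius_mean_um, self.large_radius_mean_um) <= 0:
            raise ValueError("cell radii must be positive")
        if self.division_rate_per_hr < 0:
            raise ValueError("division rate must be non-negative")
        if not 0.0 <= self.large_fraction <= 1.0:
            raise ValueError("large_fraction must lie in [0, 1]")
        if not 0.0 <= self.proliferation_fraction <= 1.0:
            raise ValueError("proliferation_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Simulator truth: tracks, divisions, volumes and per-cell labels."""

    tracks: pd.DataFrame  # track_id, frame, x_um, y_um, z_um
    divisions: pd.DataFrame  # frame, t_min, cell_id, x_um, y_um, z_um
    frame_volumes: pd.DataFrame  # frame, t_min, total_volume_um3
    cell_volumes: pd.DataFrame  # frame, cell_id, radius_um, volume_um3
    seed: int = 0


def _sample_radii(tissue: TissueModel, n: int, rng: np.random.Generator) -> np.ndarray:
    is_large = rng.random(n) < tissue.large_fraction
    radii = rng.normal(tissue.radius_mean_um, tissue.radius_sd_um, n)
    radii[is_large] = rng.normal(
        tissue.large_radius_mean_um, tissue.large_radius_sd_um, is_large.sum()
    )
    return np.clip(radii, 0.2 * tissue.radius_mean_um, None)


def generate_cell_packing(
    tissue: TissueModel,
    seed: int,
    max_overlap_fraction: float = 0.1,
    max_tries_per_cell: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential packing of spheres into the tissue domain.

    Returns ``(centres, radii)`` with centres of shape (n, 3) in µm
    (x, y, z order). Any two spheres overlap by at most
    ``max_overlap_fraction`` of the smaller radius; spheres are kept
    fully inside the domain. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = tissue.domain_um
    radii = _sample_radii(tissue, tissue.n_cells, rng)
    centres = np.empty((tissue.n_cells, 3))
    for i in range(tissue.n_cells):
        r = radii[i]
        # margin keeps spheres inside the domain; in a thin-slab axis
        # (2r > extent) cells sit at the mid-plane instead
        lo_m = [min(r, lx / 2), min(r, ly / 2), min(r, lz / 2)]
        hi_m = [max(lx - r, lx / 2), max(ly - r, ly / 2), max(lz - r, lz / 2)]
        for _ in range(max_tries_per_cell):
            c = rng.uniform(lo_m, hi_m)
            if i == 0:
                break
            d = np.linalg.norm(centres[:i] - c, axis=1)
            min_gap = (radii[:i] + r) - max_overlap_fraction * np.minimum(radii[:i], r)
            if np.all(d >= min_gap):
                break
        else:
            raise RuntimeError(
                f"packing infeasible: placed {i}/{tissue.n_cells} cells "
                f"in {tissue.domain_um} µm domain"
            )
        centres[i] = c
    return centres, radii


def _truncated_step_lengths(
    mean: float, sd: float, size: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerate cases handled."""
    if mean == 0 and sd == 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_motion(
    centres: np.ndarray,
    motion: MotionModel,
    n_frames: int,
    domain_um: tuple[float, float, float],
    dt_min: float,
    seed: int,
) -> np.ndarray:
    """Simulate in-plane (x, y) cell motion; z is kept fixed.

    Returns positions of shape ``(n_frames, n_cells, 3)`` in µm. Cells
    are reflected at the domain boundary.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = np.random.default_rng(seed)
    centres = np.asarray(centres, float)
    n = len(centres)
    sink = np.asarray(
        motion.sink
        if motion.mode == "directed"
        else (domain_um[0] / 2, domain_um[1] / 2),
        float,
    )
    pos = np.empty((n_frames, n, 3))
    pos[0] = centres
    lengths = _truncated_step_lengths(
        motion.mean_speed * dt_min, motion.speed_sd * dt_min, (n_frames - 1, n), rng
    )
    for t in range(1, n_frames):
        phi = rng.uniform(-np.pi, np.pi, n)
        u = np.column_stack([np.cos(phi), np.sin(phi)])
        if motion.mode in ("directed", "inward") and motion.drift_weight > 0:
            to_sink = sink - pos[t - 1, :, :2]
            norm = np.linalg.norm(to_sink, axis=1, keepdims=True)
            to_sink = np.divide(to_sink, norm, out=np.zeros_like(to_sink), where=norm > 0)
            u = motion.drift_weight * to_sink + (1 - motion.drift_weight) * u
            norm = np.linalg.norm(u, axis=1, keepdims=True)
            u = np.divide(u, norm, out=np.zeros_like(u), where=norm > 0)
        step = u * lengths[t - 1][:, None]
        nxt = pos[t - 1].copy()
        nxt[:, :2] += step
        for ax in (0, 1):  # reflect at the domain walls
            L = domain_um[ax]
            nxt[:, ax] = np.abs(nxt[:, ax])
            over = nxt[:, ax] > L
            nxt[over, ax] = 2 * L - nxt[over, ax]
            nxt[:, ax] = np.clip(nxt[:, ax], 0, L)
        pos[t] = nxt
    return pos


def simulate_divisions(
    n_cells: int,
    rate_per_hr: float,
    duration_min: float,
    total_min: float,
    seed: int,
) -> pd.DataFrame:
    """Schedule division events as a homogeneous Poisson process.

    The event count over ``total_min`` is Poisson with mean
    ``rate_per_hr · total_min / 60``; event onsets are uniform in time
    and each event is assigned to a distinct random cell. Returns a
    DataFrame with columns ``t_min`` (rounding onset) and ``cell_id``.
    """
    if rate_per_hr < 0:
        raise ValueError("rate must be non-negative")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_events = int(rng.poisson(rate_per_hr * total_min / 60.0)) if rate_per_hr > 0 else 0
    n_events = min(n_events, n_cells)
    times = np.sort(rng.uniform(0.0, total_min, n_events))
    cells = rng.choice(n_cells, size=n_events, replace=False)
    return pd.DataFrame({"t_min": times, "cell_id": cells.astype(int)})


def _render_cells(
    shape_vox: tuple[int, ...],
    centres_vox: np.ndarray,
    radii_vox: np.ndarray,
    filled: np.ndarray,
    shell_half_vox: np.ndarray,
) -> np.ndarray:
    """Rasterize membrane shells (and filled rounded cells) at unit
    amplitude. Works in 2D and 3D; radii/shell widths are per-axis to
    honour anisotropic voxels."""
    img = np.zeros(shape_vox, float)
    ndim = len(shape_vox)
    for c, r, fill in zip(centres_vox, radii_vox, filled):
        # bounding box in voxels, per axis
        ext = r + shell_half_vox + 1
        lo = np.maximum(np.floor(c - ext).astype(int), 0)
        hi = np.minimum(np.ceil(c + ext).astype(int) + 1, shape_vox)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(
            *[np.arange(lo[ax], hi[ax]) for ax in range(ndim)], indexing="ij"
        )
        # normalized radial coordinate: 1.0 on the membrane mid-surface
        rho = np.sqrt(sum(((g - c[ax]) / r[ax]) ** 2 for ax, g in enumerate(grids)))
        half = np.mean(shell_half_vox / r)
        mask = rho <= 1 + half if fill else np.abs(rho - 1) <= half
        sub = tuple(slice(lo[ax], hi[ax]) for ax in range(ndim))
        img[sub] = np.maximum(img[sub], mask.astype(float))
    return img


def _apply_noise(
    img: np.ndarray, noise: dict | None, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise plus Gaussian read noise, parameterized by SNR.

    ``noise={"snr": s}``: unit-amplitude structures get shot noise from
    s² photons plus read noise of SD 0.5/s, giving a peak SNR ≥ s.
    """
    if not noise:
        return img
    snr = float(noise.get("snr", 10.0))
    if snr <= 0:
        raise ValueError("snr must be positive")
    photons = snr**2
    bg = float(noise.get("background", 0.05))
    out = rng.poisson((img + bg) * photons) / photons - bg
    out = out + rng.normal(0.0, 0.5 / snr, img.shape)
    return np.clip(out, 0.0, None)


def render_membrane_frame(
    centres_um: np.ndarray,
    radii_um: np.ndarray,
    domain_um: tuple[float, float, float],
    geometry: VoxelGeometry,
    rounded: np.ndarray | None = None,
    psf_sigma_um: float = 0.3,
    noise: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render one 3D ``(z, y, x)`` membrane-labelled frame.

    Each cell contributes a bright spherical shell of thickness
    ~0.5 µm at its boundary with a dark interior; cells flagged in
    ``rounded`` are drawn as filled bright spheres of diameter
    ~14 µm (a rounded mitotic cell). The frame is blurred with an
    isotropic Gaussian PSF of ``psf_sigma_um`` and corrupted with
    Poisson + Gaussian noise. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    centres_um = np.atleast_2d(np.asarray(centres_um, float))
    nvox = (
        max(1, int(round(domain_um[2] / geometry.dz))),
        max(1, int(round(domain_um[1] / geometry.dy))),
        max(1, int(round(domain_um[0] / geometry.dx))),
    )
    scale = np.array([geometry.dz, geometry.dy, geometry.dx])
    n = len(centres_um)
    if n == 0:
        img = np.zeros(nvox)
        return _apply_noise(img, noise, rng)
    rounded = np.zeros(n, bool) if rounded is None else np.asarray(rounded, bool)
    radii_eff = np.where(rounded, ROUNDED_DIAMETER_UM / 2, np.asarray(radii_um, float))
    centres_vox = centres_um[:, ::-1] / scale  # (x,y,z) µm -> (z,y,x) vox
    radii_vox = radii_eff[:, None] / scale[None, :]
    shell_half_vox = (SHELL_THICKNESS_UM / 2) / scale
    img = _render_cells(nvox, centres_vox, radii_vox, rounded, shell_half_vox)
    if psf_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=psf_sigma_um / scale)
    return _apply_noise(img, noise, rng)


def render_membrane_plane(
    centres_um: np.ndarray,
    radii_um: np.ndarray,
    domain_um: tuple[float, float],
    geometry: VoxelGeometry,
    rounded: np.ndarray | None = None,
    psf_sigma_um: float = 0.3,
    noise: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render one 2D ``(y, x)`` dorsal-plane frame (thin-z imaging).

    Cells appear as bright rings (membrane cross-sections); rounded
    dividing cells as filled bright disks. Used for tracking- and
    division-detection movies where the measurement plane is a single
    z slice.
    """
    rng = np.random.default_rng(seed)
    centres_um = np.atleast_2d(np.asarray(centres_um, float))[:, :2]
    npx = (
        max(1, int(round(domain_um[1] / geometry.dy))),
        max(1, int(round(domain_um[0] / geometry.dx))),
    )
    scale = np.array([geometry.dy, geometry.dx])
    n = len(centres_um)
    if n == 0:
        return _apply_noise(np.zeros(npx), noise, rng)
    rounded = np.zeros(n, bool) if rounded is None else np.asarray(rounded, bool)
    radii_eff = np.where(rounded, ROUNDED_DIAMETER_UM / 2, np.asarray(radii_um, float))
    centres_px = centres_um[:, ::-1] / scale
    radii_px = radii_eff[:, None] / scale[None, :]
    shell_half_px = (SHELL_THICKNESS_UM / 2) / scale
    img = _render_cells(npx, centres_px, radii_px, rounded, shell_half_px)
    if psf_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=psf_sigma_um / scale)
    return _apply_noise(img, noise, rng)


def render_solid_sphere(
    volume_um3: float,
    geometry: VoxelGeometry,
    margin_um: float = 4.0,
    psf_sigma_um: float = 0.3,
    noise: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render a filled bright sphere of the given true volume.

    Emulates a low-magnification view of a near-spherical structure
    (whole somite or somitocoel) for perimeter-based volume
    measurement. Returns a 3D ``(z, y, x)`` stack with the sphere
    centred; the central z slice passes through the equator.
    """
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    rng = np.random.default_rng(seed)
    r = (3 * volume_um3 / (4 * np.pi)) ** (1 / 3)
    ext = r + margin_um
    nvox = np.array(
        [
            int(np.ceil(2 * ext / geometry.dz)) | 1,  # odd so a slice hits centre
            int(np.ceil(2 * ext / geometry.dy)) | 1,
            int(np.ceil(2 * ext / geometry.dx)) | 1,
        ]
    )
    scale = np.array([geometry.dz, geometry.dy, geometry.dx])
    centre = (nvox - 1) / 2.0
    grids = np.meshgrid(*[np.arange(nv) for nv in nvox], indexing="ij")
    rho = np.sqrt(sum(((g - centre[ax]) * scale[ax]) ** 2 for ax, g in enumerate(grids)))
    img = (rho <= r).astype(float)
    if psf_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=psf_sigma_um / scale)
    return _apply_noise(img, noise, rng)


def _sphere_volume(r: np.ndarray) -> np.ndarray:
    return 4.0 / 3.0 * np.pi * np.asarray(r, float) ** 3


@dataclass
class _SimCell:
    cell_id: int
    pos: np.ndarray  # (x, y, z) µm
    radius: float
    alive_from: int = 0


def simulate_movie(
    tissue: TissueModel,
    motion: MotionModel,
    n_frames: int,
    geometry: VoxelGeometry,
    seed: int,
    render: str | None = "plane",
    psf_sigma_um: float = 0.3,
    noise: dict | None = None,
    division_margin_um: float = 8.0,
) -> tuple[ImageSequence | None, GroundTruth]:
    """Simulate a full movie: packing, motion, divisions, growth, render.

    ``render`` is ``"plane"`` (2D dorsal plane per frame, stored as a
    one-slice stack), ``"volume"`` (full 3D render) or ``None``
    (ground truth only). Dividing cells round up for
    ``division_duration_min``, then split into two daughters of half
    volume; total true volume follows
    ``V0 + growth_rate_um3_per_hr · t`` by uniform radial growth.
    Division events are kept ``division_margin_um`` away from the x/y
    field edges so the rounding phase is fully in view.

    Returns the rendered :class:`~somitekit.io.ImageSequence` (or
    ``None``) and the :class:`GroundTruth`.
    """
    rng_master = np.random.default_rng(seed)
    s_pack, s_motion, s_div, s_render = rng_master.integers(0, 2**31 - 1, 4)
    centres, radii = generate_cell_packing(tissue, int(s_pack))
    pos = simulate_motion(
        centres, motion, n_frames, tissue.domain_um, geometry.dt, int(s_motion)
    )
    total_min = (n_frames - 1) * geometry.dt
    schedule = simulate_divisions(
        tissue.n_cells,
        tissue.division_rate_per_hr,
        tissue.division_duration_min,
        max(total_min, geometry.dt),
        int(s_div),
    )

    lx, ly, _ = tissue.domain_um
    rng_div = np.random.default_rng(int(s_div) + 1)

    cells: list[_SimCell] = [
        _SimCell(i, pos[0, i].copy(), radii[i]) for i in range(tissue.n_cells)
    ]
    next_id = tissue.n_cells
    # per-frame state
    track_rows: list[tuple] = []
    division_rows: list[tuple] = []
    volume_rows: list[tuple] = []
    cellvol_rows: list[tuple] = []
    frames: list[np.ndarray] = []

    v0 = float(_sphere_volume(radii).sum())
    onset_by_frame: dict[int, list[int]] = {}
    for t_min, cell_id in schedule.itertuples(index=False):
        f = int(np.floor(t_min / geometry.dt))
        onset_by_frame.setdefault(min(f, n_frames - 1), []).append(int(cell_id))
    rounding_until: dict[int, int] = {}  # cell_id -> last rounded frame
    offsets: dict[int, np.ndarray] = {}  # daughter displacement per mother
    dur_frames = max(1, int(np.ceil(tissue.division_duration_min / geometry.dt)))

    # map original cell_id -> index into pos columns for motion lookup
    motion_col = {i: i for i in range(tissue.n_cells)}

    for f in range(n_frames):
        t_min_f = f * geometry.dt
        # motion update: move each cell by its column's frame-to-frame step
        if f > 0:
            for c in cells:
                col = motion_col[c.cell_id]
                c.pos[:2] += pos[f, col, :2] - pos[f - 1, col, :2]
                c.pos[0] = min(max(c.pos[0], 0.0), lx)
                c.pos[1] = min(max(c.pos[1], 0.0), ly)
        # division onsets scheduled for this frame; if the scheduled
        # cell sits too close to the field edge or to another rounding
        # cell, the event is reassigned to an eligible cell so every
        # rounding phase is fully in view and spatially distinct
        for cid in onset_by_frame.get(f, ()):
            rounding_pos = [
                c.pos for c in cells if c.cell_id in rounding_until
            ]

            def _eligible(c: _SimCell) -> bool:
                if c.cell_id in rounding_until:
                    return False
                if not (
                    division_margin_um <= c.pos[0] <= lx - division_margin_um
                    and division_margin_um <= c.pos[1] <= ly - division_margin_um
                ):
                    return False
                return all(
                    np.hypot(c.pos[0] - p[0], c.pos[1] - p[1])
                    >= 1.5 * ROUNDED_DIAMETER_UM
                    for p in rounding_pos
                )

            cell = next((c for c in cells if c.cell_id == cid), None)
            if cell is None or not _eligible(cell):
                pool = [c for c in cells if _eligible(c)]
                if not pool:
                    continue
                cell = pool[int(rng_div.integers(len(pool)))]
            rounding_until[cell.cell_id] = f + dur_frames - 1
            division_rows.append((f, t_min_f, cell.cell_id, *cell.pos))
        # split cells whose rounding phase ended before this frame
        done = [cid for cid, last in rounding_until.items() if f > last]
        for cid in done:
            del rounding_until[cid]
            cell = next((c for c in cells if c.cell_id == cid), None)
            if cell is None:
                continue
            cells.remove(cell)
            r_d = cell.radius / 2 ** (1 / 3)  # half volume each
            direction = rng_div.normal(size=2)
            direction /= max(np.linalg.norm(direction), 1e-12)
            off = np.array([*(direction * r_d), 0.0])
            for sgn in (+1.0, -1.0):
                d = _SimCell(next_id, cell.pos + sgn * off, r_d, alive_from=f)
                d.pos[0] = min(max(d.pos[0], 0.0), lx)
                d.pos[1] = min(max(d.pos[1], 0.0), ly)
                motion_col[next_id] = motion_col[cid]
                cells.append(d)
                next_id += 1
        # uniform radial growth so total volume tracks the linear model
        target_v = v0 + tissue.growth_rate_um3_per_hr * t_min_f / 60.0
        cur_v = float(_sphere_volume([c.radius for c in cells]).sum())
        if cur_v > 0 and tissue.growth_rate_um3_per_hr != 0:
            s = (target_v / cur_v) ** (1 / 3)
            for c in cells:
                c.radius *= s
            cur_v = target_v
        volume_rows.append((f, t_min_f, cur_v))
        for c in cells:
            track_rows.append((c.cell_id, f, c.pos[0], c.pos[1], c.pos[2]))
            cellvol_rows.append((f, c.cell_id, c.radius, float(_sphere_volume(c.radius))))
        if render is not None:
            cen = np.array([c.pos for c in cells])
            rad = np.array([c.radius for c in cells])
            flag = np.array([c.cell_id in rounding_until for c in cells])
            frame_seed = int(s_render) + f
            if render == "plane":
                img = render_membrane_plane(
                    cen, rad, tissue.domain_um[:2], geometry, flag,
                    psf_sigma_um, noise, frame_seed,
                )[None]  # one-slice stack
            elif render == "volume":
                img = render_membrane_frame(
                    cen, rad, tissue.domain_um, geometry, flag,
                    psf_sigma_um, noise, frame_seed,
                )
            else:
                raise ValueError(f"unknown render mode {render!r}")
            frames.append(img)

    tracks = validate_track_table(
        pd.DataFrame(track_rows, columns=["track_id", "frame", "x_um", "y_um", "z_um"])
    )
    gt = GroundTruth(
        tracks=tracks,
        divisions=pd.DataFrame(
            division_rows, columns=["frame", "t_min", "cell_id", "x_um", "y_um", "z_um"]
        ),
        frame_volumes=pd.DataFrame(
            volume_rows, columns=["frame", "t_min", "total_volume_um3"]
        ),
        cell_volumes=pd.DataFrame(
            cellvol_rows, columns=["frame", "cell_id", "radius_um", "volume_um3"]
        ),
        seed=seed,
    )
    seq = None
    if render is not None:
        seq = ImageSequence(np.stack(frames), geometry)
    return seq, gt


def export_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    """Write ground truth as CSVs (tracks/divisions/volumes/cells)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tracks(gt.tracks, out / "tracks.csv")
    gt.divisions.to_csv(out / "divisions.csv", index=False)
    gt.frame_volumes.to_csv(out / "frame_volumes.csv", index=False)
    gt.cell_volumes.to_csv(out / "cell_volumes.csv", index=False)
    pd.DataFrame({"seed": [gt.seed]}).to_csv(out / "meta.csv", index=False)


def load_ground_truth(in_dir: str | Path) -> GroundTruth:
    """Reload ground truth written by :func:`export_ground_truth`."""
    p = Path(in_dir)
    return GroundTruth(
        tracks=read_tracks(p / "tracks.csv"),
        divisions=pd.read_csv(p / "divisions.csv", float_precision="round_trip"),
        frame_volumes=pd.read_csv(p / "frame_volumes.csv", float_precision="round_trip"),
        cell_volumes=pd.read_csv(p / "cell_volumes.csv", float_precision="round_trip"),
        seed=int(pd.read_csv(p / "meta.csv")["seed"][0]),
    )


def stage_preset(stage: str, domain_um: tuple[float, float, float]) -> dict:
    """Motion and proliferation regime for a developmental stage.

    Reproduces the study's qualitative regimes: slow random motion and
    moderate proliferation early; faster motion directed toward the
    rostro-medial corner and high proliferation at mid stage; slow
    inward motion and very low proliferation late. Speeds follow the
    reported 0.14 / 0.21 / 0.06 µm min⁻¹ (SD 0.08 / 0.11 / 0.03) and
    division rates the reported 1.7 / 4.4 / 0.3 cells hr⁻¹.

    In the package's dorsal-view convention +x is lateral→medial and
    +y caudal→rostral, so the mid-stage sink lies beyond the (+x, +y)
    corner; it is placed well outside the domain so the flow across
    the field is quasi-parallel (cells head toward the rostro-medial
    quadrant rather than converging on a point inside the field).
    """
    lx, ly = domain_um[0], domain_um[1]
    presets = {
        "early": {
            "motion": MotionModel(mode="random", mean_speed=0.14, speed_sd=0.08),
            "division_rate_per_hr": 1.7,
        },
        "mid": {
            "motion": MotionModel(
                mode="directed", mean_speed=0.21, speed_sd=0.11,
                sink=(3 * lx, 3 * ly), drift_weight=0.7,
            ),
            "division_rate_per_hr": 4.4,
        },
        "late": {
            "motion": MotionModel(
                mode="inward", mean_speed=0.06, speed_sd=0.03, drift_weight=0.5
            ),
            "division_rate_per_hr": 0.3,
        },
    }
    if stage not in presets:
        raise ValueError(f"unknown stage {stage!r}")
    return presets[stage]


STAGE_PRESETS = ("early", "mid", "late")
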