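"""Morphological change as pixel-wise image correlation.

Two slices of the same somite taken 180 minutes apart are compared
pixel by pixel: every pixel contributes an (intensity at t0, intensity
at t1) pair and the Pearson correlation of those pairs measures how
much the tissue has changed — identical images give r = 1, heavily
rearranged tissue drives r toward 0. The time course is evaluated at
dorsal, centre and ventral depths to resolve change through the
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ImageSequence

__all__ = [
    "CorrelationResult",
    "pearson_image_correlation",
    "correlation_timecourse",
    "DEPTH_LABELS",
]

DEPTH_LABELS = ("dorsal", "centre", "ventral")


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between two time points at one imaging depth."""

    depth_label: str
    depth_fraction: float
    z_index: int
    t0_min: float
    t1_min: float
    r: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.t1_min <= self.t0_min:
            raise ValueError("t1 must be later than t0")


def pearson_image_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally shaped images, pixel by pixel.

    Invariant under positive affine intensity transforms and symmetric
    in its arguments; r(A, A) = 1 for any non-constant A.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    av, bv = a.ravel(), b.ravel()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("correlation undefined for a constant image")
    r = float(np.corrcoef(av, bv)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def correlation_timecourse(
    seq: ImageSequence,
    depth_fractions: Sequence[float] = (0.25, 0.5, 0.75),
    t0_min: float = 0.0,
    t1_min: float = 180.0,
    mask: np.ndarray | None = None,
) -> list[CorrelationResult]:
    """Correlate the t0 and t1 slices at the given depth fractions.

    Depth fractions (0 = dorsal surface, 1 = ventral-most slice) are
    resolved to the nearest z slice. An optional boolean ``mask``
    restricts the comparison to somite pixels; by default the whole
    slice is used, matching the raw overlay measurement. No drift
    correction is applied.
    """
    dt = seq.geometry.dt
    f0, f1 = int(round(t0_min / dt)), int(round(t1_min / dt))
    if not 0 <= f0 < seq.n_frames or not 0 <= f1 < seq.n_frames:
        raise ValueError(
            f"time points {t0_min}, {t1_min} min map to frames {f0}, {f1} "
            f"outside [0, {seq.n_frames})"
        )
    if f1 <= f0:
        raise ValueError("t1 must map to a later frame than t0")
    results = []
    for i, frac in enumerate(depth_fractions):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"depth fraction {frac} outside [0, 1]")
        z = int(round(frac * (seq.n_slices - 1)))
        a, b = seq.data[f0, z], seq.data[f1, z]
        if mask is not None:
            a, b = a[mask], b[mask]
        label = DEPTH_LABELS[i] if len(depth_fractions) == 3 else f"depth_{frac:g}"
        results.append(
            CorrelationResult(
                depth_label=label,
                depth_fraction=float(frac),
                z_index=z,
                t0_min=f0 * dt,
                t1_min=f1 * dt,
                r=pearson_image_correlation(a, b),
            )
        )
    return results
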