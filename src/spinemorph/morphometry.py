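"""Per-structure height measurement and the Disc Height Index (DHI).

For one spinal level the DHI is the dimensionless ratio

    DHI = 2 * IVD height / (cranial VB height + caudal VB height)

where the three heights are measured along a *local level axis*: the unit
direction from the cranial vertebral-body centroid to the caudal one. Using a
local axis rather than the image vertical makes the measurement robust to
lordotic curvature and to global image rotation.

The height of a structure along an axis is its mean chord length: member
pixel centres are rotated into the axis frame (u along the axis, v across),
binned across v at the pixel pitch, and the per-bin chord length is
``count * pixel_area / bin_width``. Bins whose centre lies in the central 80%
of the occupied v-extent are averaged, which suppresses endplate curvature
and corner effects; the statistic is exact for axis-aligned rectangles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, MissingStructureError
from .mask_io import LEVELS, LabelMask

logger = logging.getLogger(__name__)

#: fraction of the cross-axis extent kept when averaging chords
CENTRAL_FRACTION = 0.8


@dataclass(frozen=True)
class LevelAxis:
    """Measurement direction for one disc level, in mm coordinates."""

    level: str
    unit_vector: tuple[float, float]  # (d_row, d_col), unit norm
    cranial_vb: str
    caudal_vb: str


@dataclass(frozen=True)
class HeightMeasurement:
    structure: str
    height_mm: float
    axis: LevelAxis
    n_chords: int


@dataclass(frozen=True)
class DHIRecord:
    """Heights (mm) and DHI for one level; ``complete`` is False when any of
    the three structures is missing, in which case ``dhi`` is NaN."""

    level: str
    ivd_height_mm: float
    cranial_vb_height_mm: float
    caudal_vb_height_mm: float
    dhi: float
    complete: bool


def _member_coords_mm(mask: LabelMask, structure: str) -> np.ndarray:
    """(n, 2) mm coordinates of member-pixel centres; raises when absent."""
    rows, cols = np.nonzero(mask.structure_pixels(structure))
    if rows.size == 0:
        raise MissingStructureError(structure)
    sr, sc = mask.spacing_mm
    return np.column_stack([rows * sr, cols * sc]).astype(np.float64)


def centroid_mm(mask: LabelMask, structure: str) -> tuple[float, float]:
    """Arithmetic mean of member-pixel centres, in mm (row, col) coordinates."""
    xy = _member_coords_mm(mask, structure)
    c = xy.mean(axis=0)
    return (float(c[0]), float(c[1]))


def level_axis(mask: LabelMask, level: str) -> LevelAxis:
    """Unit vector from the cranial to the caudal vertebral-body centroid."""
    for lvl, cranial, caudal in LEVELS:
        if lvl == level:
            break
    else:
        raise KeyError(f"unknown disc level {level!r}")
    p_cr = np.array(centroid_mm(mask, cranial))
    p_ca = np.array(centroid_mm(mask, caudal))
    d = p_ca - p_cr
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise DegenerateGeometryError(
            f"coincident centroids for {cranial} and {caudal}; no axis for {level}"
        )
    u = d / norm
    return LevelAxis(level, (float(u[0]), float(u[1])), cranial, caudal)


def measure_height(mask: LabelMask, structure: str, axis: LevelAxis) -> HeightMeasurement:
    """Mean chord length of ``structure`` along ``axis``, in mm.

    Bin width is the smaller spacing component, which avoids aliasing under
    anisotropic spacing. Bins with centres outside the central 80% of the
    occupied cross-axis extent are trimmed before averaging.
    """
    xy = _member_coords_mm(mask, structure)
    u = np.array(axis.unit_vector, dtype=np.float64)
    v_dir = np.array([-u[1], u[0]])
    v = xy @ v_dir
    bin_width = float(min(mask.spacing_mm))
    pixel_area = float(mask.spacing_mm[0] * mask.spacing_mm[1])

    v_min, v_max = float(v.min()), float(v.max())
    # epsilon-tolerant floor: pixels landing a rounding error below a bin
    # edge must not split off into a phantom bin
    idx = np.floor((v - v_min) / bin_width + 1e-9).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    centers = v_min + (np.arange(n_bins) + 0.5) * bin_width

    margin = (1.0 - CENTRAL_FRACTION) / 2.0 * (v_max - v_min)
    keep = (counts > 0) & (centers >= v_min + margin) & (centers <= v_max - margin)
    if not np.any(keep):
        # extremely thin structures: fall back to all occupied bins
        keep = counts > 0
    if not np.any(keep):
        raise DegenerateGeometryError(f"no eligible chord bins for {structure}")
    chords = counts[keep] * pixel_area / bin_width
    return HeightMeasurement(
        structure=structure,
        height_mm=float(chords.mean()),
        axis=axis,
        n_chords=int(keep.sum()),
    )


def compute_dhi(mask: LabelMask, level: str) -> DHIRecord:
    """DHI record for one level; incomplete (never raising) when the disc or
    either adjacent vertebral body is absent."""
    for lvl, cranial, caudal in LEVELS:
        if lvl == level:
            break
    else:
        raise KeyError(f"unknown disc level {level!r}")

    missing = [s for s in (level, cranial, caudal) if not mask.structure_pixels(s).any()]
    if missing:
        logger.info("level %s incomplete; missing structures: %s", level, ", ".join(missing))
        return DHIRecord(level, np.nan, np.nan, np.nan, np.nan, complete=False)

    axis = level_axis(mask, level)
    ivd = measure_height(mask, level, axis).height_mm
    cr = measure_height(mask, cranial, axis).height_mm
    ca = measure_height(mask, caudal, axis).height_mm
    if cr + ca == 0.0:
        raise DegenerateGeometryError(
            f"zero summed vertebral-body height at {level}; DHI undefined"
        )
    return DHIRecord(level, ivd, cr, ca, 2.0 * ivd / (cr + ca), complete=True)


def compute_all_dhi(mask: LabelMask) -> list[DHIRecord]:
    """DHI records for L1/2..L5/S1 in cranio-caudal order (always 5 records;
    per-level completeness flags are independent)."""
    return [compute_dhi(mask, lvl) for lvl, _, _ in LEVELS]
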