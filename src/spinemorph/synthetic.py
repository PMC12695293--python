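"""Parametric sagittal lumbar-spine phantoms with analytic ground truth.

A phantom is a stack of six vertebral bodies (rounded rectangles) separated
by five disc rectangles, drawn onto a label grid with physical spacing. Each
successive structure can be tilted so the stack curves like a lordotic lumbar
spine. The analytic structure heights and per-level DHI come straight from
the generating parameters — never from re-measuring the raster — so they are
an oracle independent of the morphometry code under test.

A rater-style perturbation model (smoothed boundary jitter plus a systematic
dilation/erosion bias) turns one phantom into a simulated second annotator,
which exercises the agreement suite end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import PhantomGeometryError
from .mask_io import (
    DISCS,
    LEVELS,
    STRUCTURES,
    VERTEBRAL_BODIES,
    GrayImage,
    LabelMask,
    SpineLabelScheme,
)

#: corner radius = min(VB_CORNER_FRACTION * height, VB_CORNER_DEPTH_CAP * depth).
#: The depth cap keeps the rounding inside the 10% cross-axis trim margin of
#: the chord-mean height statistic, so axis-aligned phantom heights stay exact.
VB_CORNER_FRACTION = 0.15
VB_CORNER_DEPTH_CAP = 0.09


@dataclass(frozen=True)
class SpinePhantomSpec:
    """Geometry of one phantom; defaults mimic an adult lumbar spine on a
    mid-sagittal 0.5 mm slice (heights and depths in mm)."""

    shape: tuple[int, int] = (512, 512)
    spacing_mm: tuple[float, float] = (0.5, 0.5)
    vb_heights_mm: tuple[float, ...] = (27.0, 28.0, 29.0, 29.0, 28.0, 30.0)
    vb_depths_mm: tuple[float, ...] = (32.0, 33.0, 34.0, 35.0, 35.0, 33.0)
    disc_heights_mm: tuple[float, ...] = (8.0, 9.0, 10.0, 10.5, 9.0)
    disc_depth_ratio: float = 0.9
    inter_level_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.vb_heights_mm) != 6 or len(self.vb_depths_mm) != 6:
            raise ValueError("need 6 vertebral-body heights and depths (L1..S1)")
        if len(self.disc_heights_mm) != 5:
            raise ValueError("need 5 disc heights (L1/2..L5/S1)")
        vals = (*self.vb_heights_mm, *self.vb_depths_mm, *self.disc_heights_mm)
        if any(v <= 0 for v in vals) or not (0 < self.disc_depth_ratio <= 1):
            raise ValueError("heights, depths and disc_depth_ratio must be positive")
        if not -30.0 < self.inter_level_angle_deg < 30.0:
            raise ValueError("inter_level_angle_deg must lie in (-30, 30)")

    @classmethod
    def sample(cls, seed: int, **overrides) -> "SpinePhantomSpec":
        """Draw a realistic random phantom (heights, depths, curvature)."""
        rng = np.random.default_rng(seed)
        params = dict(
            vb_heights_mm=tuple(rng.uniform(24.0, 32.0, 6).round(1)),
            vb_depths_mm=tuple(rng.uniform(30.0, 38.0, 6).round(1)),
            disc_heights_mm=tuple(rng.uniform(6.0, 12.0, 5).round(1)),
            inter_level_angle_deg=float(rng.uniform(0.0, 10.0)),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "shape": list(self.shape),
                    "spacing_mm": list(self.spacing_mm),
                    "vb_heights_mm": list(self.vb_heights_mm),
                    "vb_depths_mm": list(self.vb_depths_mm),
                    "disc_heights_mm": list(self.disc_heights_mm),
                    "disc_depth_ratio": self.disc_depth_ratio,
                    "inter_level_angle_deg": self.inter_level_angle_deg,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SpinePhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            shape=tuple(d.get("shape", (512, 512))),
            spacing_mm=tuple(d.get("spacing_mm", (0.5, 0.5))),
            vb_heights_mm=tuple(d["vb_heights_mm"]),
            vb_depths_mm=tuple(d["vb_depths_mm"]),
            disc_heights_mm=tuple(d["disc_heights_mm"]),
            disc_depth_ratio=float(d.get("disc_depth_ratio", 0.9)),
            inter_level_angle_deg=float(d.get("inter_level_angle_deg", 0.0)),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic heights (mm) and DHI per level, straight from the spec."""

    structure_heights_mm: dict[str, float]
    dhi: dict[str, float]

    @classmethod
    def from_spec(cls, spec: SpinePhantomSpec) -> "GroundTruth":
        heights = dict(zip(VERTEBRAL_BODIES, spec.vb_heights_mm))
        heights.update(zip(DISCS, spec.disc_heights_mm))
        dhi = {
            lvl: 2.0 * heights[lvl] / (heights[cr] + heights[ca])
            for lvl, cr, ca in LEVELS
        }
        return cls(heights, dhi)


@dataclass(frozen=True)
class RaterPerturbSpec:
    """Simulated annotator variability: smoothed Gaussian boundary jitter of
    scale ``boundary_sd_px`` plus a uniform boundary shift ``bias_px``
    (positive dilates, negative erodes). Zero jitter and zero bias is the
    identity."""

    boundary_sd_px: float = 1.0
    bias_px: float = 0.0
    noise_smoothing_px: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.boundary_sd_px < 0 or self.noise_smoothing_px <= 0:
            raise ValueError("boundary_sd_px must be >= 0 and smoothing > 0")


def _structure_plan(spec: SpinePhantomSpec):
    """Ordered (name, height, depth, corner_radius) along the spine."""
    plan = []
    for i in range(6):
        h, w = spec.vb_heights_mm[i], spec.vb_depths_mm[i]
        r = min(VB_CORNER_FRACTION * h, VB_CORNER_DEPTH_CAP * w)
        plan.append((VERTEBRAL_BODIES[i], h, w, r))
        if i < 5:
            dw = spec.disc_depth_ratio * 0.5 * (spec.vb_depths_mm[i] + spec.vb_depths_mm[i + 1])
            plan.append((DISCS[i], spec.disc_heights_mm[i], dw, 0.0))
    return plan


def generate_phantom(
    spec: SpinePhantomSpec, scheme: SpineLabelScheme | None = None
) -> tuple[LabelMask, GroundTruth]:
    """Rasterize the phantom and return it with its analytic ground truth.

    Structures are painted cranio-caudally; each structure boundary rotates
    the running direction by half the inter-level angle, so one full level
    (vertebral body + disc) accumulates the whole angle. Membership along the
    axis is half-open, so axis-aligned heights that are multiples of the row
    spacing rasterize to exact pixel counts. Raises
    :class:`PhantomGeometryError` when a structure's footprint leaves the
    grid.
    """
    scheme = scheme or SpineLabelScheme.default()
    rows, cols = spec.shape
    sr, sc = spec.spacing_mm
    grid_r, grid_c = np.meshgrid(
        np.arange(rows) * sr, np.arange(cols) * sc, indexing="ij"
    )
    pixels = np.zeros(spec.shape, dtype=np.int64)

    plan = _structure_plan(spec)
    half_step = np.deg2rad(spec.inter_level_angle_deg) / 2.0
    theta = 0.0
    # start near the top, horizontally centred, with a small margin
    p = np.array([0.06 * rows * sr, 0.5 * (cols - 1) * sc])
    extent = np.array([(rows - 1) * sr, (cols - 1) * sc])

    for name, h, w, radius in plan:
        d = np.array([np.cos(theta), np.sin(theta)])
        v_dir = np.array([-d[1], d[0]])
        center = p + d * (h / 2.0)

        for su in (-0.5, 0.5):
            for sv in (-0.5, 0.5):
                corner = center + d * (su * h) + v_dir * (sv * w)
                if np.any(corner < 0.0) or np.any(corner > extent):
                    raise PhantomGeometryError(
                        name, f"structure {name!r} leaves the grid at {corner}"
                    )

        U = (grid_r - center[0]) * d[0] + (grid_c - center[1]) * d[1]
        V = (grid_r - center[0]) * v_dir[0] + (grid_c - center[1]) * v_dir[1]
        inside = (U >= -h / 2) & (U < h / 2) & (V >= -w / 2) & (V < w / 2)
        if radius > 0.0:
            qx = np.abs(U) - (h / 2 - radius)
            qy = np.abs(V) - (w / 2 - radius)
            sdf = (
                np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
                + np.minimum(np.maximum(qx, qy), 0.0)
                - radius
            )
            inside &= sdf <= 0.0
        inside &= pixels == 0  # earlier structures win at tilted joints
        if not inside.any():
            raise PhantomGeometryError(name, f"structure {name!r} rasterized to nothing")
        pixels[inside] = scheme.code(name)

        p = p + d * h
        theta += half_step

    mask = LabelMask(pixels, spec.spacing_mm, scheme, source=f"phantom(seed={spec.seed})")
    return mask, GroundTruth.from_spec(spec)


def perturb_mask(mask: LabelMask, spec: RaterPerturbSpec) -> LabelMask:
    """Displace every structure boundary by smoothed seeded noise plus a
    uniform bias, emulating a second human annotator.

    Each structure's signed distance field (pixel units, negative inside) is
    thresholded at ``bias + noise``; contested pixels go to the structure
    whose displaced field is deepest, so codes never swap between structures.
    """
    if spec.boundary_sd_px == 0.0 and spec.bias_px == 0.0:
        return mask
    rng = np.random.default_rng(spec.seed)
    score = np.full(mask.shape, np.inf)
    out = np.zeros(mask.shape, dtype=np.int64)
    for name in STRUCTURES:
        m = mask.structure_pixels(name)
        if not m.any():
            continue
        d = ndimage.distance_transform_edt(~m) - ndimage.distance_transform_edt(m)
        if spec.boundary_sd_px > 0.0:
            noise = ndimage.gaussian_filter(
                rng.standard_normal(mask.shape), spec.noise_smoothing_px
            )
            noise *= spec.boundary_sd_px / noise.std()
        else:
            noise = 0.0
        s = d - spec.bias_px - noise
        # a structure may claim its own pixels or background, never pixels
        # of a sibling structure: codes must not swap between structures
        code = mask.scheme.code(name)
        claim = (s <= 0.0) & (s < score) & ((mask.pixels == 0) | (mask.pixels == code))
        out[claim] = mask.scheme.code(name)
        score = np.where(claim, s, score)
    return mask.with_pixels(out, source=f"{mask.source}|perturbed(seed={spec.seed})")


#: T2-like base intensities: fluid-rich discs bright, vertebral bodies mid,
#: background dark.
_BASE_INTENSITY = {"background": 30.0, "vb": 110.0, "disc": 220.0}


def generate_gray(mask: LabelMask, noise_sd: float = 0.0, seed: int = 0) -> GrayImage:
    """Piecewise-constant T2-like intensity image for a mask, plus seeded
    Gaussian noise of scale ``noise_sd``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = np.full(mask.shape, _BASE_INTENSITY["background"])
    for name in VERTEBRAL_BODIES:
        base[mask.structure_pixels(name)] = _BASE_INTENSITY["vb"]
    for name in DISCS:
        base[mask.structure_pixels(name)] = _BASE_INTENSITY["disc"]
    if noise_sd > 0:
        base = base + np.random.default_rng(seed).normal(0.0, noise_sd, mask.shape)
    return GrayImage(base, mask.spacing_mm, source=f"{mask.source}|gray")
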