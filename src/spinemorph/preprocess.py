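"""Image preprocessing operators used to harden segmentation across scanners.

Three operators act on grayscale sagittal images (and one of them on label
masks): percentile histogram clipping (default 0.5th/99.5th percentiles),
square median filtering (default kernel 11), and geometric scaling that
preserves physical extent by adjusting pixel spacing. A seeded composition of
the three serves as a reproducible augmentation sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .mask_io import GrayImage, LabelMask


@dataclass(frozen=True)
class PreprocessConfig:
    """Operator parameters.

    clip_lo_pct / clip_hi_pct
        Percentile bounds for histogram clipping (linear interpolation
        between order statistics).
    median_kernel
        Odd side length of the square median window; 1 is the identity.
    scale_range
        (min, max) multiplicative factor sampled by the augmentation.
    """

    clip_lo_pct: float = 0.5
    clip_hi_pct: float = 99.5
    median_kernel: int = 11
    scale_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.clip_lo_pct < self.clip_hi_pct <= 100.0):
            raise ValueError("need 0 <= clip_lo_pct < clip_hi_pct <= 100")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 1")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise ValueError("scale_range must be positive with min <= max")

    @classmethod
    def from_json_dict(cls, d: dict) -> "PreprocessConfig":
        kwargs = {}
        for key in ("clip_lo_pct", "clip_hi_pct", "median_kernel", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "scale_min" in d or "scale_max" in d:
            kwargs["scale_range"] = (d.get("scale_min", 0.8), d.get("scale_max", 1.2))
        return cls(**kwargs)


def clip_histogram(image: GrayImage, cfg: PreprocessConfig = PreprocessConfig()) -> GrayImage:
    """Clamp intensities to the [lo, hi] percentile bounds of the image.

    Percentiles use linear interpolation between order statistics (rank
    ``p/100 * (n - 1)``). Idempotent and monotone; a constant image is
    unchanged.
    """
    lo, hi = np.percentile(image.pixels, [cfg.clip_lo_pct, cfg.clip_hi_pct])
    return replace(image, pixels=np.clip(image.pixels, lo, hi))


def median_filter(image: GrayImage, cfg: PreprocessConfig = PreprocessConfig()) -> GrayImage:
    """Square median filter of side ``cfg.median_kernel`` with reflected
    (edge-repeating) boundary handling; shape preserved."""
    if cfg.median_kernel % 2 == 0:
        raise ValueError("median kernel must be odd")
    out = ndimage.median_filter(image.pixels, size=cfg.median_kernel, mode="reflect")
    return replace(image, pixels=out)


def geometric_scale(item, factor: float):
    """Resample to round(dim * factor) pixels per axis, dividing the spacing
    by the factor so the physical field of view is (near-)preserved.

    Grayscale images use bilinear interpolation; label masks use
    nearest-neighbour so the emitted label set is a subset of the input's.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    rows, cols = item.pixels.shape
    new_shape = (int(round(rows * factor)), int(round(cols * factor)))
    if new_shape[0] < 1 or new_shape[1] < 1:
        raise ValueError(f"scale factor {factor} collapses the grid to {new_shape}")
    new_spacing = (item.spacing_mm[0] / factor, item.spacing_mm[1] / factor)
    if isinstance(item, LabelMask):
        out = resize(
            item.pixels.astype(np.float64), new_shape, order=0,
            preserve_range=True, anti_aliasing=False,
        ).astype(np.int64)
        return LabelMask(out, new_spacing, item.scheme, source=item.source)
    if isinstance(item, GrayImage):
        out = resize(item.pixels, new_shape, order=1, preserve_range=True, anti_aliasing=False)
        return GrayImage(out, new_spacing, source=item.source)
    raise TypeError(f"expected GrayImage or LabelMask, got {type(item).__name__}")


def sample_augmentation(
    image: GrayImage, cfg: PreprocessConfig, seed: int | None = None
) -> GrayImage:
    """One seeded draw of the augmentation pipeline.

    Composition: percentile clip, then a blend toward the median-filtered
    image with a uniformly drawn weight (the seeded stand-in for the filter
    stage's slight random intensity variation), then a geometric scale drawn
    uniformly from ``cfg.scale_range``. Deterministic for a fixed seed; with
    ``median_kernel=1`` and ``scale_range=(1, 1)`` it degenerates to the clip
    alone.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = clip_histogram(image, cfg)
    w = float(rng.uniform(0.0, 1.0))
    if cfg.median_kernel > 1:
        med = median_filter(out, cfg)
        out = replace(out, pixels=(1.0 - w) * out.pixels + w * med.pixels)
    lo, hi = cfg.scale_range
    factor = float(rng.uniform(lo, hi))
    if factor != 1.0:
        out = geometric_scale(out, factor)
    return out
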