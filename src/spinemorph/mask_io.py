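"""Reading, writing and validating level-labeled lumbar spine masks.

A :class:`LabelMask` is a 2D integer grid in which each nonzero code names one
of the eleven mid-sagittal lumbar structures: vertebral bodies L1..S1 and
intervertebral discs L1/2..L5/S1. Physical pixel spacing travels with the
grid, so downstream morphometry is computed in millimetres and anisotropic
acquisitions are handled correctly by construction.

Supported on-disk formats are single-channel PNG (8/16-bit, no spacing
metadata) and NIfTI-1 (spacing taken from the header). For 3D NIfTI volumes a
single sagittal slice is extracted; by convention the middle slice
``floor(n/2)`` along the first (sagittal) axis unless an explicit index is
given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import MaskFormatError, MaskValidationError

logger = logging.getLogger(__name__)

VERTEBRAL_BODIES = ("L1", "L2", "L3", "L4", "L5", "S1")
DISCS = ("L1/2", "L2/3", "L3/4", "L4/5", "L5/S1")
STRUCTURES = VERTEBRAL_BODIES + DISCS

#: (disc, cranial VB, caudal VB) triplets in cranio-caudal order
LEVELS = (
    ("L1/2", "L1", "L2"),
    ("L2/3", "L2", "L3"),
    ("L3/4", "L3", "L4"),
    ("L4/5", "L4", "L5"),
    ("L5/S1", "L5", "S1"),
)


@dataclass(frozen=True)
class SpineLabelScheme:
    """Mapping from structure name to positive integer pixel code.

    Exactly the 11 lumbar structures must be present; code 0 is reserved for
    background. The default scheme codes vertebral bodies L1..S1 as 1..6 and
    discs L1/2..L5/S1 as 7..11.
    """

    name_to_code: Mapping[str, int]

    def __post_init__(self):
        names = set(self.name_to_code)
        expected = set(STRUCTURES)
        if names != expected:
            missing = sorted(expected - names)
            extra = sorted(names - expected)
            raise MaskValidationError(
                f"label scheme must cover exactly the 11 lumbar structures; "
                f"missing={missing}, unexpected={extra}"
            )
        codes = list(self.name_to_code.values())
        if any((not isinstance(c, (int, np.integer))) or c <= 0 for c in codes):
            raise MaskValidationError("label codes must be positive integers (0 is background)")
        if len(set(codes)) != len(codes):
            raise MaskValidationError("label codes must be unique")
        object.__setattr__(self, "name_to_code", dict(self.name_to_code))

    @property
    def code_to_name(self) -> dict[int, str]:
        return {c: n for n, c in self.name_to_code.items()}

    def code(self, structure: str) -> int:
        try:
            return self.name_to_code[structure]
        except KeyError:
            raise KeyError(f"unknown structure {structure!r}") from None

    @classmethod
    def default(cls) -> "SpineLabelScheme":
        return cls({name: i + 1 for i, name in enumerate(STRUCTURES)})

    @classmethod
    def from_json(cls, path) -> "SpineLabelScheme":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({str(k): int(v) for k, v in raw.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(self.name_to_code), fh, indent=2, sort_keys=True)


def _check_grid(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise MaskValidationError(f"expected a non-empty 2D grid, got shape {pixels.shape}")
    return pixels


def _check_spacing(spacing_mm) -> tuple[float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 2 or not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing must be two finite positive values in mm, got {spacing_mm!r}")
    return spacing


@dataclass(frozen=True)
class LabelMask:
    """2D integer label grid with physical spacing and a label scheme.

    ``pixels[r, c]`` maps to millimetre coordinates ``(r * spacing_mm[0],
    c * spacing_mm[1])`` (0-based, row-major).
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    scheme: SpineLabelScheme = field(default_factory=SpineLabelScheme.default)
    source: str = "<memory>"

    def __post_init__(self):
        pixels = _check_grid(self.pixels)
        if not np.issubdtype(pixels.dtype, np.integer):
            if not np.array_equal(pixels, np.round(pixels)):
                raise MaskValidationError("label mask pixels must be integers")
            pixels = pixels.astype(np.int64)
        if pixels.min() < 0:
            raise MaskValidationError("label mask pixels must be non-negative")
        codes = set(np.unique(pixels).tolist()) - {0}
        bad = sorted(codes - set(self.scheme.name_to_code.values()))
        if bad:
            raise MaskValidationError(
                f"pixel values not in label scheme: {bad}", offending_codes=bad
            )
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "spacing_mm", _check_spacing(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def structure_pixels(self, structure: str) -> np.ndarray:
        """Boolean membership grid for one named structure."""
        return self.pixels == self.scheme.code(structure)

    def with_pixels(self, pixels: np.ndarray, source: str | None = None) -> "LabelMask":
        return replace(self, pixels=pixels, source=source or self.source)


@dataclass(frozen=True)
class GrayImage:
    """2D real-valued intensity grid with physical spacing."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    source: str = "<memory>"

    def __post_init__(self):
        pixels = np.asarray(_check_grid(self.pixels), dtype=np.float64)
        if not np.all(np.isfinite(pixels)):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "spacing_mm", _check_spacing(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _load_nifti_slice(path: Path, slice_index: int | None):
    """Return (2D array, (row, col) spacing, provenance) from a NIfTI file.

    3D volumes are sliced along the first axis (sagittal by the usual RAS
    on-disk layout); the default slice is the middle one, floor(n/2).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    if data.ndim == 2:
        if slice_index is not None:
            raise MaskFormatError(f"{path}: slice_index given for a 2D NIfTI")
        return data, (float(zooms[0]), float(zooms[1])), str(path)
    if data.ndim == 3:
        n = data.shape[0]
        idx = n // 2 if slice_index is None else int(slice_index)
        if not 0 <= idx < n:
            raise MaskFormatError(f"{path}: slice index {idx} out of range [0, {n})")
        return data[idx], (float(zooms[1]), float(zooms[2])), f"{path}[slice {idx}]"
    raise MaskFormatError(f"{path}: expected 2D or 3D NIfTI, got {data.ndim}D")


def _load_png(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "P", "1"):
            raise MaskFormatError(
                f"{path}: expected a single-channel integer image, got mode {im.mode!r}"
            )
        if im.mode == "P":
            im = im.convert("L")
        return np.asarray(im, dtype=np.int64)


def read_mask(
    path,
    scheme: SpineLabelScheme | None = None,
    spacing_override: tuple[float, float] | None = None,
    slice_index: int | None = None,
) -> LabelMask:
    """Read a label mask from PNG or NIfTI.

    PNG carries no spacing: ``spacing_override`` is used when given, otherwise
    1.0 mm isotropic is assumed with a logged warning (DHI is unaffected under
    isotropy, but absolute heights in mm then are pixel counts). For NIfTI the
    header spacing is used unless overridden. 3D NIfTI volumes yield their
    middle sagittal slice unless ``slice_index`` says otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scheme = scheme or SpineLabelScheme.default()
    if _is_nifti(path):
        data, spacing, source = _load_nifti_slice(path, slice_index)
        if spacing_override is not None:
            spacing = spacing_override
    else:
        data = _load_png(path)
        source = str(path)
        if spacing_override is not None:
            spacing = spacing_override
        else:
            logger.warning("%s: PNG has no spacing metadata; assuming 1.0 mm isotropic", path)
            spacing = (1.0, 1.0)
    if not np.array_equal(data, np.round(np.asarray(data, dtype=np.float64))):
        raise MaskFormatError(f"{path}: non-integer pixel values in label mask")
    return LabelMask(np.asarray(data).astype(np.int64), spacing, scheme, source=source)


def write_mask(mask: LabelMask, path) -> None:
    """Write a mask as PNG (8-bit when codes fit, else 16-bit) or NIfTI.

    The written file round-trips bit-exactly through :func:`read_mask`
    (spacing included for NIfTI; PNG writers must pass the spacing back
    themselves).
    """
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([mask.spacing_mm[0], mask.spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(mask.pixels.astype(np.int16), affine)
        img.header.set_zooms(mask.spacing_mm)
        nib.save(img, str(path))
        return
    max_code = int(mask.pixels.max(initial=0))
    if max_code <= 255:
        im = Image.fromarray(mask.pixels.astype(np.uint8), mode="L")
    elif max_code <= 65535:
        im = Image.fromarray(mask.pixels.astype(np.int32), mode="I")
    else:
        raise MaskFormatError(f"label code {max_code} does not fit a 16-bit PNG")
    im.save(path)


def write_gray(image: GrayImage, path) -> None:
    """Write a grayscale image (NIfTI float, or 16-bit PNG after rounding)."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([image.spacing_mm[0], image.spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(image.pixels.astype(np.float32), affine)
        img.header.set_zooms(image.spacing_mm)
        nib.save(img, str(path))
        return
    px = np.clip(np.round(image.pixels), 0, 65535).astype(np.int32)
    Image.fromarray(px, mode="I").save(path)


def read_gray(
    path, spacing_override: tuple[float, float] | None = None, slice_index: int | None = None
) -> GrayImage:
    """Read a grayscale image from PNG or NIfTI (same slicing rules as masks)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data, spacing, source = _load_nifti_slice(path, slice_index)
        if spacing_override is not None:
            spacing = spacing_override
    else:
        data = _load_png(path)
        source = str(path)
        spacing = spacing_override if spacing_override is not None else (1.0, 1.0)
    return GrayImage(np.asarray(data, dtype=np.float64), spacing, source=source)


def validate_mask(mask: LabelMask) -> dict[str, dict]:
    """Inventory all 11 structures: presence flag and pixel count each.

    Absence is reported, never raised; counts over nonzero codes sum to the
    number of nonzero pixels.
    """
    codes, counts = np.unique(mask.pixels, return_counts=True)
    by_code = dict(zip(codes.tolist(), counts.tolist()))
    inventory = {}
    for name in STRUCTURES:
        n = by_code.get(mask.scheme.code(name), 0)
        inventory[name] = {"present": n > 0, "pixel_count": int(n)}
    return inventory
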