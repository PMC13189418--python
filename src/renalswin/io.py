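"""Image and mask I/O for 2-D CT-style slices.

The working unit throughout the package is a single 2-D grayscale slice with
an integer label mask.  Supported raster formats are 8/16-bit grayscale PNG
and TIFF; NIfTI volumes are accepted only when they contain a single slice
(volumetric iteration is the caller's loop).  Pixel values are loaded without
rescaling so that intensity statistics downstream see native units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "ImageSlice",
    "SegMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

DEFAULT_LABEL_MAP = {0: "background", 1: "kidney", 2: "lesion"}


@dataclass
class ImageSlice:
    """A single 2-D grayscale slice.

    Attributes
    ----------
    pixels : ndarray
        2-D float array, row-major, top-left origin, native intensity units.
    spacing : tuple of float
        Physical pixel size ``(row_mm, col_mm)``; both > 0.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError(f"slice must be at least 8x8, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain NaN or Inf")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.pixels.min()), float(self.pixels.max())


@dataclass
class SegMask:
    """Integer label map paired with an :class:`ImageSlice`.

    ``label_map`` names each label value; it must contain 0 (background) and
    every value present in ``labels``.
    """

    labels: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.int64)
        self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if 0 not in self.label_map:
            raise ValueError("label_map must contain 0 (background)")
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.label_map)
        if unknown:
            raise ValueError(f"mask contains labels {sorted(unknown)} not in label_map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def validate_against(self, img: ImageSlice) -> None:
        if self.labels.shape != img.pixels.shape:
            raise ValueError(
                f"mask shape {self.labels.shape} != image shape {img.pixels.shape}"
            )


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    lower = str(path).lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".tif", ".tiff")):
        return "tiff"
    return "png"


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel raster to luminance (ITU-R 601 for RGB)."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[..., 0]
    raise ValueError(f"unsupported channel layout: shape {arr.shape}")


def read_image(path: str, fmt: str | None = None,
               spacing: tuple[float, float] = (1.0, 1.0)) -> ImageSlice:
    """Read a grayscale slice from PNG, TIFF, or single-slice NIfTI.

    Multi-channel rasters are collapsed to luminance; intensities are kept in
    native units (no rescaling).  A NIfTI volume with more than one slice
    raises a dimensionality error naming its shape.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image not found: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "nifti":
        vol = nib.load(path)
        arr = np.asanyarray(vol.dataobj)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ValueError(
                f"NIfTI input must be a single slice; got shape {arr.shape}"
            )
        zooms = vol.header.get_zooms()[:2]
        spacing = (float(zooms[0]) or 1.0, float(zooms[1]) or 1.0)
    elif fmt == "tiff":
        arr = _collapse_channels(tifffile.imread(path))
    elif fmt == "png":
        with Image.open(path) as im:
            arr = _collapse_channels(np.array(im))
    else:
        raise ValueError(f"unsupported format: {fmt}")
    return ImageSlice(pixels=arr.astype(np.float64), spacing=spacing)


def write_image(img: ImageSlice, path: str) -> str:
    """Write a slice losslessly.

    Integer-valued non-negative images go to 8/16-bit PNG or integer TIFF;
    general float images require TIFF or NIfTI (PNG cannot hold them).
    """
    fmt = _infer_format(path, None)
    px = img.pixels
    integral = np.allclose(px, np.round(px)) and px.min() >= 0
    if fmt == "png":
        if not integral or px.max() > 65535:
            raise ValueError("PNG output requires integer pixels in [0, 65535]; "
                             "use TIFF or NIfTI for float images")
        if px.max() <= 255:
            Image.fromarray(px.astype(np.uint8), mode="L").save(path)
        else:
            Image.fromarray(px.astype(np.uint16)).save(path)
    elif fmt == "tiff":
        if integral and px.max() <= 65535:
            tifffile.imwrite(path, px.astype(np.uint16))
        else:
            tifffile.imwrite(path, px.astype(np.float32))
    elif fmt == "nifti":
        affine = np.diag([img.spacing[0], img.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(px.astype(np.float64), affine), path)
    else:
        raise ValueError(f"unsupported format: {fmt}")
    return path


def read_mask(path: str, label_map: dict[int, str] | None = None) -> SegMask:
    img = read_image(path)
    labels = np.round(img.pixels).astype(np.int64)
    if label_map is None:
        label_map = {int(v): DEFAULT_LABEL_MAP.get(int(v), f"label_{int(v)}")
                     for v in np.unique(labels)}
        label_map.setdefault(0, "background")
    return SegMask(labels=labels, label_map=label_map)


def write_mask(mask: SegMask, path: str) -> str:
    """Write an integer mask losslessly (PNG 8/16-bit, integer TIFF, or NIfTI)."""
    mx = int(mask.labels.max(initial=0))
    if mx > 65535:
        raise ValueError(f"label value {mx} exceeds 16-bit encoding depth")
    fmt = _infer_format(path, None)
    if fmt == "nifti":
        nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), np.eye(4)), path)
    elif fmt == "tiff":
        tifffile.imwrite(path, mask.labels.astype(np.uint16))
    else:
        arr = mask.labels.astype(np.uint8) if mx <= 255 else mask.labels.astype(np.uint16)
        Image.fromarray(arr).save(path)
    return path
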