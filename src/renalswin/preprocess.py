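"""Deterministic slice preprocessing.

Fixed stage order: resize -> Wiener denoise -> CLAHE -> range scaling ->
optional histogram matching -> optional z-score.  Denoising precedes contrast
amplification so CLAHE does not amplify noise; tone-mapping stages preserve
pixel rank order.  Masks are only ever resized (nearest-neighbour), never
intensity-filtered.  No stage uses randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import wiener as _scipy_wiener
from skimage import exposure, transform

from .io import ImageSlice, SegMask

__all__ = ["NormalizationSpec", "resize_image", "resize_mask", "wiener_denoise",
           "apply_clahe", "normalize_intensity", "histogram_match",
           "reference_cdf_from_images", "preprocess_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class NormalizationSpec:
    """Preprocessing parameters.

    ``clahe_clip_limit`` follows the common contrast-limiting convention
    (default 2.0) and is mapped internally to skimage's fractional limit.
    ``range_mode`` rescales to [0, 1] ("unit") or [0, 255] ("byte") before
    any z-scoring.  ``reference_cdf`` is ``(bin_edges, cdf)`` for histogram
    matching; None disables the stage.
    """

    target_size: int = 512
    wiener_window: int = 5
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8
    clahe_enabled: bool = True
    clahe_adjacent_weighting: bool = False  # experimental tile-blending variant
    range_mode: str = "unit"
    zscore: bool = False
    reference_cdf: tuple[np.ndarray, np.ndarray] | None = None
    wiener_enabled: bool = True

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if self.clahe_tile_grid < 1:
            raise ValueError("tile_grid must be >= 1")
        if self.range_mode not in ("unit", "byte"):
            raise ValueError(f"range_mode must be 'unit' or 'byte', got {self.range_mode}")


def resize_image(img: ImageSlice, target: int) -> ImageSlice:
    """Bilinear resize to ``target x target``; spacing rescaled accordingly."""
    if target < 8:
        raise ValueError(f"target size must be >= 8, got {target}")
    r, c = img.shape
    if (r, c) == (target, target):
        return ImageSlice(img.pixels.copy(), img.spacing)
    out = transform.resize(img.pixels, (target, target), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    spacing = (img.spacing[0] * r / target, img.spacing[1] * c / target)
    return ImageSlice(out, spacing)


def resize_mask(mask: SegMask, target: int) -> SegMask:
    """Nearest-neighbour resize; the label set can only shrink, never grow."""
    if target < 8:
        raise ValueError(f"target size must be >= 8, got {target}")
    if mask.shape == (target, target):
        return SegMask(mask.labels.copy(), dict(mask.label_map))
    out = transform.resize(mask.labels.astype(np.float64), (target, target), order=0,
                           mode="edge", anti_aliasing=False, preserve_range=True)
    return SegMask(np.round(out).astype(np.int64), dict(mask.label_map))


def wiener_denoise(img: ImageSlice, window: int = 5) -> ImageSlice:
    """Local-statistics adaptive Wiener filter.

    Uses the local mean / local variance estimator: where the local variance
    falls below the noise estimate the output is the local mean, so a
    constant image passes through unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"wiener window must be odd and >= 3, got {window}")
    px = img.pixels
    if np.ptp(px) == 0:
        return ImageSlice(px.copy(), img.spacing)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = _scipy_wiener(px, mysize=window)
    out = np.nan_to_num(out, nan=float(px.mean()))
    return ImageSlice(out, img.spacing)


def apply_clahe(img: ImageSlice, clip_limit: float = 2.0, tile_grid: int = 8,
                adjacent_weighting: bool = False) -> ImageSlice:
    """Contrast-limited adaptive histogram equalization, byte-range output.

    Input must already be scaled to [0, 255].  ``adjacent_weighting`` is an
    experimental variant that additionally blends each tile mapping with its
    neighbours (beyond the standard bilinear interpolation) by running a
    second pass at a coarser grid and averaging.
    """
    px = img.pixels
    if not np.all(np.isfinite(px)):
        raise ValueError("CLAHE input contains non-finite pixels")
    if px.min() < -1e-9 or px.max() > 255 + 1e-9:
        raise ValueError("CLAHE input must be scaled to byte range [0, 255] first")
    if np.ptp(px) == 0:
        return ImageSlice(px.copy(), img.spacing)
    unit = np.clip(px / 255.0, 0.0, 1.0)
    kernel = max(1, img.shape[0] // tile_grid)
    # skimage expresses the clip limit as a fraction of tile pixel count
    frac = min(1.0, clip_limit / 100.0)
    out = exposure.equalize_adapthist(unit, kernel_size=kernel, clip_limit=frac)
    if adjacent_weighting:
        coarse = exposure.equalize_adapthist(
            unit, kernel_size=max(1, img.shape[0] // max(1, tile_grid // 2)),
            clip_limit=frac)
        out = 0.5 * (out + coarse)
    return ImageSlice(out * 255.0, img.spacing)


def normalize_intensity(img: ImageSlice, spec: NormalizationSpec) -> ImageSlice:
    """Range scaling then optional z-score (mean 0, std 1)."""
    px = img.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi > lo:
        scaled = (px - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(px)
    if spec.range_mode == "byte":
        scaled = scaled * 255.0
    if spec.zscore:
        sd = scaled.std()
        if sd == 0:
            raise ValueError("z-score requested on a constant image")
        scaled = (scaled - scaled.mean()) / sd
    return ImageSlice(scaled, img.spacing)


def histogram_match(img: ImageSlice, reference: tuple[np.ndarray, np.ndarray]) -> ImageSlice:
    """Monotone quantile mapping of ``img`` onto a reference CDF.

    ``reference`` is ``(bin_edges, cdf)`` with ``cdf`` nondecreasing and
    ending at 1.  Output values live on the reference's intensity scale and
    preserve the input's pixel rank order.
    """
    edges, cdf = np.asarray(reference[0], float), np.asarray(reference[1], float)
    if cdf.ndim != 1 or np.any(np.diff(cdf) < -1e-12) or abs(cdf[-1] - 1.0) > 1e-6:
        raise ValueError("reference CDF must be nondecreasing and end at 1")
    if len(edges) != len(cdf):
        raise ValueError("bin_edges and cdf must have equal length")
    px = img.pixels
    flat = px.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    # mid-rank empirical quantiles, ties share a quantile via averaging
    quantiles = (ranks + 0.5) / flat.size
    uniq, inv = np.unique(flat, return_inverse=True)
    qsum = np.zeros(uniq.size)
    qcnt = np.zeros(uniq.size)
    np.add.at(qsum, inv, quantiles)
    np.add.at(qcnt, inv, 1.0)
    q_of_value = qsum / qcnt
    mapped_vals = np.interp(q_of_value, cdf, edges)
    out = mapped_vals[inv].reshape(px.shape)
    return ImageSlice(out, img.spacing)


def reference_cdf_from_images(images: list[ImageSlice],
                              bins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Mean empirical CDF over a set of slices (the matching reference)."""
    if not images:
        raise ValueError("need at least one reference image")
    lo = min(im.pixels.min() for im in images)
    hi = max(im.pixels.max() for im in images)
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins)
    cdfs = []
    for im in images:
        hist, _ = np.histogram(im.pixels.ravel(), bins=bins, range=(lo, hi))
        c = np.cumsum(hist).astype(float)
        cdfs.append(c / c[-1])
    cdf = np.mean(cdfs, axis=0)
    cdf = np.maximum.accumulate(cdf)
    cdf /= cdf[-1]
    return edges, cdf


def preprocess_pipeline(img: ImageSlice, spec: NormalizationSpec,
                        mask: SegMask | None = None):
    """Run the full deterministic pipeline on one slice.

    Returns the processed image, or ``(image, mask)`` when a mask is given
    (the mask is only resized).  Stage order is fixed; see the module
    docstring.
    """
    out = resize_image(img, spec.target_size)
    log.debug("resize -> %s", out.shape)
    if spec.wiener_enabled:
        out = wiener_denoise(out, spec.wiener_window)
        log.debug("wiener window=%d", spec.wiener_window)
    if spec.clahe_enabled:
        # CLAHE operates on byte range
        byte_img = normalize_intensity(out, NormalizationSpec(
            target_size=spec.target_size, range_mode="byte", zscore=False))
        out = apply_clahe(byte_img, spec.clahe_clip_limit, spec.clahe_tile_grid,
                          spec.clahe_adjacent_weighting)
        log.debug("clahe clip=%.2f grid=%d", spec.clahe_clip_limit, spec.clahe_tile_grid)
    out = normalize_intensity(out, NormalizationSpec(
        target_size=spec.target_size, range_mode=spec.range_mode, zscore=False))
    if spec.reference_cdf is not None:
        out = histogram_match(out, spec.reference_cdf)
        log.debug("histogram matched")
    if spec.zscore:
        out = normalize_intensity(out, NormalizationSpec(
            target_size=spec.target_size, range_mode=spec.range_mode, zscore=True))
    if mask is not None:
        return out, resize_mask(mask, spec.target_size)
    return out
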