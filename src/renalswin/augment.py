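"""Seedable online augmentation.

Five strategies: geometric transforms (rotation ±15°, horizontal flip,
translation ±10%, scaling 0.9–1.1), intensity transforms (brightness/
contrast ±10% about mid-gray, gamma correction 0.8–1.2), noise injection
(Gaussian noise sigma 0.01 then Gaussian blur sigma 0.5), mixup with
Beta(0.2, 0.2) weights, and lesion-aware oversampling of minority classes
and small lesions.  Geometric draws apply the identical transform to image
(bilinear) and mask (nearest-neighbour); mixup applies to classification
pairs only — mixing integer masks is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, warp

from .io import ImageSlice, SegMask
from .manifest import DatasetManifest

__all__ = ["AugmentationSpec", "random_geometric", "apply_geometric",
           "random_intensity", "add_noise", "mixup_pair",
           "lesion_aware_oversample"]


@dataclass
class AugmentationSpec:
    rotation_deg: float = 15.0
    hflip: bool = True
    translate_frac: float = 0.10
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness_frac: float = 0.10
    contrast_frac: float = 0.10
    gamma_range: tuple[float, float] = (0.8, 1.2)
    gauss_noise_sigma: float = 0.01
    blur_sigma: float = 0.5
    mixup_alpha: float = 0.2
    oversample_boost: float = 2.0          # weight multiplier for small lesions
    small_lesion_frac: float = 0.005       # lesion area < 0.5% of image area

    def __post_init__(self) -> None:
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be > 0")
        for name in ("rotation_deg", "translate_frac", "brightness_frac",
                     "contrast_frac", "gauss_noise_sigma", "blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GeometricDraw:
    """A sampled geometric transform, replayable on image or mask."""

    angle_deg: float
    flip: bool
    translate: tuple[float, float]
    scale: float


def _draw_geometric(shape, spec: AugmentationSpec, rng: np.random.Generator) -> GeometricDraw:
    return GeometricDraw(
        angle_deg=float(rng.uniform(-spec.rotation_deg, spec.rotation_deg)),
        flip=bool(spec.hflip and rng.random() < 0.5),
        translate=(float(rng.uniform(-spec.translate_frac, spec.translate_frac) * shape[0]),
                   float(rng.uniform(-spec.translate_frac, spec.translate_frac) * shape[1])),
        scale=float(rng.uniform(*spec.scale_range)),
    )


def apply_geometric(arr: np.ndarray, draw: GeometricDraw, order: int,
                    cval: float = 0.0) -> np.ndarray:
    """Replay a geometric draw on one array (order 1 image, 0 mask)."""
    h, w = arr.shape
    out = arr.astype(np.float64)
    if draw.flip:
        out = out[:, ::-1]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(rotation=np.deg2rad(draw.angle_deg), scale=draw.scale)
          + AffineTransform(translation=center)
          + AffineTransform(translation=(draw.translate[1], draw.translate[0])))
    out = warp(out, tf.inverse, order=order, cval=cval, preserve_range=True)
    return out


def random_geometric(img: ImageSlice, mask: SegMask, spec: AugmentationSpec,
                     rng: np.random.Generator) -> tuple[ImageSlice, SegMask, GeometricDraw]:
    """One geometric draw applied identically to image and mask.

    Out-of-canvas regions are filled with the image background value
    (its minimum) and mask label 0.  The draw is returned so callers can
    verify or replay it.
    """
    mask.validate_against(img)
    draw = _draw_geometric(img.shape, spec, rng)
    bg = float(img.pixels.min())
    out_img = apply_geometric(img.pixels, draw, order=1, cval=bg)
    out_mask = np.round(apply_geometric(mask.labels, draw, order=0, cval=0)).astype(np.int64)
    return (ImageSlice(out_img, img.spacing),
            SegMask(out_mask, dict(mask.label_map)), draw)


def random_intensity(img: ImageSlice, spec: AugmentationSpec,
                     rng: np.random.Generator) -> ImageSlice:
    """Brightness/contrast jitter about mid-gray then gamma correction.

    x -> clip(c*(x-0.5)+0.5+b, 0, 1) -> x**g.  Input must be in [0, 1].
    """
    px = img.pixels
    if px.min() < -1e-9 or px.max() > 1 + 1e-9:
        raise ValueError("intensity augmentation expects unit-range input")
    b = rng.uniform(-spec.brightness_frac, spec.brightness_frac)
    c = rng.uniform(1 - spec.contrast_frac, 1 + spec.contrast_frac)
    g = rng.uniform(*spec.gamma_range)
    out = np.clip(c * (px - 0.5) + 0.5 + b, 0.0, 1.0) ** g
    return ImageSlice(out, img.spacing)


def add_noise(img: ImageSlice, spec: AugmentationSpec,
              rng: np.random.Generator) -> ImageSlice:
    """Gaussian noise then Gaussian blur, clipped to [0, 1]."""
    px = img.pixels
    if px.min() < -1e-9 or px.max() > 1 + 1e-9:
        raise ValueError("noise augmentation expects unit-range input")
    out = px.copy()
    if spec.gauss_noise_sigma > 0:
        out = out + rng.normal(0.0, spec.gauss_noise_sigma, size=px.shape)
    if spec.blur_sigma > 0:
        out = gaussian_filter(out, sigma=spec.blur_sigma)
    return ImageSlice(np.clip(out, 0.0, 1.0), img.spacing)


def mixup_pair(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray],
               alpha: float = 0.2, rng: np.random.Generator | None = None,
               lam: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Convex combination of two (image, one-hot label) pairs.

    lam ~ Beta(alpha, alpha) unless forced; returns (image, soft label, lam).
    """
    img_a, lab_a = np.asarray(a[0], float), np.asarray(a[1], float)
    img_b, lab_b = np.asarray(b[0], float), np.asarray(b[1], float)
    if img_a.shape != img_b.shape:
        raise ValueError(f"image shape mismatch: {img_a.shape} vs {img_b.shape}")
    if lab_a.shape != lab_b.shape:
        raise ValueError(f"label shape mismatch: {lab_a.shape} vs {lab_b.shape}")
    if lam is None:
        if rng is None:
            raise ValueError("provide rng or a forced lam")
        lam = float(rng.beta(alpha, alpha))
    return lam * img_a + (1 - lam) * img_b, lam * lab_a + (1 - lam) * lab_b, float(lam)


def lesion_aware_oversample(manifest: DatasetManifest,
                            lesion_areas: dict[str, float],
                            spec: AugmentationSpec,
                            image_area: float) -> np.ndarray:
    """Per-record sampling weights: inverse class frequency, boosted for
    records whose lesion area is below the small-lesion threshold.

    ``lesion_areas`` maps image_path -> lesion pixel count (0 for none).
    Weights are normalized to sum to 1.
    """
    counts = manifest.class_counts
    weights = np.empty(len(manifest.records))
    thresh = spec.small_lesion_frac * image_area
    for i, rec in enumerate(manifest.records):
        w = 1.0 / max(counts[rec.class_label], 1)
        area = lesion_areas.get(rec.image_path, 0.0)
        if 0 < area < thresh:
            w *= spec.oversample_boost
        weights[i] = w
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    return weights / total
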