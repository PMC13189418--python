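"""Synthetic CT-like kidney phantoms with known ground truth.

Each phantom is an elliptical kidney (parenchyma) on background, optionally
carrying one class-specific lesion: a round hypodense cyst, a small
hyperdense stone, or an irregular multi-lobed tumor whose core interleaves
two Gamma laws (heterogeneity).  Every region's pixels are drawn i.i.d. from
a known three-parameter Gamma law, so the moments of each region are exact
test oracles (mean loc + alpha*beta, variance alpha*beta^2).

Default laws follow CT hypo/hyper-density ordering
background < cyst < parenchyma < tumor-core < stone, with lesion laws at
least 4 pooled standard deviations from parenchyma in the "clear" tier.
"mild" and "low" difficulty tiers shift the lesion law's location so the
lesion/parenchyma mean gap shrinks to 2 and 1 pooled SD respectively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .gamma import GammaParams
from .io import ImageSlice, SegMask, write_image, write_mask
from .manifest import CLASSES, DatasetManifest, ManifestRecord, save_manifest

__all__ = ["PhantomSpec", "DEFAULT_TISSUE_LAWS", "CONTRAST_TIERS",
           "generate_phantom", "generate_dataset", "tiered_laws"]

DEFAULT_TISSUE_LAWS: dict[str, GammaParams] = {
    "background": GammaParams(alpha=2.0, beta=5.0, gamma_loc=10.0),    # mean 20
    "parenchyma": GammaParams(alpha=4.0, beta=10.0, gamma_loc=100.0),  # mean 140
    "cyst": GammaParams(alpha=3.0, beta=6.0, gamma_loc=40.0),          # mean 58
    "stone": GammaParams(alpha=4.0, beta=6.0, gamma_loc=200.0),        # mean 224
    "tumor": GammaParams(alpha=4.0, beta=5.0, gamma_loc=185.0),        # mean 205
    "tumor_alt": GammaParams(alpha=3.0, beta=5.0, gamma_loc=200.0),    # mean 215
}

# lesion/parenchyma mean gap in pooled SDs per difficulty tier
CONTRAST_TIERS = {"clear": None, "mild": 2.0, "low": 1.0}

_LESION_SIGN = {"cyst": -1.0, "stone": 1.0, "tumor": 1.0, "tumor_alt": 1.0}


def tiered_laws(contrast_level: str,
                base: dict[str, GammaParams] | None = None) -> dict[str, GammaParams]:
    """Tissue laws for a difficulty tier.

    The "clear" tier returns the base laws; other tiers relocate each lesion
    law so its mean sits ``gap`` pooled SDs from the parenchyma mean on its
    hypo/hyper-dense side, keeping shape and scale.
    """
    base = dict(base or DEFAULT_TISSUE_LAWS)
    if contrast_level not in CONTRAST_TIERS:
        raise ValueError(f"unknown contrast level {contrast_level!r}")
    gap = CONTRAST_TIERS[contrast_level]
    if gap is None:
        return base
    par = base["parenchyma"]
    par_mean = par.gamma_loc + par.alpha * par.beta
    par_var = par.alpha * par.beta ** 2
    out = dict(base)
    for name in ("cyst", "stone", "tumor", "tumor_alt"):
        p = base[name]
        pooled_sd = np.sqrt(0.5 * (par_var + p.alpha * p.beta ** 2))
        target = par_mean + _LESION_SIGN[name] * gap * pooled_sd
        out[name] = replace(p, gamma_loc=target - p.alpha * p.beta)
    return out


@dataclass
class PhantomSpec:
    class_label: str = "normal"
    image_size: int = 64
    kidney_axes: tuple[float, float] | None = None  # (a, b) px; default from size
    lesion_radius_range: tuple[float, float] | None = None
    tissue_laws: dict[str, GammaParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_LAWS))
    contrast_level: str = "clear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}")
        if self.contrast_level not in CONTRAST_TIERS:
            raise ValueError(f"contrast_level must be one of {tuple(CONTRAST_TIERS)}")
        s = self.image_size
        if self.kidney_axes is None:
            self.kidney_axes = (0.36 * s, 0.24 * s)
        if self.lesion_radius_range is None:
            if self.class_label == "stone":
                self.lesion_radius_range = (0.035 * s, 0.06 * s)
            else:
                self.lesion_radius_range = (0.07 * s, 0.11 * s)
        a, b = self.kidney_axes
        if self.lesion_radius_range[1] >= min(a, b) / 2 and self.class_label != "normal":
            raise ValueError("lesion radius must be < min(kidney axis)/2")


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _sample_lesion_center(kidney: np.ndarray, radius: float,
                          rng: np.random.Generator) -> tuple[int, int]:
    """A point whose disc of the given radius fits inside the kidney mask."""
    from scipy.ndimage import binary_erosion
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = yy ** 2 + xx ** 2 <= r ** 2
    interior = binary_erosion(kidney, structure=disc)
    idx = np.argwhere(interior)
    if len(idx) == 0:
        raise ValueError(
            f"lesion of radius {radius:.1f} cannot fit inside the kidney")
    return tuple(idx[rng.integers(len(idx))])


def generate_phantom(spec: PhantomSpec) -> tuple[ImageSlice, SegMask, str]:
    """Generate one phantom: (image, mask, class_label), reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    laws = tiered_laws(spec.contrast_level, spec.tissue_laws)

    center = (s / 2 + rng.uniform(-0.05 * s, 0.05 * s),
              s / 2 + rng.uniform(-0.05 * s, 0.05 * s))
    angle = rng.uniform(0, np.pi)
    kidney = _ellipse_mask((s, s), center, spec.kidney_axes, angle)

    lesion = np.zeros((s, s), dtype=bool)
    lesion_alt = np.zeros((s, s), dtype=bool)
    if spec.class_label != "normal":
        radius = rng.uniform(*spec.lesion_radius_range)
        cy, cx = _sample_lesion_center(kidney, radius, rng)
        if spec.class_label == "tumor":
            # union of 3-5 overlapping random ellipses, two interleaved laws
            n_lobes = int(rng.integers(3, 6))
            for i in range(n_lobes):
                off = rng.uniform(-0.5 * radius, 0.5 * radius, size=2)
                ax = (rng.uniform(0.5, 1.0) * radius, rng.uniform(0.5, 1.0) * radius)
                lobe = _ellipse_mask((s, s), (cy + off[0], cx + off[1]), ax,
                                     rng.uniform(0, np.pi))
                if i % 2 == 0:
                    lesion |= lobe
                else:
                    lesion_alt |= lobe
        else:
            yy, xx = np.mgrid[0:s, 0:s]
            lesion = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        lesion &= kidney  # clip to parenchyma
        lesion_alt &= kidney
        lesion_alt &= ~lesion

    img = np.empty((s, s), dtype=np.float64)
    mask = np.zeros((s, s), dtype=np.int64)
    regions = [(~kidney, laws["background"], 0),
               (kidney & ~lesion & ~lesion_alt, laws["parenchyma"], 1)]
    if spec.class_label == "tumor":
        regions += [(lesion, laws["tumor"], 2), (lesion_alt, laws["tumor_alt"], 2)]
    elif spec.class_label != "normal":
        regions += [(lesion, laws[spec.class_label], 2)]
    for region, law, label in regions:
        n = int(region.sum())
        if n:
            img[region] = law.sample(rng, n)
            mask[region] = label
    slice_ = ImageSlice(img, spacing=(1.0, 1.0))
    seg = SegMask(mask)
    return slice_, seg, spec.class_label


def _assign_splits(n: int, rng: np.random.Generator) -> list[str]:
    """70/15/15 split labels for n records of one class, shuffled.

    For very small n, val and test each keep at least one record (a split
    with an empty validation set cannot drive early stopping)."""
    n_train = int(round(0.70 * n))
    n_val = min(int(round(0.15 * n)), n - n_train)
    if n >= 3 and n_val == 0:
        n_train -= 1
        n_val = 1
    if n >= 3 and n - n_train - n_val == 0:
        n_train -= 1
    labels = (["train"] * n_train + ["val"] * n_val
              + ["test"] * (n - n_train - n_val))
    rng.shuffle(labels)
    return labels


def generate_dataset(n_per_class: int, out_dir: str,
                     contrast_mix: dict[str, float] | None = None,
                     seed: int = 0, image_size: int = 64) -> DatasetManifest:
    """Write a balanced phantom dataset (PNG images + masks + CSV manifest).

    Splits are assigned 70/15/15 stratified by class; difficulty tiers are
    sampled per record from ``contrast_mix`` (default: all "clear").
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    contrast_mix = contrast_mix or {"clear": 1.0}
    tiers = list(contrast_mix)
    probs = np.array([contrast_mix[t] for t in tiers], float)
    probs = probs / probs.sum()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    records: list[ManifestRecord] = []
    for cls in CLASSES:
        splits = _assign_splits(n_per_class, rng)
        for i in range(n_per_class):
            tier = tiers[rng.choice(len(tiers), p=probs)]
            spec = PhantomSpec(class_label=cls, image_size=image_size,
                               contrast_level=tier,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
            img, mask, _ = generate_phantom(spec)
            img_name = f"{cls}_{i:04d}.png"
            mask_name = f"{cls}_{i:04d}_mask.png"
            write_image(ImageSlice(np.clip(np.round(img.pixels), 0, 65535)),
                        os.path.join(out_dir, img_name))
            write_mask(mask, os.path.join(out_dir, mask_name))
            records.append(ManifestRecord(image_path=img_name, mask_path=mask_name,
                                          class_label=cls, split=splits[i],
                                          contrast=tier))
    manifest = DatasetManifest(records)
    save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
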