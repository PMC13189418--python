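"""End-to-end orchestration: phantoms -> Gamma maps -> training -> metrics.

This module glues the statistical core to the networks.  Each image gets a
per-image Gamma-mixture fit (hierarchical initialization + EM) whose
atypicality map rides along as a second input channel, so the networks see
both raw intensity and "no tissue law explains this pixel" evidence.
The scaled-down protocol used for CPU verification lives here too: tiny
profile, 64-px clear-tier phantoms, short schedules.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .gamma import em_fit, gamma_feature_map, hierarchical_init
from .io import ImageSlice, read_image, read_mask
from .manifest import CLASSES, DatasetManifest, ManifestRecord
from .nn.classifier import PyramidClassifier
from .nn.segmodel import SegmentationModel
from .nn.swin import PROFILES, ModelProfile
from .phantom import PhantomSpec, generate_phantom
from .train import (ArrayDataset, CropDataset, TINY_CLS_RECIPE,
                    TINY_SEG_RECIPE, TrainConfig, evaluate_cls, evaluate_seg,
                    train_classifier, train_segmentation)

__all__ = ["compute_gamma_map", "compute_gamma_map_kmeans",
           "build_phantom_arrays", "load_arrays", "ScaledRunResult",
           "run_scaled_pipeline"]

log = logging.getLogger(__name__)


def compute_gamma_map(img: ImageSlice, max_k: int = 3, seed: int = 0,
                      em_iters: int = 15) -> np.ndarray:
    """Fit a per-image Gamma mixture and return its atypicality map in [0,1]."""
    init = hierarchical_init(img.pixels.ravel(), max_k=max_k, seed=seed)
    state = em_fit(img.pixels.ravel(), init, max_iter=em_iters)
    return gamma_feature_map(img, state.mixture).pixels


def compute_gamma_map_kmeans(img: ImageSlice, k: int = 3,
                             seed: int = 0) -> np.ndarray:
    """Ablation variant: k-means initialization instead of hierarchical.

    Fixed k (no merge-gap selection); per-cluster moment fits feed the same
    atypicality map."""
    from sklearn.cluster import KMeans

    from .gamma import GammaMixture, fit_gamma_mom
    y = img.pixels.ravel()
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(y.reshape(-1, 1))
    comps, ws = [], []
    for c in range(k):
        pts = y[km.labels_ == c]
        if pts.size < 10:
            continue
        loc = pts.min() - max(1e-3, 0.01 * np.ptp(pts))
        comps.append(fit_gamma_mom(pts, loc))
        ws.append(pts.size)
    mix = GammaMixture(comps, np.asarray(ws, float) / np.sum(ws))
    return gamma_feature_map(img, mix).pixels


def _unit(px: np.ndarray) -> np.ndarray:
    lo, hi = px.min(), px.max()
    return (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)


def build_phantom_arrays(n_per_class: int, image_size: int = 64,
                         contrast_level: str = "clear", seed: int = 0,
                         use_gamma_maps: bool = True,
                         ) -> tuple[ArrayDataset, DatasetManifest]:
    """Generate an in-memory balanced phantom dataset with 70/15/15 splits."""
    rng = np.random.default_rng(seed)
    images, masks, class_idx, gmaps = [], [], [], []
    records = []
    from .phantom import _assign_splits
    for ci, cls in enumerate(CLASSES):
        splits = _assign_splits(n_per_class, rng)
        for i in range(n_per_class):
            spec = PhantomSpec(class_label=cls, image_size=image_size,
                               contrast_level=contrast_level,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
            img, mask, _ = generate_phantom(spec)
            images.append(_unit(img.pixels))
            masks.append(mask.labels)
            class_idx.append(ci)
            if use_gamma_maps:
                gmaps.append(compute_gamma_map(
                    img, seed=int(rng.integers(0, 2 ** 31 - 1))))
            records.append(ManifestRecord(image_path=f"mem://{cls}_{i}",
                                          mask_path=None, class_label=cls,
                                          split=splits[i],
                                          contrast=contrast_level))
    data = ArrayDataset(images=images, masks=masks, class_idx=class_idx,
                        gamma_maps=gmaps if use_gamma_maps else None)
    return data, DatasetManifest(records)


def load_arrays(manifest: DatasetManifest, root: str,
                use_gamma_maps: bool = True, seed: int = 0) -> ArrayDataset:
    """Materialize a manifest from disk into training arrays."""
    images, masks, class_idx, gmaps = [], [], [], []
    rng = np.random.default_rng(seed)
    for rec in manifest.records:
        img = read_image(os.path.join(root, rec.image_path))
        if rec.mask_path is None:
            raise ValueError(f"record {rec.image_path} has no mask")
        mask = read_mask(os.path.join(root, rec.mask_path))
        images.append(_unit(img.pixels))
        masks.append(mask.labels)
        class_idx.append(CLASSES.index(rec.class_label))
        if use_gamma_maps:
            gmaps.append(compute_gamma_map(
                img, seed=int(rng.integers(0, 2 ** 31 - 1))))
    return ArrayDataset(images=images, masks=masks, class_idx=class_idx,
                        gamma_maps=gmaps if use_gamma_maps else None)


def _split_indices(manifest: DatasetManifest) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for i, r in enumerate(manifest.records):
        out[r.split].append(i)
    return out


@dataclass
class ScaledRunResult:
    val_dice: float
    test_dice: float
    cls_val_accuracy: float
    cls_test_accuracy: float
    seg_epochs: int
    cls_epochs: int
    seg_history: list
    cls_history: list


def run_scaled_pipeline(seed: int = 0, n_per_class: int = 50,
                        image_size: int = 64,
                        profile: ModelProfile | None = None,
                        seg_cfg: TrainConfig | None = None,
                        cls_cfg: TrainConfig | None = None,
                        use_swin: bool = True,
                        use_cross_attention: bool = True,
                        gamma_modulation: str = "deepest",
                        use_gamma_maps: bool = True,
                        gamma_init: str = "hierarchical",
                        ) -> ScaledRunResult:
    """The CPU-scale two-stage pipeline on clear-tier phantoms.

    Trains the tiny segmentation network and the crop classifier, returning
    validation/test macro Dice and classification accuracy.  The ablation
    flags mirror the architecture's variant structure (attention encoder
    off, cross-attention decoder off, channel gating off, Gamma channel
    off, k-means instead of hierarchical initialization).
    """
    profile = profile or PROFILES["tiny"]
    seg_cfg = seg_cfg or TrainConfig(**{**TINY_SEG_RECIPE.__dict__, "seed": seed})
    cls_cfg = cls_cfg or TrainConfig(**{**TINY_CLS_RECIPE.__dict__, "seed": seed + 1})
    data, manifest = build_phantom_arrays(
        n_per_class, image_size=image_size, seed=seed,
        use_gamma_maps=use_gamma_maps)
    if gamma_init == "kmeans" and use_gamma_maps:
        # ablation: replace hierarchical initialization with k-means centers
        rng = np.random.default_rng(seed + 5)
        data.gamma_maps = [
            compute_gamma_map_kmeans(ImageSlice(im * 255.0),
                                     seed=int(rng.integers(0, 2 ** 31 - 1)))
            for im in data.images]
    splits = _split_indices(manifest)
    in_ch = 2 if use_gamma_maps else 1
    seg_model = SegmentationModel(profile, image_size, in_channels=in_ch,
                                  seed=seed, use_swin=use_swin,
                                  use_cross_attention=use_cross_attention,
                                  gamma_modulation=gamma_modulation)
    seg_state = train_segmentation(seg_model, data, splits["train"],
                                   splits["val"], seg_cfg)
    val_dice = seg_state.best_metric
    test_dice = evaluate_seg(seg_model, data, splits["test"])
    # stage 2: classifier on ground-truth-guided crops (teacher forcing)
    crop = profile.classifier_crop
    tr = CropDataset.from_arrays(data, splits["train"], crop)
    va = CropDataset.from_arrays(data, splits["val"], crop)
    te = CropDataset.from_arrays(data, splits["test"], crop)
    clf = PyramidClassifier(profile, seed=seed + 2, in_channels=2)
    cls_state = train_classifier(clf, tr, va, cls_cfg)
    val_eval = evaluate_cls(clf, va)
    test_eval = evaluate_cls(clf, te)
    return ScaledRunResult(
        val_dice=float(val_dice), test_dice=float(test_dice),
        cls_val_accuracy=float(val_eval["accuracy"]),
        cls_test_accuracy=float(test_eval["accuracy"]),
        seg_epochs=seg_state.epoch + 1, cls_epochs=cls_state.epoch + 1,
        seg_history=seg_state.history, cls_history=cls_state.history)
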