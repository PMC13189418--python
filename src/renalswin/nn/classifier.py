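"""Hierarchical pyramid classifier for lesion crops.

Crops of the segmented lesion (or the kidney for lesion-free cases) are
resized to the profile's standard crop (224 px for the full profile, 64 px
for tiny), encoded by the four-stage windowed-attention pyramid, and
summarized by one global token per stage (spatial mean).  A learned class
token then attends over the four scale tokens (attention-based multi-scale
fusion, BERT-style aggregation) and a dropout-regularized MLP head emits
class probabilities.  The default head is the 4-class renal task
(normal/cyst/stone/tumor); a binary benign/malignant grouping maps
tumor -> malignant and everything else -> benign.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.transform import resize as _sk_resize

from .autodiff import Tensor, concat
from .layers import Dropout, LayerNorm, Linear, Module
from .swin import ModelProfile, SwinEncoder

__all__ = ["PyramidClassifier", "prepare_crop", "prepare_crop_with_shape",
           "BENIGN_MALIGNANT_MAP"]

log = logging.getLogger(__name__)

# class order matches manifest.CLASSES: normal, cyst, stone, tumor
BENIGN_MALIGNANT_MAP = {0: 0, 1: 0, 2: 0, 3: 1}


def prepare_crop(image: np.ndarray, mask: np.ndarray | None, crop_size: int,
                 margin: float = 0.15, min_context_frac: float = 0.25) -> np.ndarray:
    """Crop around the mask's highest present label and resize.

    The square crop is centered on the target region's bounding box,
    expanded by ``margin``, but never smaller than ``min_context_frac`` of
    the image side: keeping surrounding parenchyma in frame preserves the
    absolute lesion size cue (a calculus and a tumor can have identical
    texture after a tight zoom).  Inputs of the wrong size are resized with
    a log notice rather than rejected.
    """
    img = np.asarray(image, dtype=np.float64)
    if mask is not None:
        m = np.asarray(mask)
        target = m == m.max() if m.max() > 0 else None
        if target is not None and target.any():
            ys, xs = np.where(target)
            h, w = img.shape
            box = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
            side = int(max(box * (1 + 2 * margin), min_context_frac * min(h, w)))
            side = min(side, min(h, w))
            cy = (ys.min() + ys.max()) // 2
            cx = (xs.min() + xs.max()) // 2
            y0 = int(np.clip(cy - side // 2, 0, h - side))
            x0 = int(np.clip(cx - side // 2, 0, w - side))
            img = img[y0:y0 + side, x0:x0 + side]
    if img.shape != (crop_size, crop_size):
        log.debug("resizing crop %s -> %dx%d", img.shape, crop_size, crop_size)
        img = _sk_resize(img, (crop_size, crop_size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    return img


def prepare_crop_with_shape(image: np.ndarray, mask: np.ndarray | None,
                            crop_size: int, margin: float = 0.15,
                            min_context_frac: float = 0.25) -> np.ndarray:
    """Two-channel crop: (image, binary target-region shape), (2, S, S).

    The shape channel carries the segmented region's geometry — a compact
    calculus and a multi-lobed mass can share texture after zooming, but
    not shape.  Both channels are cut with identical geometry; the shape
    channel is resized nearest-neighbour.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if mask is None or np.asarray(mask).max() == 0:
        shape = np.zeros_like(img)
        ic = prepare_crop(img, mask, crop_size, margin, min_context_frac)
        mc = _sk_resize(shape, (crop_size, crop_size), order=0,
                        preserve_range=True, anti_aliasing=False)
        return np.stack([ic, mc])
    m = np.asarray(mask)
    target = (m == m.max()).astype(np.float64)
    ys, xs = np.where(target > 0)
    box = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    side = int(min(max(box * (1 + 2 * margin), min_context_frac * min(h, w)),
                   min(h, w)))
    cy = (ys.min() + ys.max()) // 2
    cx = (xs.min() + xs.max()) // 2
    y0 = int(np.clip(cy - side // 2, 0, h - side))
    x0 = int(np.clip(cx - side // 2, 0, w - side))
    ic = _sk_resize(img[y0:y0 + side, x0:x0 + side], (crop_size, crop_size),
                    order=1, mode="edge", anti_aliasing=False,
                    preserve_range=True)
    mc = _sk_resize(target[y0:y0 + side, x0:x0 + side],
                    (crop_size, crop_size), order=0, preserve_range=True,
                    anti_aliasing=False)
    return np.stack([ic, mc])


class PyramidClassifier(Module):
    def __init__(self, profile: ModelProfile, seed: int = 0,
                 binary_head: bool = False, in_channels: int = 1):
        super().__init__()
        self.profile = profile
        self.binary_head = binary_head
        self.in_channels = in_channels
        self.crop_size = profile.classifier_crop
        rng = np.random.default_rng(seed + 13)
        self.encoder = SwinEncoder(profile, self.crop_size,
                                   in_channels=in_channels, seed=seed + 1)
        d = profile.embed_dims[-1]
        self.scale_proj = [Linear(c, d, rng) for c in profile.embed_dims]
        self.cls_token = Tensor(rng.normal(0, 0.02, (1, 1, d)), requires_grad=True)
        self.norm = LayerNorm(d)
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        n_out = 2 if binary_head else profile.cls_classes
        hidden = max(2 * d, 16)
        self.head1 = Linear(d, hidden, rng)
        self.drop = Dropout(profile.dropout, seed=seed + 97)
        self.head2 = Linear(hidden, n_out, rng)
        self.last_fusion_attention: np.ndarray | None = None

    def forward_logits(self, x: Tensor) -> Tensor:
        """Pre-softmax class scores (B, n_classes)."""
        b = x.shape[0]
        feats = self.encoder(x)
        scale_tokens = []
        for f, proj in zip(feats, self.scale_proj):
            bb, h, w, c = f.shape
            pooled = f.reshape(bb, h * w, c).mean(axis=1)  # (B, C)
            scale_tokens.append(proj(pooled).reshape(bb, 1, -1))
        tokens = concat(scale_tokens, axis=1)  # (B, 4, d)
        cls = self.cls_token + Tensor(np.zeros((b, 1, tokens.shape[-1])))
        q = self.wq(self.norm(cls))
        k = self.wk(self.norm(tokens))
        v = self.wv(self.norm(tokens))
        d = q.shape[-1]
        attn = ((q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))).softmax(axis=-1)
        self.last_fusion_attention = attn.data.copy()
        fused = (attn @ v + cls).reshape(b, -1)
        return self.head2(self.drop(self.head1(fused).gelu()))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 1, S, S) crops -> (B, n_classes) probabilities (rows sum to 1)."""
        return self.forward_logits(x).softmax(axis=-1)
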