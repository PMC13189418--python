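"""Saliency: Grad-CAM for the classifier, attention overlays for the encoder.

Grad-CAM backpropagates a class score to a chosen pyramid stage, weights
each channel by its spatially averaged gradient, rectifies the weighted sum
and normalizes to [0, 1].  Attention overlays reshape a retained attention
map (mean over heads and queries by default) onto the stage's token grid
and alpha-blend it over the input image.  Neither path mutates model state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import ImageSlice
from .nn.autodiff import Tensor
from .nn.classifier import PyramidClassifier

__all__ = ["SaliencyMap", "grad_cam", "attention_overlay", "render_overlay"]


@dataclass
class SaliencyMap:
    values: np.ndarray          # H x W in [0, 1]
    source: str                 # "gradcam" | "attention"
    target: int | None = None   # class index for gradcam
    layer: str | None = None


def _normalize(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi > lo:
        return (m - lo) / (hi - lo)
    return np.zeros_like(m)


def grad_cam(model: PyramidClassifier, crop: np.ndarray, target_class: int,
             stage: int = 3) -> SaliencyMap:
    """Gradient-weighted class activation map for one crop.

    ``stage`` selects the pyramid stage whose spatial features are weighted
    (default: the last / coarsest).  Dropout is disabled for the pass; two
    calls on the same input produce identical maps.
    """
    if not 0 <= stage <= 3:
        raise ValueError("stage must be in 0..3 (spatial pyramid stages)")
    was_training = model.training
    model.eval()
    try:
        arr = np.asarray(crop, float)
        if arr.ndim == 2:
            arr = arr[None]
        x = Tensor(arr[None], requires_grad=True)
        feats = model.encoder(x)
        fmap = feats[stage]  # (1, h, w, c), part of the graph
        # rebuild the head exactly as forward_logits does, reusing fmap's graph
        from .nn.autodiff import concat
        scale_tokens = []
        for f, proj in zip(feats, model.scale_proj):
            bb, h, w, c = f.shape
            scale_tokens.append(proj(f.reshape(bb, h * w, c).mean(axis=1))
                                .reshape(bb, 1, -1))
        tokens = concat(scale_tokens, axis=1)
        cls = model.cls_token + Tensor(np.zeros((1, 1, tokens.shape[-1])))
        q = model.wq(model.norm(cls))
        k = model.wk(model.norm(tokens))
        v = model.wv(model.norm(tokens))
        d = q.shape[-1]
        attn = ((q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))).softmax(axis=-1)
        fused = (attn @ v + cls).reshape(1, -1)
        logits = model.head2(model.head1(fused).gelu())
        if not 0 <= target_class < logits.shape[-1]:
            raise ValueError(f"target class {target_class} out of range")
        score = logits[:, target_class].sum()
        model.zero_grad()
        score.backward()
        grads = fmap.grad  # (1, h, w, c)
        if grads is None:
            raise RuntimeError("stage produced no gradient; not a spatial layer")
        weights = grads.mean(axis=(1, 2))  # (1, c)
        cam = np.maximum((fmap.data * weights[:, None, None, :]).sum(-1), 0.0)[0]
        up = _sk_resize(cam, arr.shape[-2:], order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        return SaliencyMap(values=_normalize(up), source="gradcam",
                           target=target_class, layer=f"stage{stage}")
    finally:
        model.train(was_training)


def attention_overlay(attention_maps: list[list[np.ndarray]],
                      image: ImageSlice, stage: int = 2, head: int | None = None,
                      block: int = -1) -> SaliencyMap:
    """Mean attention received per token, reshaped to the stage grid.

    ``attention_maps[stage][block]`` has shape (n_windows, heads, T, T+M);
    averaging over queries (and heads unless one is selected) gives each
    token's received attention, mapped back through the window tiling.
    """
    if stage >= len(attention_maps) or not attention_maps[stage]:
        raise ValueError(f"no retained attention maps for stage {stage}")
    attn = attention_maps[stage][block]
    nwin, heads, t, _ = attn.shape
    a = attn[:, head] if head is not None else attn.mean(axis=1)  # (nwin, T, T+M)
    received = a[:, :, :t].mean(axis=1)  # (nwin, T): mean over queries
    ws = int(np.sqrt(t))
    nside = int(np.sqrt(nwin))
    grid = received.reshape(nside, nside, ws, ws).transpose(0, 2, 1, 3)
    grid = grid.reshape(nside * ws, nside * ws)
    up = _sk_resize(grid, image.shape, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return SaliencyMap(values=_normalize(up), source="attention",
                       layer=f"stage{stage}")


def render_overlay(image: ImageSlice, saliency: SaliencyMap,
                   alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend the saliency over the grayscale image -> (H, W, 3) in [0,1].

    Saliency uses a red-yellow ramp; underlying pixels are preserved where
    the saliency is zero.
    """
    base = _normalize(image.pixels)
    rgb = np.stack([base, base, base], axis=-1)
    heat = np.stack([saliency.values,
                     saliency.values ** 2,
                     np.zeros_like(saliency.values)], axis=-1)
    w = alpha * saliency.values[..., None]
    return np.clip(rgb * (1 - w) + heat * w, 0.0, 1.0)
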