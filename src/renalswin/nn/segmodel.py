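"""Segmentation network: encoder, Gamma channel gating, cross-attention
skip fusion, boundary enhancement and a deep-supervised decoder.

The decoder walks the encoder pyramid from 1/32 back to 1/4 resolution.
At each level the upsampled decoder state queries the corresponding encoder
stage through single-head cross-attention — softmax(Q K^T / sqrt(d)) V plus
the decoder residual — instead of concatenation, and an auxiliary head at
each intermediate level provides deep supervision.  A dilated-convolution
boundary branch predicts lesion/organ edges from the finest decoder
feature.  Channel gating: per-channel global average pooling feeds two
small positive-output networks estimating Gamma (shape k, scale theta) for
each channel; the gate sigmoid(u*mu_hat + v*var_hat + b) rescales channels
by how informative their activation statistics are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .layers import MLP, Conv2d, LayerNorm, Linear, Module
from .swin import ModelProfile, SwinEncoder

__all__ = ["ChannelGammaStats", "GammaModulation", "cross_attention_fuse",
           "CrossAttentionSkip", "BoundaryEnhance", "ConvEncoder",
           "SegmentationModel"]


@dataclass
class ChannelGammaStats:
    """Per-channel Gamma activation summary (B, C) arrays."""

    k: np.ndarray
    theta: np.ndarray

    @property
    def mu(self) -> np.ndarray:
        return self.k * self.theta

    @property
    def var(self) -> np.ndarray:
        return self.k * self.theta ** 2


class GammaModulation(Module):
    """Gamma-parameterized channel gating of a (B, C, H, W) feature map."""

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int = 8):
        super().__init__()
        self.fc_k1 = Linear(1, hidden, rng)
        self.fc_k2 = Linear(hidden, 1, rng)
        self.fc_t1 = Linear(1, hidden, rng)
        self.fc_t2 = Linear(hidden, 1, rng)
        self.gate_u = Tensor(np.array(1.0), requires_grad=True)
        self.gate_v = Tensor(np.array(-1.0), requires_grad=True)
        self.gate_b = Tensor(np.array(0.0), requires_grad=True)
        self.last_stats: ChannelGammaStats | None = None

    def __call__(self, f: Tensor) -> Tensor:
        b, c, h, w = f.shape
        s = f.mean(axis=(2, 3)).reshape(b, c, 1)  # per-channel GAP
        k = self.fc_k2(self.fc_k1(s).gelu()).softplus().reshape(b, c)
        theta = self.fc_t2(self.fc_t1(s).gelu()).softplus().reshape(b, c)
        mu = k * theta
        var = k * theta * theta
        # standardize across channels so the gate sees comparable scales
        mu_hat = (mu - mu.mean(axis=1, keepdims=True)) * \
            (((mu - mu.mean(axis=1, keepdims=True)) ** 2).mean(axis=1, keepdims=True)
             + 1e-6) ** -0.5
        var_hat = (var - var.mean(axis=1, keepdims=True)) * \
            (((var - var.mean(axis=1, keepdims=True)) ** 2).mean(axis=1, keepdims=True)
             + 1e-6) ** -0.5
        gate = (self.gate_u * mu_hat + self.gate_v * var_hat + self.gate_b).sigmoid()
        self.last_stats = ChannelGammaStats(k=k.data.copy(), theta=theta.data.copy())
        self.last_gates = gate.data.copy()
        return f * gate.reshape(b, c, 1, 1)


def cross_attention_fuse(q: Tensor, k: Tensor, v: Tensor,
                         f_decoder: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d)) V + F_decoder, softmax over keys.

    Shapes: Q (..., Nq, d), K (..., Nk, d), V (..., Nk, dv), F (..., Nq, dv).
    """
    d = q.shape[-1]
    if d <= 0 or k.shape[-1] != d:
        raise ValueError(f"Q/K feature dimension mismatch or nonpositive: "
                         f"{d} vs {k.shape[-1]}")
    ndim = len(k.shape)
    perm = tuple(range(ndim - 2)) + (ndim - 1, ndim - 2)
    logits = (q @ k.transpose(perm)) * (1.0 / np.sqrt(d))
    attn = logits.softmax(axis=-1)
    return attn @ v + f_decoder


class CrossAttentionSkip(Module):
    """Skip connection replacing concatenation: decoder tokens query the
    encoder stage; Q/K/V are learned projections, fusion is Eq.-style
    single-head cross-attention with the decoder residual."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm_q = LayerNorm(dim)
        self.norm_kv = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)

    def __call__(self, dec_tokens: Tensor, enc_tokens: Tensor) -> Tensor:
        q = self.wq(self.norm_q(dec_tokens))
        k = self.wk(self.norm_kv(enc_tokens))
        v = self.wv(self.norm_kv(enc_tokens))
        return cross_attention_fuse(q, k, v, dec_tokens)


class BoundaryEnhance(Module):
    """Parallel dilated 3x3 convolutions (dilations 1, 2, 4) fused by a 1x1
    projection and a sigmoid; emits a (B, 1, H, W) edge-probability map."""

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int = 8):
        super().__init__()
        self.d1 = Conv2d(channels, hidden, 3, rng, padding=1, dilation=1)
        self.d2 = Conv2d(channels, hidden, 3, rng, padding=2, dilation=2)
        self.d4 = Conv2d(channels, hidden, 3, rng, padding=4, dilation=4)
        self.fuse = Conv2d(3 * hidden, 1, 1, rng)

    def __call__(self, f: Tensor) -> Tensor:
        branches = concat([self.d1(f).gelu(), self.d2(f).gelu(),
                           self.d4(f).gelu()], axis=1)
        return self.fuse(branches).sigmoid()


class ConvEncoder(Module):
    """Plain convolutional pyramid used by the no-attention ablation: four
    stride-2 stages after a patch-size stem, same dims/scales as the
    windowed-attention encoder."""

    def __init__(self, profile: ModelProfile, image_size: int,
                 in_channels: int = 1, seed: int = 0):
        super().__init__()
        profile.validate(image_size)
        self.profile = profile
        rng = np.random.default_rng(seed)
        dims = profile.embed_dims
        self.stem = Conv2d(in_channels, dims[0], profile.patch_size, rng,
                           stride=profile.patch_size)
        self.convs = [Conv2d(dims[i], dims[i], 3, rng, padding=1) for i in range(4)]
        self.downs = [Conv2d(dims[i], dims[i + 1], 2, rng, stride=2)
                      for i in range(3)]
        self.attention_maps: list = []

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = []
        z = self.stem(x)
        for s in range(4):
            z = self.convs[s](z).gelu() + z
            feats.append(z.transpose(0, 2, 3, 1))  # (B, H, W, C) like the encoder
            if s < 3:
                z = self.downs[s](z)
        self.attention_maps = []
        return feats


def _tokens(f: Tensor) -> tuple[Tensor, int, int]:
    b, h, w, c = f.shape
    return f.reshape(b, h * w, c), h, w


class SegmentationModel(Module):
    """Full segmentation graph with ablation switches.

    use_swin=False swaps in the convolutional encoder; use_cross_attention=
    False removes the decoder pyramid entirely (direct upsampling head from
    the deepest feature); gamma_modulation controls the channel gating
    ("deepest" default, "all" or "off").
    """

    def __init__(self, profile: ModelProfile, image_size: int,
                 in_channels: int = 1, seed: int = 0, use_swin: bool = True,
                 use_cross_attention: bool = True,
                 gamma_modulation: str = "deepest"):
        super().__init__()
        if gamma_modulation not in ("deepest", "all", "off"):
            raise ValueError("gamma_modulation must be deepest/all/off")
        self.profile = profile
        self.image_size = image_size
        self.gamma_mode = gamma_modulation
        self.use_cross_attention = use_cross_attention
        rng = np.random.default_rng(seed + 7)
        dims = profile.embed_dims
        enc_cls = SwinEncoder if use_swin else ConvEncoder
        self.encoder = enc_cls(profile, image_size, in_channels=in_channels, seed=seed)
        if gamma_modulation == "deepest":
            self.gammas = [GammaModulation(dims[3], rng)]
        elif gamma_modulation == "all":
            self.gammas = [GammaModulation(d, rng) for d in dims]
        else:
            self.gammas = []
        n_cls = profile.seg_classes
        if use_cross_attention:
            self.up_proj = [Linear(dims[i + 1], dims[i], rng) for i in range(3)]
            self.skips = [CrossAttentionSkip(dims[i], rng) for i in range(3)]
            self.refine = [MLP(dims[i], int(dims[i] * 2), rng,
                               dropout=profile.dropout, seed=seed + 31 * i)
                           for i in range(3)]
            self.deep_heads = [Linear(dims[i], n_cls, rng) for i in range(3)]
        else:
            self.direct_proj = Linear(dims[3], dims[0], rng)
        self.boundary = BoundaryEnhance(dims[0], rng)
        # full-resolution refinement: upsampled decoder features concatenated
        # with the raw input channels recover pixel-level boundary detail
        self.final_conv1 = Conv2d(dims[0] + in_channels, dims[0], 3, rng, padding=1)
        self.final_conv2 = Conv2d(dims[0], n_cls, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> dict:
        """x: (B, C, H, W).  Returns dict with final logits at input
        resolution, deep-supervision logits (coarse->fine), the boundary
        map, and retained attention maps."""
        feats = self.encoder(x)  # (B,H,W,C) x4, fine->coarse
        if self.gamma_mode == "deepest":
            f3 = feats[3].transpose(0, 3, 1, 2)
            feats[3] = self.gammas[0](f3).transpose(0, 2, 3, 1)
        elif self.gamma_mode == "all":
            for i in range(4):
                fi = feats[i].transpose(0, 3, 1, 2)
                feats[i] = self.gammas[i](fi).transpose(0, 2, 3, 1)
        deep_logits: list[Tensor] = []
        if self.use_cross_attention:
            z = feats[3]
            for lvl in (2, 1, 0):
                zc = z.transpose(0, 3, 1, 2).upsample2x()  # (B, C, 2h, 2w)
                zt = zc.transpose(0, 2, 3, 1)
                zt = self.up_proj[lvl](zt)
                dec_tok, h, w = _tokens(zt)
                enc_tok, _, _ = _tokens(feats[lvl])
                fused = self.skips[lvl](dec_tok, enc_tok)
                fused = fused + self.refine[lvl](fused)
                z = fused.reshape(zt.shape[0], h, w, -1)
                deep_logits.append(
                    self.deep_heads[lvl](z).transpose(0, 3, 1, 2))
            top = z.transpose(0, 3, 1, 2)  # (B, C0, H/4, W/4)
        else:
            # direct decoder: repeated upsampling of the deepest feature
            z = feats[3].transpose(0, 3, 1, 2)
            for _ in range(3):
                z = z.upsample2x()
            b, c, h, w = z.shape
            zt = z.transpose(0, 2, 3, 1).reshape(b, h * w, c)
            zt = self.direct_proj(zt)
            top = zt.reshape(b, h, w, -1).transpose(0, 3, 1, 2)
        boundary = self.boundary(top)
        full = top.upsample2x().upsample2x()
        full = concat([full, x], axis=1)
        logits = self.final_conv2(self.final_conv1(full).gelu())
        return {"logits": logits, "deep_supervision": deep_logits,
                "boundary": boundary,
                "attention_maps": self.encoder.attention_maps,
                "gamma_stats": [g.last_stats for g in self.gammas]}
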