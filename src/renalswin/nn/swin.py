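"""Hierarchical windowed-attention encoder.

Tokens live on a 2-D grid as (B, H, W, C) tensors.  Each stage applies
Swin-style blocks — pre-norm windowed multi-head self-attention with a
residual, then a pre-norm feed-forward with a residual — alternating plain
(W-MSA) and shifted (SW-MSA) windows, with relative position bias inside
windows and a learned absolute position embedding after patch embedding.
Between stages, 2x2 patch merging halves the grid and doubles the channel
width, yielding features at 1/4, 1/8, 1/16 and 1/32 of input resolution.

Options mirroring the architecture's published variants: a convolutional
feed-forward (3x3 conv between the two projections, keeping spatial
layout), and learnable memory tokens appended as extra attention keys and
values so every token can read a global context slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .layers import MLP, Conv2d, LayerNorm, Linear, Module

__all__ = ["ModelProfile", "PROFILES", "count_patches", "WindowAttention",
           "SwinBlock", "PatchEmbed", "PatchMerging", "SwinEncoder"]


@dataclass
class ModelProfile:
    """Architecture hyperparameters for one model size."""

    name: str = "tiny"
    patch_size: int = 4
    embed_dims: tuple[int, ...] = (16, 32, 64, 128)
    depths: tuple[int, ...] = (1, 1, 1, 1)
    num_heads: int = 2
    window_size: int = 4
    memory_tokens: int = 2
    conv_ffn: bool = False
    mlp_ratio: float = 2.0
    dropout: float = 0.1
    seg_classes: int = 3
    cls_classes: int = 4
    classifier_crop: int = 64

    def validate(self, image_size: int) -> None:
        if image_size % (self.patch_size * 8) != 0:
            raise ValueError(
                f"image_size {image_size} must be divisible by "
                f"patch_size*8 = {self.patch_size * 8} so four scales exist")


PROFILES = {
    "tiny": ModelProfile(),
    "full": ModelProfile(name="full", patch_size=4, embed_dims=(64, 128, 256, 512),
                         depths=(2, 2, 4, 2), num_heads=4, window_size=8,
                         memory_tokens=4, mlp_ratio=4.0, classifier_crop=224),
}


def count_patches(image_side: int, patch_side: int) -> int:
    """Number of non-overlapping patches covering a square image."""
    if image_side % patch_side != 0:
        raise ValueError(
            f"image side {image_side} not divisible by patch side {patch_side}")
    return (image_side // patch_side) ** 2


def _relative_index(ws: int) -> np.ndarray:
    """(ws^2, ws^2) index into the (2ws-1)^2 relative position bias table."""
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel + (ws - 1)
    return rel[0] * (2 * ws - 1) + rel[1]


def _shift_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive attention mask (n_windows, ws^2, ws^2) for shifted windows."""
    region = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for wsl in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            region[hs, wsl] = cnt
            cnt += 1
    region = np.roll(region, (-shift, -shift), axis=(0, 1))
    win = region.reshape(h // ws, ws, w // ws, ws).transpose(0, 2, 1, 3)
    win = win.reshape(-1, ws * ws)
    mask = win[:, :, None] != win[:, None, :]
    return np.where(mask, -1e9, 0.0)


def window_partition(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nWin, ws*ws, C)."""
    b, h, w, c = x.shape
    x = x.reshape(b, h // ws, ws, w // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // ws) * (w // ws), ws * ws, c)


def window_reverse(x: Tensor, ws: int, b: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(b, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, c)


class WindowAttention(Module):
    """Multi-head self-attention within windows, with relative position bias
    and optional global memory tokens as extra keys/values."""

    def __init__(self, dim: int, heads: int, ws: int, rng: np.random.Generator,
                 memory_tokens: int = 0):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.ws = dim, heads, ws
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = Tensor(np.zeros(((2 * ws - 1) ** 2, heads)),
                               requires_grad=True)
        self.rel_index = _relative_index(ws)
        self.n_memory = memory_tokens
        if memory_tokens:
            self.memory = Tensor(rng.normal(0, 0.02, (memory_tokens, dim)),
                                 requires_grad=True)
            self.mem_kv = Linear(dim, 2 * dim, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw, t, c = xw.shape
        h, d = self.heads, self.head_dim
        qkv = self.qkv(xw).reshape(bw, t, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (bw, h, t, d)
        logits = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = self.rel_bias[self.rel_index.ravel()].reshape(t, t, h)
        logits = logits + bias.transpose(2, 0, 1).reshape(1, h, t, t)
        if mask is not None:
            nw = mask.shape[0]
            logits = logits.reshape(bw // nw, nw, h, t, t) + \
                Tensor(mask[None, :, None, :, :])
            logits = logits.reshape(bw, h, t, t)
        if self.n_memory:
            kv = self.mem_kv(self.memory)
            kv = kv.reshape(self.n_memory, 2, h, d).transpose(1, 2, 0, 3)
            mk, mv = kv[0], kv[1]  # (h, M, d)
            mem_logits = (q @ mk.transpose(0, 2, 1).reshape(1, h, d, self.n_memory)) \
                * self.scale
            logits = concat([logits, mem_logits], axis=-1)
            attn = logits.softmax(axis=-1)
            a_tok = attn[:, :, :, :t]
            a_mem = attn[:, :, :, t:]
            out = a_tok @ v + a_mem @ mv.reshape(1, h, self.n_memory, d)
        else:
            attn = logits.softmax(axis=-1)
            out = attn @ v
        self.last_attention = attn.data
        out = out.transpose(0, 2, 1, 3).reshape(bw, t, c)
        return self.proj(out)


class ConvFFN(Module):
    """Feed-forward with a 3x3 convolution between projections (keeps spatial
    layout), used when the profile asks for convolutional FFNs."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.conv = Conv2d(hidden, hidden, 3, rng, padding=1)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor, h: int, w: int) -> Tensor:
        b = x.shape[0]
        y = self.fc1(x).gelu()
        grid = y.reshape(b, h, w, -1).transpose(0, 3, 1, 2)
        grid = self.conv(grid).gelu()
        y = grid.transpose(0, 2, 3, 1).reshape(b, h * w, -1)
        return self.fc2(y)


class SwinBlock(Module):
    """One (shifted-)window attention block: the standard two-residual layout
    z' = (S)W-MSA(LN(z)) + z ; z'' = FFN(LN(z')) + z'."""

    def __init__(self, dim: int, heads: int, ws: int, shifted: bool,
                 rng: np.random.Generator, mlp_ratio: float = 2.0,
                 conv_ffn: bool = False, memory_tokens: int = 0,
                 dropout: float = 0.0, seed: int = 0):
        super().__init__()
        self.ws = ws
        self.shifted = shifted
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, ws, rng, memory_tokens)
        self.norm2 = LayerNorm(dim)
        self.conv_ffn = conv_ffn
        if conv_ffn:
            self.ffn = ConvFFN(dim, int(dim * mlp_ratio), rng)
        else:
            self.ffn = MLP(dim, int(dim * mlp_ratio), rng, dropout=dropout, seed=seed)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        ws = self.ws
        if ws > min(h, w):
            raise ValueError(
                f"window {ws} larger than token grid {h}x{w}; "
                f"use a profile whose windows fit every stage")
        if h % ws or w % ws:
            raise ValueError(f"token grid {h}x{w} incompatible with window {ws}")
        shift = ws // 2 if (self.shifted and ws < min(h, w)) else 0
        z = self.norm1(x)
        if shift:
            z = z.roll((-shift, -shift), axis=(1, 2))
            mask = _shift_mask(h, w, ws, shift)
        else:
            mask = None
        zw = window_partition(z, ws)
        aw = self.attn(zw, mask=mask)
        a = window_reverse(aw, ws, b, h, w)
        if shift:
            a = a.roll((shift, shift), axis=(1, 2))
        x = x + a
        zt = self.norm2(x).reshape(b, h * w, c)
        if self.conv_ffn:
            y = self.ffn(zt, h, w)
        else:
            y = self.ffn(zt)
        return x + y.reshape(b, h, w, c)


class PatchEmbed(Module):
    """Non-overlapping patch projection plus learned absolute positions."""

    def __init__(self, in_ch: int, dim: int, patch: int, grid: int,
                 rng: np.random.Generator):
        super().__init__()
        self.patch = patch
        self.proj = Linear(in_ch * patch * patch, dim, rng)
        self.abs_pos = Tensor(rng.normal(0, 0.02, (grid, grid, dim)),
                              requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        p = self.patch
        x = x.reshape(b, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(b, h // p, w // p, c * p * p)
        return self.proj(x) + self.abs_pos


class PatchMerging(Module):
    """2x2 token merge: concat neighbours, LayerNorm, project 4C -> 2C."""

    def __init__(self, dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.proj = Linear(4 * dim, out_dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.proj(self.norm(x))


class SwinEncoder(Module):
    """Four-stage hierarchical encoder producing features at 1/4..1/32 scale.

    Attention maps of every block are retained after each forward pass in
    ``attention_maps`` (stage -> list of (bw, heads, T, T+M) arrays).
    """

    def __init__(self, profile: ModelProfile, image_size: int,
                 in_channels: int = 1, seed: int = 0):
        super().__init__()
        profile.validate(image_size)
        self.profile = profile
        self.image_size = image_size
        rng = np.random.default_rng(seed)
        dims = profile.embed_dims
        grid = image_size // profile.patch_size
        self.embed = PatchEmbed(in_channels, dims[0], profile.patch_size, grid, rng)
        self.stages: list[list[SwinBlock]] = []
        self.mergers: list[PatchMerging] = []
        blocks_flat = []
        mergers = []
        for s in range(4):
            stage_grid = grid // (2 ** s)
            ws_s = min(profile.window_size, stage_grid)
            stage_blocks = []
            for i in range(profile.depths[s]):
                stage_blocks.append(SwinBlock(
                    dims[s], profile.num_heads, ws_s,
                    shifted=(i % 2 == 1), rng=rng, mlp_ratio=profile.mlp_ratio,
                    conv_ffn=profile.conv_ffn,
                    memory_tokens=profile.memory_tokens,
                    dropout=profile.dropout, seed=seed + 101 * s + i))
            self.stages.append(stage_blocks)
            blocks_flat.extend(stage_blocks)
            if s < 3:
                mergers.append(PatchMerging(dims[s], dims[s + 1], rng))
        self.mergers = mergers
        self._all_blocks = blocks_flat  # registers parameters
        self._all_mergers = mergers
        self.attention_maps: list[list[np.ndarray]] = []

    def __call__(self, x: Tensor) -> list[Tensor]:
        """x: (B, C, H, W) -> list of 4 stage features (B, H_l, W_l, C_l)."""
        feats = []
        self.attention_maps = []
        z = self.embed(x)
        for s in range(4):
            stage_attn = []
            for blk in self.stages[s]:
                z = blk(z)
                stage_attn.append(blk.attn.last_attention)
            self.attention_maps.append(stage_attn)
            feats.append(z)
            if s < 3:
                z = self.mergers[s](z)
        return feats
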