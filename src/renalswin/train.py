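"""Losses, optimization and the two-stage training protocol.

Stage 1 trains the segmentation network with Dice + boundary-weighted
cross-entropy, deep supervision at the intermediate decoder heads and an
edge-map loss on the boundary branch; stage 2 trains the pyramid classifier
on lesion crops with class-weighted cross-entropy and balanced sampling.
The published recipes (AdamW, cosine annealing, early stopping) are the
defaults; the ``tiny`` recipe scales the schedule for CPU-sized phantom
runs.  Everything is reproducible from (config, seed): batch order, dropout
and augmentation draws all derive from the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, distance_transform_edt

from .augment import AugmentationSpec, lesion_aware_oversample
from .manifest import CLASSES, DatasetManifest
from .metrics import overlap_metrics
from .nn.autodiff import Tensor, no_grad
from .nn.classifier import (PyramidClassifier, prepare_crop,
                            prepare_crop_with_shape)
from .nn.segmodel import SegmentationModel

__all__ = ["SegLossSpec", "TrainConfig", "TrainState", "dice_loss",
           "boundary_weighted_bce", "total_seg_loss", "AdamW",
           "cosine_lr", "warmup_cosine_lr", "clip_grad_norm", "kfold_split",
           "train_segmentation", "train_classifier", "SEG_RECIPE",
           "CLS_RECIPE", "TINY_SEG_RECIPE", "TINY_CLS_RECIPE"]

log = logging.getLogger(__name__)


@dataclass
class SegLossSpec:
    dice_weight: float = 1.0
    bce_weight: float = 1.0
    boundary_band_px: int = 3
    boundary_boost: float = 4.0
    deep_supervision_weights: tuple[float, ...] = (0.4, 0.3, 0.3)  # shallow->deep
    boundary_branch_weight: float = 0.5
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.dice_weight < 0 or self.bce_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.dice_weight == 0 and self.bce_weight == 0:
            raise ValueError("at least one of dice/bce weight must be positive")


@dataclass
class TrainConfig:
    """One training stage's hyperparameters (defaults: published stage 1)."""

    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 8
    epochs: int = 200
    patience: int = 20
    clip_norm: float = 1.0
    warmup_frac: float = 0.0
    dropout: float = 0.1
    seed: int = 0


SEG_RECIPE = TrainConfig()
CLS_RECIPE = TrainConfig(lr=2e-5, weight_decay=0.001, batch_size=16,
                         epochs=100, patience=15, warmup_frac=0.05)
# CPU-sized phantom schedules: larger lr and few epochs suit the tiny model
TINY_SEG_RECIPE = TrainConfig(lr=3e-3, epochs=12, patience=6, batch_size=8)
TINY_CLS_RECIPE = TrainConfig(lr=1e-3, weight_decay=0.001, batch_size=16,
                              epochs=30, patience=12, warmup_frac=0.1)


@dataclass
class TrainState:
    epoch: int = 0
    best_metric: float = -np.inf
    patience_counter: int = 0
    history: list[dict] = field(default_factory=list)
    best_state: dict | None = None
    stopped_early: bool = False


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))


def dice_loss(pred, target, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss, per-class mean for (C, ...) probability maps.

    pred in [0,1]; target binary with the same shape.  The smooth constant
    stabilizes empty classes (both-empty -> loss 0).
    """
    p, t = _lift(pred), _lift(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.ndim == 2:
        p = p.reshape(1, *p.shape)
        t = t.reshape(1, *t.shape)
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (inter * 2.0 + smooth) / (denom + smooth)
    return (1.0 - dice).mean()


def boundary_weight_map(target: np.ndarray, band_px: int, boost: float) -> np.ndarray:
    """1 + boost inside a ``band_px`` distance band around label edges."""
    t = np.asarray(target)
    w = np.ones(t.shape, dtype=np.float64)
    edges = np.zeros(t.shape, dtype=bool)
    for lab in np.unique(t):
        region = t == lab
        # border_value=1: the label field continues past the image edge,
        # so image borders are not label edges
        edges |= region & ~binary_erosion(region, border_value=1)
    if edges.any():
        dist = distance_transform_edt(~edges)
        w += boost * (dist <= band_px)
    return w


def boundary_weighted_bce(pred, target, spec: SegLossSpec) -> Tensor:
    """Pixel BCE scaled by the boundary band weight map, mean over pixels.

    2-D inputs are treated as binary foreground probabilities; (C, H, W)
    inputs as per-class one-vs-rest probabilities against a label mask or
    one-hot target.
    """
    p = _lift(pred)
    t_arr = np.asarray(target.data if isinstance(target, Tensor) else target, float)
    if p.ndim == 2:
        probs = p.reshape(1, *p.shape)
        onehot = t_arr.reshape(1, *t_arr.shape)
        labels = t_arr
    else:
        probs = p
        c = p.shape[0]
        if t_arr.ndim == 2:  # label mask -> one-hot
            onehot = np.stack([(t_arr == k).astype(float) for k in range(c)])
            labels = t_arr
        else:
            onehot = t_arr
            labels = t_arr.argmax(axis=0)
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {onehot.shape}")
    w = boundary_weight_map(labels, spec.boundary_band_px, spec.boundary_boost)
    eps = 1e-7
    pc = probs * (1 - 2 * eps) + eps
    bce = -(Tensor(onehot) * pc.log() + Tensor(1.0 - onehot) * (1.0 - pc).log())
    return (bce * Tensor(w[None, :, :])).mean()


def _edge_map(target: np.ndarray) -> np.ndarray:
    fg = np.asarray(target) > 0
    if not fg.any():
        return np.zeros(fg.shape, float)
    return (binary_dilation(fg) & ~binary_erosion(fg, border_value=0)).astype(float)


def _downsample_labels(t: np.ndarray, factor: int) -> np.ndarray:
    return t[::factor, ::factor]


def total_seg_loss(outputs: dict, target: np.ndarray, spec: SegLossSpec,
                   sample_index: int = 0) -> tuple[Tensor, dict]:
    """Weighted sum over the final head, deep-supervision heads (at matching
    downsampled targets) and the boundary branch.  Returns (total, breakdown)
    with the breakdown summing to the total."""
    t = np.asarray(target)
    n_cls = outputs["logits"].shape[1]
    probs = outputs["logits"][sample_index].softmax(axis=0)
    onehot = np.stack([(t == k).astype(float) for k in range(n_cls)])
    parts: dict[str, Tensor] = {}
    main = spec.dice_weight * dice_loss(probs, onehot, spec.smooth) \
        + spec.bce_weight * boundary_weighted_bce(probs, t, spec)
    parts["final"] = main
    deep = outputs.get("deep_supervision") or []
    # heads are ordered coarse->fine; weights are shallow->deep
    ds_weights = list(spec.deep_supervision_weights)[::-1]
    for head, wgt in zip(deep, ds_weights):
        factor = t.shape[0] // head.shape[2]
        td = _downsample_labels(t, factor)
        hp = head[sample_index].softmax(axis=0)
        oh = np.stack([(td == k).astype(float) for k in range(n_cls)])
        parts[f"deep_{head.shape[2]}"] = wgt * (
            spec.dice_weight * dice_loss(hp, oh, spec.smooth)
            + spec.bce_weight * boundary_weighted_bce(hp, td, spec))
    bmap = outputs.get("boundary")
    if bmap is not None and spec.boundary_branch_weight > 0:
        factor = t.shape[0] // bmap.shape[2]
        edge = _edge_map(_downsample_labels(t, factor))
        bp = bmap[sample_index, 0]
        eps = 1e-7
        bpc = bp * (1 - 2 * eps) + eps
        bce = -(Tensor(edge) * bpc.log() + Tensor(1.0 - edge) * (1.0 - bpc).log())
        parts["boundary"] = spec.boundary_branch_weight * bce.mean()
    total = None
    for v in parts.values():
        total = v if total is None else total + v
    breakdown = {k: float(v.data) for k, v in parts.items()}
    return total, breakdown


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    """Cosine annealing from base_lr to ~0 over the run."""
    frac = min(step / max(total_steps, 1), 1.0)
    return base_lr * 0.5 * (1 + np.cos(np.pi * frac))


def warmup_cosine_lr(base_lr: float, step: int, total_steps: int,
                     warmup_frac: float = 0.05) -> float:
    warm = max(int(warmup_frac * total_steps), 1)
    if step < warm:
        return base_lr * (step + 1) / warm
    return cosine_lr(base_lr, step - warm, total_steps - warm)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def kfold_split(manifest: DatasetManifest, k: int = 5,
                seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """Stratified k-fold over the train+val pool (test split held out).

    Returns per-fold (train_indices, val_indices) into manifest.records.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pool = [i for i, r in enumerate(manifest.records) if r.split != "test"]
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i in pool:
        by_class.setdefault(manifest.records[i].class_label, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls, idxs in sorted(by_class.items()):
        if len(idxs) < k:
            raise ValueError(f"class {cls!r} has {len(idxs)} records < k={k}")
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        for j, i in enumerate(idxs):
            folds[j % k].append(int(i))
    out = []
    for j in range(k):
        val = sorted(folds[j])
        train = sorted(i for jj in range(k) if jj != j for i in folds[jj])
        out.append((train, val))
    return out


# --------------------------------------------------------------------------
# training loops
# --------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """In-memory dataset: aligned lists of images (H, W) in [0, 1], masks,
    class indices and optional gamma feature maps."""

    images: list[np.ndarray]
    masks: list[np.ndarray]
    class_idx: list[int]
    gamma_maps: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.images)

    def stack_input(self, idx: list[int]) -> np.ndarray:
        """(B, C, H, W) network input, gamma map as a second channel."""
        imgs = [self.images[i] for i in idx]
        if self.gamma_maps is not None:
            return np.stack([np.stack([im, self.gamma_maps[i]])
                             for im, i in zip(imgs, idx)])
        return np.stack([im[None] for im in imgs])


def _macro_dice(pred_labels: np.ndarray, target: np.ndarray,
                labels=(1, 2)) -> float:
    return float(np.mean([overlap_metrics(pred_labels, target, label=c)["dice"]
                          for c in labels]))


def evaluate_seg(model: SegmentationModel, data: ArrayDataset,
                 indices: list[int], batch: int = 8) -> float:
    """Mean macro Dice (kidney+lesion) over the given records."""
    model.eval()
    if not len(indices):
        return float("nan")
    scores = []
    with no_grad():
        for s in range(0, len(indices), batch):
            idx = list(indices[s:s + batch])
            x = Tensor(data.stack_input(idx))
            out = model(x)
            pred = out["logits"].data.argmax(axis=1)
            for bi, i in enumerate(idx):
                scores.append(_macro_dice(pred[bi], data.masks[i]))
    return float(np.mean(scores))


def train_segmentation(model: SegmentationModel, data: ArrayDataset,
                       train_idx: list[int], val_idx: list[int],
                       cfg: TrainConfig, loss_spec: SegLossSpec | None = None,
                       ) -> TrainState:
    """Stage-1 loop: AdamW, cosine-annealed lr, gradient clipping, early
    stopping on validation macro Dice."""
    if not val_idx:
        raise ValueError("no validation records; cannot early-stop")
    loss_spec = loss_spec or SegLossSpec()
    params = model.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    state = TrainState()
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = np.array(train_idx)
        rng.shuffle(order)
        epoch_loss = 0.0
        for s in range(0, len(order), cfg.batch_size):
            idx = list(order[s:s + cfg.batch_size])
            x = Tensor(data.stack_input(idx))
            out = model(x)
            total = None
            breakdowns = []
            for bi, i in enumerate(idx):
                li, br = total_seg_loss(out, data.masks[i], loss_spec,
                                        sample_index=bi)
                total = li if total is None else total + li
                breakdowns.append(br)
            total = total * (1.0 / len(idx))
            model.zero_grad()
            total.backward()
            clip_grad_norm(params, cfg.clip_norm)
            opt.lr = cosine_lr(cfg.lr, step, total_steps)
            opt.step()
            epoch_loss += float(total.data)
            step += 1
        val_dice = evaluate_seg(model, data, val_idx,
                                batch=cfg.batch_size)
        state.epoch = epoch
        mean_loss = epoch_loss / steps_per_epoch
        state.history.append({"epoch": epoch, "train_loss": mean_loss,
                              "val_dice": val_dice, "lr": opt.lr})
        log.info("seg epoch %d loss %.4f val dice %.4f", epoch, mean_loss, val_dice)
        if val_dice > state.best_metric + 1e-6:
            state.best_metric = val_dice
            state.best_state = model.state_dict()
            state.patience_counter = 0
        else:
            state.patience_counter += 1
            if state.patience_counter >= cfg.patience:
                state.stopped_early = True
                break
    if state.best_state is not None:
        model.load_state_dict(state.best_state)
    return state


@dataclass
class CropDataset:
    """Classifier crops with integer class labels.

    Crops are (S, S) single-channel or (C, S, S) multi-channel arrays; the
    default pipeline uses two channels (image + segmented-region shape)."""

    crops: list[np.ndarray]
    labels: list[int]

    def __len__(self) -> int:
        return len(self.crops)

    def stack(self, idx) -> np.ndarray:
        """(B, C, S, S) batch from crop indices."""
        arrs = [self.crops[i] for i in idx]
        return np.stack([a[None] if a.ndim == 2 else a for a in arrs])

    @classmethod
    def from_arrays(cls, data: ArrayDataset, indices: list[int],
                    crop_size: int, masks: list[np.ndarray] | None = None,
                    with_shape: bool = True) -> "CropDataset":
        """Build crops around lesions (label 2) or the kidney (label 1) using
        the given masks (defaults to ground truth: teacher forcing)."""
        src_masks = masks if masks is not None else data.masks
        crops, labels = [], []
        for i in indices:
            if with_shape:
                crops.append(prepare_crop_with_shape(
                    data.images[i], src_masks[i], crop_size))
            else:
                crops.append(prepare_crop(data.images[i], src_masks[i],
                                          crop_size))
            labels.append(data.class_idx[i])
        return cls(crops, labels)


def class_weights(labels: list[int], n_classes: int) -> np.ndarray:
    """Inverse-frequency class weights, mean-normalized."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    if not present.all():
        missing = [CLASSES[i] if i < len(CLASSES) else str(i)
                   for i in np.where(~present)[0]]
        raise ValueError(f"classes absent from the training split: {missing}")
    w = 1.0 / counts
    return w / w.mean()


def evaluate_cls(model: PyramidClassifier, data: CropDataset,
                 batch: int = 16) -> dict:
    model.eval()
    if not len(data):
        return {"accuracy": float("nan"), "macro_f1": float("nan"),
                "probs": np.zeros((0, model.profile.cls_classes))}
    preds, probs_all = [], []
    with no_grad():
        for s in range(0, len(data), batch):
            x = Tensor(data.stack(range(s, min(s + batch, len(data)))))
            probs = model(x).data
            probs_all.append(probs)
            preds.extend(probs.argmax(axis=1).tolist())
    y = np.array(data.labels)
    preds = np.array(preds)
    f1s = []
    for k in range(model.profile.cls_classes if not model.binary_head else 2):
        tp = np.sum((preds == k) & (y == k))
        fp = np.sum((preds == k) & (y != k))
        fn = np.sum((preds != k) & (y == k))
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return {"accuracy": float(np.mean(preds == y)),
            "macro_f1": float(np.mean(f1s)),
            "probs": np.concatenate(probs_all)}


def train_classifier(model: PyramidClassifier, train_data: CropDataset,
                     val_data: CropDataset, cfg: TrainConfig,
                     manifest: DatasetManifest | None = None,
                     lesion_areas: dict | None = None,
                     aug_spec: AugmentationSpec | None = None,
                     ) -> TrainState:
    """Stage-2 loop: class-weighted cross-entropy, warm-up + cosine decay,
    balanced sampling, early stopping on validation macro F1."""
    n_classes = 2 if model.binary_head else model.profile.cls_classes
    cw = class_weights(train_data.labels, n_classes)
    params = model.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(train_data)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    # balanced sampling weights; lesion-aware when a manifest is supplied
    if manifest is not None and lesion_areas is not None:
        image_area = train_data.crops[0].size
        weights = lesion_aware_oversample(manifest, lesion_areas,
                                          aug_spec or AugmentationSpec(),
                                          image_area)
    else:
        wl = cw[np.array(train_data.labels)]
        weights = wl / wl.sum()
    state = TrainState()
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        epoch_loss = 0.0
        for _ in range(steps_per_epoch):
            idx = rng.choice(n, size=min(cfg.batch_size, n), replace=True,
                             p=weights)
            x = Tensor(train_data.stack(idx))
            y = np.array([train_data.labels[i] for i in idx])
            logits = model.forward_logits(x)
            logp = logits.log_softmax(axis=-1)
            onehot = np.zeros(logp.shape)
            onehot[np.arange(len(y)), y] = cw[y]
            loss = -(logp * Tensor(onehot)).sum() * (1.0 / len(y))
            model.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.clip_norm)
            opt.lr = warmup_cosine_lr(cfg.lr, step, total_steps, cfg.warmup_frac)
            opt.step()
            epoch_loss += float(loss.data)
            step += 1
        val = evaluate_cls(model, val_data, batch=cfg.batch_size)
        state.epoch = epoch
        state.history.append({"epoch": epoch,
                              "train_loss": epoch_loss / steps_per_epoch,
                              "val_macro_f1": val["macro_f1"],
                              "val_accuracy": val["accuracy"], "lr": opt.lr})
        log.info("cls epoch %d loss %.4f val f1 %.4f acc %.4f", epoch,
                 epoch_loss / steps_per_epoch, val["macro_f1"], val["accuracy"])
        if val["macro_f1"] > state.best_metric + 1e-6:
            state.best_metric = val["macro_f1"]
            state.best_state = model.state_dict()
            state.patience_counter = 0
        else:
            state.patience_counter += 1
            if state.patience_counter >= cfg.patience:
                state.stopped_early = True
                break
    if state.best_state is not None:
        model.load_state_dict(state.best_state)
    return state
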