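"""Run configuration: YAML loading, defaults, validation, seeding."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import random
from dataclasses import dataclass, field

import numpy as np
import yaml

from .augment import AugmentationSpec
from .nn.swin import PROFILES, ModelProfile
from .train import CLS_RECIPE, SEG_RECIPE, SegLossSpec, TrainConfig

__all__ = ["RunConfig", "load_config", "seed_everything", "config_hash",
           "setup_logging"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved run configuration.

    ``image_size`` must be divisible by ``patch_size * 8`` so the encoder's
    four scales exist.  ``patch_size`` here is the embedding patch of the
    hierarchical encoder (4); the coarse 16-px patch arithmetic is exposed
    separately through :func:`renalswin.nn.swin.count_patches`.
    """

    image_size: int = 512
    patch_size: int = 4
    profile: str = "full"
    seed: int = 0
    stage1: TrainConfig = field(default_factory=lambda: TrainConfig(**SEG_RECIPE.__dict__))
    stage2: TrainConfig = field(default_factory=lambda: TrainConfig(**CLS_RECIPE.__dict__))
    seg_loss: SegLossSpec = field(default_factory=SegLossSpec)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    use_gamma_maps: bool = True
    gamma_max_k: int = 6

    def __post_init__(self) -> None:
        if self.image_size % (self.patch_size * 8) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by "
                f"patch_size*8 = {self.patch_size * 8}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; "
                             f"choose from {sorted(PROFILES)}")

    def model_profile(self) -> ModelProfile:
        return PROFILES[self.profile]


_NESTED = {"stage1": TrainConfig, "stage2": TrainConfig,
           "seg_loss": SegLossSpec, "augmentation": AugmentationSpec}


def _build(cls, payload: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    coerced = {}
    for k, v in payload.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load YAML config, fill defaults, apply overrides last.

    Unknown keys raise; an empty (or absent) file yields the documented
    defaults.  Overrides use dotted keys for nested blocks, e.g.
    ``{"stage1.lr": 3e-3, "seed": 7}``.
    """
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config {path} must be a mapping")
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = payload
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    nested = {}
    for name, cls in _NESTED.items():
        sub = payload.pop(name, {})
        if not isinstance(sub, dict):
            raise ValueError(f"config block {name!r} must be a mapping")
        nested[name] = _build(cls, sub, name)
    cfg = _build(RunConfig, {**payload, **nested}, "top level")
    log.info("resolved config: %s", config_hash(cfg))
    return cfg


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(x) for x in obj]
    return obj


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the resolved configuration (provenance manifests)."""
    blob = json.dumps(_as_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def seed_everything(seed: int) -> np.random.Generator:
    """Seed Python and NumPy global state; returns a fresh Generator too."""
    random.seed(seed)
    np.random.seed(seed % 2 ** 32)
    return np.random.default_rng(seed)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
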