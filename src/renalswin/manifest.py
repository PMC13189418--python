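"""Dataset manifests: the image/mask/label/split catalogue.

A manifest is a CSV (or JSON) table with columns ``image_path, mask_path,
class_label, split`` where ``class_label`` is one of the four renal classes
(normal, cyst, stone, tumor) and ``split`` partitions records into
train/val/test.  Class counts are always recomputed by tally, never trusted
from the file.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CLASSES", "SPLITS", "ManifestRecord", "DatasetManifest",
           "load_manifest", "validate_manifest", "save_manifest"]

log = logging.getLogger(__name__)

CLASSES = ("normal", "cyst", "stone", "tumor")
SPLITS = ("train", "val", "test")
_COLUMNS = ("image_path", "mask_path", "class_label", "split")


@dataclass
class ManifestRecord:
    image_path: str
    class_label: str
    split: str
    mask_path: str | None = None
    contrast: str | None = None  # optional difficulty tier tag


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(r.class_label for r in self.records)
        return {c: counts.get(c, 0) for c in CLASSES}

    @property
    def split_counts(self) -> dict[str, int]:
        counts = Counter(r.split for r in self.records)
        return {s: counts.get(s, 0) for s in SPLITS}

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_path": r.image_path,
                    "mask_path": r.mask_path if r.mask_path is not None else "",
                    "class_label": r.class_label,
                    "split": r.split,
                    "contrast": r.contrast if r.contrast is not None else "",
                }
                for r in self.records
            ]
        )


def _records_from_frame(df: pd.DataFrame, source: str) -> list[ManifestRecord]:
    missing = [c for c in _COLUMNS if c not in df.columns and c != "mask_path"]
    if missing:
        raise ValueError(f"manifest {source} missing required columns: {missing}")
    bad_class = df[~df["class_label"].isin(CLASSES)]
    if len(bad_class):
        rows = bad_class.index.tolist()[:20]
        raise ValueError(
            f"manifest {source}: unknown class labels "
            f"{sorted(set(bad_class['class_label']))} in rows {rows}"
        )
    bad_split = df[~df["split"].isin(SPLITS)]
    if len(bad_split):
        raise ValueError(
            f"manifest {source}: unknown split values "
            f"{sorted(set(bad_split['split']))} in rows {bad_split.index.tolist()[:20]}"
        )
    dupes = df["image_path"][df["image_path"].duplicated()]
    if len(dupes):
        log.warning("manifest %s: %d duplicate image_path rows retained", source, len(dupes))
    records = []
    for row in df.itertuples(index=False):
        mask = getattr(row, "mask_path", "") or None
        if isinstance(mask, float):  # NaN from pandas
            mask = None
        contrast = getattr(row, "contrast", "") or None
        if isinstance(contrast, float):
            contrast = None
        records.append(
            ManifestRecord(
                image_path=str(row.image_path),
                mask_path=mask,
                class_label=str(row.class_label),
                split=str(row.split),
                contrast=contrast,
            )
        )
    return records


def load_manifest(path: str) -> DatasetManifest:
    """Load a CSV or JSON manifest, rejecting unknown class labels."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest not found: {path}")
    if str(path).lower().endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["records"] if isinstance(payload, dict) else payload)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return DatasetManifest(_records_from_frame(df, str(path)))


def save_manifest(manifest: DatasetManifest, path: str) -> str:
    manifest.to_frame().to_csv(path, index=False)
    return path


def validate_manifest(manifest: DatasetManifest,
                      check_paths: bool = True,
                      root: str | None = None) -> dict:
    """Tally a manifest and report problems without raising.

    Returns ``{total, per_class, split_fractions, problems}`` where ``total``
    is the brute-force record count and split fractions are relative to it.
    """
    problems: list[str] = []
    total = len(manifest.records)
    if total == 0:
        return {"total": 0, "per_class": {c: 0 for c in CLASSES},
                "split_fractions": {s: 0.0 for s in SPLITS}, "problems": ["empty"]}
    per_class = manifest.class_counts
    split_fractions = {s: n / total for s, n in manifest.split_counts.items()}
    if check_paths:
        for i, rec in enumerate(manifest.records):
            p = rec.image_path if root is None else os.path.join(root, rec.image_path)
            if not os.path.exists(p):
                problems.append(f"row {i}: missing image {rec.image_path}")
            if rec.mask_path:
                mp = rec.mask_path if root is None else os.path.join(root, rec.mask_path)
                if not os.path.exists(mp):
                    problems.append(f"row {i}: missing mask {rec.mask_path}")
    return {"total": total, "per_class": per_class,
            "split_fractions": split_fractions, "problems": problems}
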