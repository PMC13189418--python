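"""Segmentation and classification metrics with bootstrap CIs.

Conventions that matter for lesion-free (normal) cases: when predicted and
reference masks are both empty, overlap metrics are defined as 1 (perfect
agreement on absence); boundary metrics are undefined on empty masks and
return NaN sentinels which aggregation excludes (the excluded count is
reported).  HD95 uses the pooled-directed-distance convention: the 95th
percentile of the union of both directed surface-distance sets; ASD is the
mean of the same pooled set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import SegMask

__all__ = ["overlap_metrics", "boundary_metrics", "classification_metrics",
           "bootstrap_ci", "MetricReport", "evaluate_segmentation"]

log = logging.getLogger(__name__)


def _binarize(mask: SegMask | np.ndarray, label: int | None) -> np.ndarray:
    arr = mask.labels if isinstance(mask, SegMask) else np.asarray(mask)
    if label is None:
        return arr > 0
    return arr == label


def overlap_metrics(pred: SegMask | np.ndarray, truth: SegMask | np.ndarray,
                    label: int | None = None) -> dict[str, float]:
    """Overlap metrics from pixel confusion counts.

    ``label`` selects one class (None = any foreground).  Both-empty masks
    give dice/iou/recall/precision 1 by convention.
    """
    p = _binarize(pred, label)
    t = _binarize(truth, label)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = float(np.sum(p & t))
    fp = float(np.sum(p & ~t))
    fn = float(np.sum(~p & t))
    tn = float(np.sum(~p & ~t))
    if tp + fp + fn == 0:
        log.debug("both masks empty: overlap metrics defined as 1")
        dice = iou = precision = recall = 1.0
    else:
        dice = 2 * tp / (2 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
        precision = tp / (tp + fp) if tp + fp > 0 else (1.0 if fn == 0 else 0.0)
        recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 1.0
    return {"dice": dice, "iou": iou, "precision": precision, "recall": recall,
            "sensitivity": recall, "specificity": specificity}


def _surface(mask: np.ndarray) -> np.ndarray:
    """Border pixels: mask minus its erosion."""
    if not mask.any():
        return np.zeros_like(mask)
    return mask & ~binary_erosion(mask, border_value=0)


def boundary_metrics(pred: SegMask | np.ndarray, truth: SegMask | np.ndarray,
                     spacing: tuple[float, float] = (1.0, 1.0),
                     label: int | None = None) -> dict[str, float]:
    """HD95 and ASD in physical units from pooled directed surface distances.

    Returns NaN sentinels (with a warning) when either mask is empty.
    """
    p = _binarize(pred, label)
    t = _binarize(truth, label)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        log.warning("boundary metrics undefined on empty mask; NaN sentinel")
        return {"hd95": float("nan"), "asd": float("nan")}
    ps, ts = _surface(p), _surface(t)
    # distance to the other surface, anisotropic spacing respected
    dt_t = distance_transform_edt(~ts, sampling=spacing)
    dt_p = distance_transform_edt(~ps, sampling=spacing)
    d_p_to_t = dt_t[ps]
    d_t_to_p = dt_p[ts]
    pooled = np.concatenate([d_p_to_t, d_t_to_p])
    return {"hd95": float(np.percentile(pooled, 95)),
            "asd": float(pooled.mean())}


def classification_metrics(y_true: np.ndarray, scores: np.ndarray,
                           class_names: list[str] | None = None) -> dict:
    """Accuracy, per-class precision/recall/F1, one-vs-rest AUCs, confusion matrix.

    ``y_true`` holds integer class indices; ``scores`` rows are class
    probabilities summing to 1.  AUC for a class absent from ``y_true`` (or
    covering all of it) is a NaN sentinel.
    """
    y_true = np.asarray(y_true, int)
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or len(y_true) != len(scores):
        raise ValueError("scores must be (n, K) aligned with y_true")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("score rows must sum to 1")
    n, K = scores.shape
    y_pred = scores.argmax(axis=1)
    acc = float(np.mean(y_pred == y_true))
    conf = np.zeros((K, K), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    per_class = {}
    for k in range(K):
        name = class_names[k] if class_names else str(k)
        tp = conf[k, k]
        fp = conf[:, k].sum() - tp
        fn = conf[k, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else float("nan")
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        binary = (y_true == k).astype(int)
        if 0 < binary.sum() < n:
            auc_roc = float(roc_auc_score(binary, scores[:, k]))
            auc_pr = float(average_precision_score(binary, scores[:, k]))
        else:
            auc_roc = auc_pr = float("nan")
        per_class[name] = {"precision": float(prec), "recall": float(rec),
                           "f1": float(f1), "auc_roc": auc_roc, "auc_pr": auc_pr}
    valid_auc = [v["auc_roc"] for v in per_class.values() if np.isfinite(v["auc_roc"])]
    macro_auc = float(np.mean(valid_auc)) if valid_auc else float("nan")
    macro_f1 = float(np.mean([v["f1"] for v in per_class.values()]))
    return {"accuracy": acc, "per_class": per_class, "macro_f1": macro_f1,
            "macro_auc_roc": macro_auc, "confusion_matrix": conf, "n": n}


def bootstrap_ci(metric_fn, records: list, n_boot: int = 1000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float, float]:
    """Percentile bootstrap over records: (point, low, high)."""
    if len(records) < 10:
        raise ValueError("need at least 10 records for a bootstrap CI")
    rng = np.random.default_rng(seed)
    point = float(metric_fn(records))
    stats = np.empty(n_boot)
    n = len(records)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = metric_fn([records[i] for i in idx])
    alpha = (1 - level) / 2
    low, high = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return point, float(min(low, point)), float(max(high, point))


@dataclass
class MetricReport:
    """Per-class metric table with bootstrap CIs (report shape used by the CLI)."""

    per_class: dict
    macro: dict
    n: int
    excluded_boundary: int = 0

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "macro": self.macro, "n": self.n,
                "excluded_boundary_cases": self.excluded_boundary}


def evaluate_segmentation(pairs: list[tuple[SegMask, SegMask]],
                          labels: dict[int, str] | None = None,
                          spacing: tuple[float, float] = (1.0, 1.0),
                          n_boot: int = 200, seed: int = 0) -> MetricReport:
    """Per-class report over (pred, truth) mask pairs with bootstrap CIs."""
    if not pairs:
        raise ValueError("no mask pairs to evaluate")
    labels = labels or {1: "kidney", 2: "lesion"}
    per_class: dict = {}
    excluded = 0
    for lab, name in labels.items():
        rows = [overlap_metrics(p, t, label=lab) for p, t in pairs]
        brows = [boundary_metrics(p, t, spacing=spacing, label=lab) for p, t in pairs]
        entry = {}
        for key in ("dice", "iou", "precision", "recall", "sensitivity", "specificity"):
            vals = [r[key] for r in rows]
            if len(vals) >= 10:
                pt, lo, hi = bootstrap_ci(lambda recs, k=key: np.mean([r[k] for r in recs]),
                                          rows, n_boot=n_boot, seed=seed)
            else:
                pt, lo, hi = float(np.mean(vals)), float(np.min(vals)), float(np.max(vals))
            entry[key] = {"mean": pt, "ci": [lo, hi],
                          "min": float(np.min(vals)), "max": float(np.max(vals))}
        for key in ("hd95", "asd"):
            vals = np.array([r[key] for r in brows])
            ok = vals[np.isfinite(vals)]
            excluded += int(np.sum(~np.isfinite(vals)))
            if ok.size:
                entry[key] = {"mean": float(ok.mean()), "min": float(ok.min()),
                              "max": float(ok.max()), "n_defined": int(ok.size)}
            else:
                entry[key] = {"mean": float("nan"), "n_defined": 0}
        per_class[name] = entry
    macro = {
        "dice": float(np.mean([per_class[c]["dice"]["mean"] for c in per_class])),
        "iou": float(np.mean([per_class[c]["iou"]["mean"] for c in per_class])),
    }
    return MetricReport(per_class=per_class, macro=macro, n=len(pairs),
                        excluded_boundary=excluded)
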