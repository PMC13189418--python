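"""Losses, optimization utilities and training-loop behavior."""

import numpy as np
import pytest

from renalswin.manifest import DatasetManifest, ManifestRecord
from renalswin.nn.autodiff import Tensor
from renalswin.nn.segmodel import SegmentationModel
from renalswin.nn.swin import PROFILES
from renalswin.train import (AdamW, ArrayDataset, SegLossSpec, TrainConfig,
                             boundary_weight_map, boundary_weighted_bce,
                             class_weights, clip_grad_norm, cosine_lr,
                             dice_loss, kfold_split, total_seg_loss,
                             train_segmentation, warmup_cosine_lr)

TINY = PROFILES["tiny"]


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1.0
        assert float(dice_loss(t, t, smooth=1.0).data) < 0.05
        assert float(dice_loss(t, t, smooth=0.0).data) == 0.0

    def test_inverted_prediction_near_one(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1.0
        assert float(dice_loss(1 - t, t, smooth=0.0).data) == 1.0

    def test_half_overlap_arithmetic(self):
        p = np.zeros((4, 4))
        t = np.zeros((4, 4))
        p[0, 0] = p[0, 1] = 1.0
        t[0, 1] = t[0, 2] = 1.0
        assert float(dice_loss(p, t, smooth=0.0).data) == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBoundaryBCE:
    def test_zero_boost_is_plain_bce(self, rng):
        p = rng.uniform(0.05, 0.95, (8, 8))
        t = rng.integers(0, 2, (8, 8)).astype(float)
        spec = SegLossSpec(boundary_boost=0.0)
        got = float(boundary_weighted_bce(p, t, spec).data)
        eps = 1e-7
        pc = p * (1 - 2 * eps) + eps
        expect = float(np.mean(-(t * np.log(pc) + (1 - t) * np.log(1 - pc))))
        assert got == pytest.approx(expect, rel=1e-9)

    def test_all_background_zero_prediction(self):
        spec = SegLossSpec()
        loss = float(boundary_weighted_bce(np.zeros((8, 8)),
                                           np.zeros((8, 8)), spec).data)
        assert loss < 1e-5

    def test_weight_map_matches_distance_band_oracle(self):
        t = np.zeros((16, 16), int)
        t[5:10, 5:10] = 1
        band, boost = 3, 4.0
        w = boundary_weight_map(t, band, boost)
        # brute force: distance from each pixel to the nearest edge pixel
        from scipy.ndimage import binary_erosion
        edges = np.zeros_like(t, bool)
        for lab in (0, 1):
            reg = t == lab
            edges |= reg & ~binary_erosion(reg, border_value=1)
        pts = np.argwhere(edges)
        expect = np.ones_like(w)
        for i in range(16):
            for j in range(16):
                d = np.min(np.sqrt(((pts - [i, j]) ** 2).sum(axis=1)))
                if d <= band:
                    expect[i, j] += boost
        np.testing.assert_allclose(w, expect)


class TestTotalLoss:
    def _outputs(self, seed=0):
        model = SegmentationModel(TINY, 64, in_channels=1, seed=seed)
        rng = np.random.default_rng(seed)
        return model(Tensor(rng.normal(size=(1, 1, 64, 64))))

    def test_breakdown_sums_to_total(self, paired_mask):
        out = self._outputs()
        t = np.zeros((64, 64), int)
        t[10:40, 10:40] = 1
        t[20:30, 20:30] = 2
        total, parts = total_seg_loss(out, t, SegLossSpec())
        assert float(total.data) == pytest.approx(sum(parts.values()), abs=1e-9)

    def test_zero_deep_supervision_equals_final_head(self):
        out = self._outputs()
        t = np.zeros((64, 64), int)
        t[10:40, 10:40] = 1
        spec = SegLossSpec(deep_supervision_weights=(0.0, 0.0, 0.0),
                           boundary_branch_weight=0.0)
        total, parts = total_seg_loss(out, t, spec)
        assert float(total.data) == pytest.approx(parts["final"], abs=1e-12)

    def test_components_nonnegative(self):
        out = self._outputs(1)
        t = np.zeros((64, 64), int)
        t[5:25, 5:25] = 1
        _, parts = total_seg_loss(out, t, SegLossSpec())
        assert all(v >= 0 for v in parts.values())


class TestOptim:
    def test_clip_caps_global_norm(self):
        ps = [Tensor(np.zeros(3), requires_grad=True) for _ in range(2)]
        ps[0].grad = np.array([3.0, 0, 0])
        ps[1].grad = np.array([0, 4.0, 0])
        pre = clip_grad_norm(ps, 1.0)
        assert pre == pytest.approx(5.0)
        post = np.sqrt(sum(float((p.grad ** 2).sum()) for p in ps))
        assert post <= 1.0 + 1e-6

    def test_adamw_decreases_quadratic(self):
        x = Tensor(np.array([5.0]), requires_grad=True)
        opt = AdamW([x], lr=0.1)
        for _ in range(200):
            x.zero_grad()
            (x * x).sum().backward()
            opt.step()
        assert abs(x.data[0]) < 0.5

    def test_cosine_schedule_endpoints(self):
        assert cosine_lr(1.0, 0, 100) == pytest.approx(1.0)
        assert cosine_lr(1.0, 100, 100) == pytest.approx(0.0, abs=1e-12)

    def test_warmup_starts_low(self):
        lr0 = warmup_cosine_lr(1.0, 0, 1000, warmup_frac=0.1)
        lr_end_warm = warmup_cosine_lr(1.0, 99, 1000, warmup_frac=0.1)
        assert lr0 < lr_end_warm <= 1.0


class TestKFold:
    def _manifest(self, n_per_class=10):
        recs = []
        for c in ("normal", "cyst", "stone", "tumor"):
            for i in range(n_per_class):
                split = "test" if i >= n_per_class - 2 else "train"
                recs.append(ManifestRecord(f"{c}_{i}.png", c, split))
        return DatasetManifest(recs)

    def test_folds_partition_pool(self):
        m = self._manifest(12)
        folds = kfold_split(m, k=5, seed=0)
        pool = {i for i, r in enumerate(m.records) if r.split != "test"}
        all_val = [set(v) for _, v in folds]
        assert set().union(*all_val) == pool
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (all_val[i] & all_val[j])
        for tr, va in folds:
            assert set(tr) | set(va) == pool
            assert not (set(tr) & set(va))

    def test_stratification_within_one_record(self):
        m = self._manifest(12)
        folds = kfold_split(m, k=5, seed=1)
        for _, val in folds:
            counts = {}
            for i in val:
                counts[m.records[i].class_label] = counts.get(
                    m.records[i].class_label, 0) + 1
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_deterministic_per_seed(self):
        m = self._manifest(10)
        assert kfold_split(m, seed=3) == kfold_split(m, seed=3)
        assert kfold_split(m, seed=3) != kfold_split(m, seed=4)

    def test_small_class_rejected(self):
        recs = [ManifestRecord(f"x{i}.png", "cyst", "train") for i in range(3)]
        recs += [ManifestRecord(f"n{i}.png", "normal", "train") for i in range(9)]
        with pytest.raises(ValueError, match="cyst"):
            kfold_split(DatasetManifest(recs), k=5)


class TestClassWeights:
    def test_balanced_gives_equal(self):
        w = class_weights([0, 1, 2, 3] * 5, 4)
        np.testing.assert_allclose(w, 1.0)

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="stone"):
            class_weights([0, 1, 3, 0, 1, 3], 4)


def _one_phantom_dataset():
    from renalswin.phantom import PhantomSpec, generate_phantom
    img, mask, _ = generate_phantom(PhantomSpec(class_label="cyst", seed=0))
    px = img.pixels
    unit = (px - px.min()) / np.ptp(px)
    return ArrayDataset(images=[unit], masks=[mask.labels], class_idx=[1])


class TestTrainingLoop:
    def test_overfit_single_phantom_loss_decreases(self):
        data = _one_phantom_dataset()
        model = SegmentationModel(TINY, 64, in_channels=1, seed=0)
        cfg = TrainConfig(lr=3e-3, epochs=5, patience=10, batch_size=1, seed=0)
        state = train_segmentation(model, data, [0], [0], cfg)
        losses = [h["train_loss"] for h in state.history]
        assert losses[-1] < losses[0]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_early_stopping_triggers_after_patience(self):
        data = _one_phantom_dataset()
        model = SegmentationModel(TINY, 64, in_channels=1, seed=0)
        cfg = TrainConfig(lr=0.0, epochs=50, patience=3, batch_size=1, seed=0)
        # zero lr freezes weights: validation never improves after epoch 0
        state = train_segmentation(model, data, [0], [0], cfg)
        assert state.stopped_early
        assert state.epoch == 3  # epochs 1..3 without improvement

    def test_seeded_runs_reproduce_loss_trace(self):
        data = _one_phantom_dataset()
        traces = []
        for _ in range(2):
            model = SegmentationModel(TINY, 64, in_channels=1, seed=4)
            cfg = TrainConfig(lr=1e-3, epochs=3, patience=10, batch_size=1,
                              seed=4)
            state = train_segmentation(model, data, [0], [0], cfg)
            traces.append([h["train_loss"] for h in state.history])
        assert traces[0] == traces[1]
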