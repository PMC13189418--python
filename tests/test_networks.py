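"""Network components: attention oracles, gating identities, shapes."""

import numpy as np
import pytest

from renalswin.nn.autodiff import Tensor
from renalswin.nn.classifier import PyramidClassifier, prepare_crop
from renalswin.nn.segmodel import (BoundaryEnhance, GammaModulation,
                                   SegmentationModel, cross_attention_fuse)
from renalswin.nn.swin import (PROFILES, ModelProfile, SwinBlock, SwinEncoder,
                               count_patches, window_partition, window_reverse)

TINY = PROFILES["tiny"]


class TestCountPatches:
    def test_published_arithmetic(self):
        assert count_patches(512, 16) == 1024

    def test_single_patch(self):
        assert count_patches(224, 224) == 1

    def test_small_case(self):
        assert count_patches(64, 4) == 256

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError, match="500.*16|16.*500"):
            count_patches(500, 16)


class TestSwinBlock:
    def test_zero_weights_residual_identity(self, rng):
        blk = SwinBlock(dim=8, heads=2, ws=4, shifted=False,
                        rng=np.random.default_rng(0))
        for p in blk.parameters():
            p.data = np.zeros_like(p.data)
        # LayerNorm gains zeroed too -> attention input all zero -> softmax
        # uniform -> value projection zero -> pure residual path
        x = Tensor(rng.normal(size=(1, 8, 8, 8)))
        out = blk(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        blk = SwinBlock(dim=8, heads=2, ws=4, shifted=False,
                        rng=np.random.default_rng(1), memory_tokens=2)
        blk(Tensor(rng.normal(size=(2, 8, 8, 8))))
        attn = blk.attn.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_window_matches_dense_attention(self, rng):
        # window covers the whole 4x4 token grid: windowed == full attention
        dim, heads = 8, 2
        blk = SwinBlock(dim=dim, heads=heads, ws=4, shifted=False,
                        rng=np.random.default_rng(2))
        x = rng.normal(size=(1, 4, 4, dim))
        out = blk(Tensor(x)).data

        # dense-attention oracle with the same weights, numpy only
        def ln(v, gain, shift, eps=1e-5):
            mu = v.mean(-1, keepdims=True)
            var = ((v - mu) ** 2).mean(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * gain + shift

        tok = x.reshape(16, dim)
        z = ln(tok, blk.norm1.gain.data, blk.norm1.shift.data)
        qkv = z @ blk.attn.qkv.weight.data + blk.attn.qkv.bias.data
        q, k, v = [qkv[:, i * dim:(i + 1) * dim].reshape(16, heads, dim // heads)
                   .transpose(1, 0, 2) for i in range(3)]
        logits = q @ k.transpose(0, 2, 1) / np.sqrt(dim // heads)
        bias = blk.attn.rel_bias.data[blk.attn.rel_index.ravel()].reshape(16, 16, heads)
        logits = logits + bias.transpose(2, 0, 1)
        e = np.exp(logits - logits.max(-1, keepdims=True))
        attn = e / e.sum(-1, keepdims=True)
        av = (attn @ v).transpose(1, 0, 2).reshape(16, dim)
        attended = av @ blk.attn.proj.weight.data + blk.attn.proj.bias.data
        z1 = tok + attended
        z2 = ln(z1, blk.norm2.gain.data, blk.norm2.shift.data)
        h = z2 @ blk.ffn.fc1.weight.data + blk.ffn.fc1.bias.data
        from scipy.special import erf
        h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
        mlp = h @ blk.ffn.fc2.weight.data + blk.ffn.fc2.bias.data
        expect = (z1 + mlp).reshape(1, 4, 4, dim)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_window_partition_roundtrip(self, rng):
        x = Tensor(rng.normal(size=(2, 8, 8, 5)))
        w = window_partition(x, 4)
        back = window_reverse(w, 4, 2, 8, 8)
        np.testing.assert_array_equal(back.data, x.data)

    def test_window_too_large_rejected(self, rng):
        blk = SwinBlock(dim=8, heads=2, ws=8, shifted=False,
                        rng=np.random.default_rng(3))
        with pytest.raises(ValueError, match="window"):
            blk(Tensor(rng.normal(size=(1, 4, 4, 8))))


class TestEncoder:
    def test_four_scales(self, rng):
        enc = SwinEncoder(TINY, 64, in_channels=1, seed=0)
        feats = enc(Tensor(rng.normal(size=(1, 1, 64, 64))))
        sides = [f.shape[1] for f in feats]
        assert sides == [16, 8, 4, 2]
        dims = [f.shape[3] for f in feats]
        assert dims == list(TINY.embed_dims)

    def test_deterministic_forward(self, rng):
        enc = SwinEncoder(TINY, 64, in_channels=1, seed=0).eval()
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        a = enc(x)[3].data
        b = enc(x)[3].data
        np.testing.assert_array_equal(a, b)

    def test_contrast_change_perturbs_output(self, rng):
        enc = SwinEncoder(TINY, 64, in_channels=1, seed=0)
        x = rng.normal(size=(1, 1, 64, 64))
        a = enc(Tensor(x))[3].data
        b = enc(Tensor(2.0 * x))[3].data
        assert not np.allclose(a, b)

    def test_attention_maps_retained(self, rng):
        enc = SwinEncoder(TINY, 64, in_channels=1, seed=0)
        enc(Tensor(rng.normal(size=(1, 1, 64, 64))))
        assert len(enc.attention_maps) == 4
        assert all(len(stage) == d for stage, d in
                   zip(enc.attention_maps, TINY.depths))


class TestGammaModulation:
    def test_frozen_maps_give_stated_moments(self, rng):
        gm = GammaModulation(3, np.random.default_rng(0))
        # freeze the two heads to constants: k=1, theta=2 for every channel
        inv_softplus = lambda y: np.log(np.expm1(y))
        for fc1, fc2, val in ((gm.fc_k1, gm.fc_k2, 1.0),
                              (gm.fc_t1, gm.fc_t2, 2.0)):
            fc1.weight.data[:] = 0
            fc1.bias.data[:] = 0
            fc2.weight.data[:] = 0
            fc2.bias.data[:] = inv_softplus(val)
        gm(Tensor(rng.normal(size=(2, 3, 4, 4))))
        stats = gm.last_stats
        np.testing.assert_allclose(stats.k, 1.0, atol=1e-12)
        np.testing.assert_allclose(stats.theta, 2.0, atol=1e-12)
        np.testing.assert_allclose(stats.mu, 2.0, atol=1e-12)
        np.testing.assert_allclose(stats.var, 4.0, atol=1e-12)

    def test_positivity_under_adversarial_activations(self):
        gm = GammaModulation(4, np.random.default_rng(1))
        x = Tensor(np.array([[-1e6, -50.0, 0.0, 1e6]]).reshape(1, 4, 1, 1)
                   * np.ones((1, 4, 2, 2)))
        gm(x)
        assert np.all(gm.last_stats.k > 0)
        assert np.all(gm.last_stats.theta > 0)

    def test_gates_match_bruteforce_recomputation(self, rng):
        gm = GammaModulation(3, np.random.default_rng(2))
        x = rng.normal(size=(1, 3, 2, 2))
        out = gm(Tensor(x))
        k, th = gm.last_stats.k, gm.last_stats.theta
        mu, var = k * th, k * th ** 2

        def std_across(v):
            c = v - v.mean(axis=1, keepdims=True)
            return c / np.sqrt((c ** 2).mean(axis=1, keepdims=True) + 1e-6)

        gate = 1 / (1 + np.exp(-(gm.gate_u.data * std_across(mu)
                                 + gm.gate_v.data * std_across(var)
                                 + gm.gate_b.data)))
        np.testing.assert_allclose(gm.last_gates, gate, atol=1e-10)
        np.testing.assert_allclose(out.data, x * gate[..., None, None], atol=1e-10)
        assert np.all((gate > 0) & (gate < 1))

    def test_shape_preserved(self, rng):
        gm = GammaModulation(5, np.random.default_rng(3))
        x = rng.normal(size=(2, 5, 6, 6))
        assert gm(Tensor(x)).shape == x.shape


class TestCrossAttention:
    def test_single_key_value(self, rng):
        q = Tensor(rng.normal(size=(1, 2, 4)))
        k = Tensor(rng.normal(size=(1, 1, 4)))
        v = Tensor(rng.normal(size=(1, 1, 4)))
        f = Tensor(rng.normal(size=(1, 2, 4)))
        out = cross_attention_fuse(q, k, v, f).data
        np.testing.assert_allclose(out, v.data + f.data, atol=1e-12)

    def test_identical_values_convexity(self, rng):
        row = rng.normal(size=4)
        q = Tensor(rng.normal(size=(1, 3, 4)))
        k = Tensor(rng.normal(size=(1, 5, 4)))
        v = Tensor(np.tile(row, (1, 5, 1)))
        f = Tensor(np.zeros((1, 3, 4)))
        out = cross_attention_fuse(q, k, v, f).data
        np.testing.assert_allclose(out, np.tile(row, (1, 3, 1)), atol=1e-12)

    def test_matches_hand_computed_two_query_three_key(self):
        d = 2
        q = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        k = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
        v = np.array([[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]])
        f = np.array([[[0.1, 0.1], [0.2, 0.2]]])
        logits = q[0] @ k[0].T / np.sqrt(d)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        expect = attn @ v[0] + f[0]
        out = cross_attention_fuse(Tensor(q), Tensor(k), Tensor(v), Tensor(f))
        np.testing.assert_allclose(out.data[0], expect, atol=1e-9)

    def test_bad_dimension_rejected(self, rng):
        q = Tensor(rng.normal(size=(1, 2, 4)))
        k = Tensor(rng.normal(size=(1, 3, 5)))
        with pytest.raises(ValueError):
            cross_attention_fuse(q, k, k, q)


class TestBoundaryEnhance:
    def test_constant_input_zero_weights_gives_half(self):
        be = BoundaryEnhance(3, np.random.default_rng(0))
        for p in be.parameters():
            p.data = np.zeros_like(p.data)
        out = be(Tensor(np.ones((1, 3, 8, 8))))
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)

    def test_output_in_unit_interval(self, rng):
        be = BoundaryEnhance(3, np.random.default_rng(1))
        out = be(Tensor(rng.normal(size=(2, 3, 8, 8)))).data
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert out.shape == (2, 1, 8, 8)

    def test_dilation4_receptive_field_span(self):
        # impulse response of the dilation-4 3x3 branch spans 9 pixels
        be = BoundaryEnhance(1, np.random.default_rng(2), hidden=1)
        x = np.zeros((1, 1, 17, 17))
        x[0, 0, 8, 8] = 1.0
        resp = be.d4(Tensor(x)).data[0, 0] - be.d4(Tensor(np.zeros_like(x))).data[0, 0]
        ys, xs = np.where(np.abs(resp) > 1e-12)
        assert ys.max() - ys.min() == 8 and xs.max() - xs.min() == 8


class TestSegmentationModel:
    def test_output_shapes(self, rng):
        model = SegmentationModel(TINY, 64, in_channels=2, seed=0)
        out = model(Tensor(rng.normal(size=(2, 2, 64, 64))))
        assert out["logits"].shape == (2, 3, 64, 64)
        assert [o.shape[2] for o in out["deep_supervision"]] == [4, 8, 16]
        assert out["boundary"].shape == (2, 1, 16, 16)

    def test_gamma_ablation_changes_output(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        on = SegmentationModel(TINY, 64, in_channels=1, seed=0,
                               gamma_modulation="deepest")
        off = SegmentationModel(TINY, 64, in_channels=1, seed=0,
                                gamma_modulation="off")
        # identical encoder weights by construction (same seed); gating off
        # must alter the decoder input
        assert not np.allclose(on(x)["logits"].data, off(x)["logits"].data)

    def test_direct_decoder_variant_runs(self, rng):
        model = SegmentationModel(TINY, 64, in_channels=1, seed=0,
                                  use_cross_attention=False)
        out = model(Tensor(rng.normal(size=(1, 1, 64, 64))))
        assert out["logits"].shape == (1, 3, 64, 64)
        assert out["deep_supervision"] == []

    def test_conv_encoder_variant_runs(self, rng):
        model = SegmentationModel(TINY, 64, in_channels=1, seed=0,
                                  use_swin=False)
        out = model(Tensor(rng.normal(size=(1, 1, 64, 64))))
        assert out["logits"].shape == (1, 3, 64, 64)


class TestClassifier:
    def test_probabilities_sum_to_one(self, rng):
        clf = PyramidClassifier(TINY, seed=0).eval()
        probs = clf(Tensor(rng.normal(size=(3, 1, 64, 64)))).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, rng):
        clf = PyramidClassifier(TINY, seed=0).eval()
        x = Tensor(rng.normal(size=(2, 1, 64, 64)))
        np.testing.assert_array_equal(clf(x).data, clf(x).data)

    def test_train_mode_dropout_varies(self, rng):
        clf = PyramidClassifier(TINY, seed=0).train()
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        assert not np.allclose(clf(x).data, clf(x).data)

    def test_head_permutation_equivariance(self, rng):
        clf = PyramidClassifier(TINY, seed=0).eval()
        x = Tensor(rng.normal(size=(1, 1, 64, 64)))
        base = clf(x).data.copy()
        perm = np.array([2, 0, 3, 1])
        clf.head2.weight.data = clf.head2.weight.data[:, perm]
        clf.head2.bias.data = clf.head2.bias.data[perm]
        permuted = clf(x).data
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-10)

    def test_wrong_size_crop_resized(self, rng):
        crop = prepare_crop(rng.uniform(size=(48, 48)), None, 64)
        assert crop.shape == (64, 64)
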