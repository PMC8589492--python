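"""Inception-YNet construction, forward contracts, and learnability."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gdynet import (GDYNet, GDYNetConfig, InceptionSpec, build_gdynet,
                    render_sample)
from gdynet.errors import ConfigurationError, ShapeError
from gdynet.model import InceptionBlock
from gdynet.nn import SGDM, Tensor

TINY = GDYNetConfig(depth=2, base_filters=4, input_size=16, seed=0)


class TestInceptionBlock:
    def test_output_channels_are_branch_sum(self):
        rng = np.random.default_rng(0)
        block = InceptionBlock(3, InceptionSpec(8, 16, 8, 8), rng=rng)
        y = block(Tensor(rng.random((1, 3, 16, 16))))
        assert y.shape == (1, 40, 16, 16)

    def test_spatial_size_preserved(self):
        rng = np.random.default_rng(1)
        block = InceptionBlock(4, InceptionSpec(2, 2, 1, 1), rng=rng)
        y = block(Tensor(rng.random((2, 4, 64, 64))))
        assert y.shape[2:] == (64, 64)

    def test_zero_input_zero_biases_zero_output(self):
        rng = np.random.default_rng(2)
        block = InceptionBlock(3, InceptionSpec(2, 2, 1, 1), rng=rng)
        for name, p in block.named_parameters():
            if "bias" in name or "beta" in name:
                p.data[:] = 0.0
        y = block(Tensor(np.zeros((1, 3, 8, 8))))
        assert np.allclose(y.data, 0.0)

    def test_scaled_spec_distributes_exactly(self):
        spec = InceptionSpec(2, 4, 1, 1).scaled(32)
        assert spec.total == 32
        assert min(spec.c1, spec.c3, spec.c5, spec.cpool) >= 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            InceptionSpec(0, 4, 1, 1)


class TestBuild:
    def test_encoder_sizes_and_seg_shape(self):
        cfg = GDYNetConfig(depth=4, base_filters=4, input_size=64, seed=0)
        model = build_gdynet(cfg)
        assert model.encoder_spatial_sizes() == [64, 32, 16, 8, 4]
        out = model(np.random.default_rng(0).random((64, 64, 3)))
        assert out.seg_prob.shape == (1, 64, 64)

    def test_outputs_in_unit_interval(self):
        model = build_gdynet(TINY)
        out = model(np.random.default_rng(1).random((2, 16, 16, 3)))
        assert out.seg_prob.data.min() >= 0.0
        assert out.seg_prob.data.max() <= 1.0
        assert 0.0 <= out.class_score.data.min() \
            and out.class_score.data.max() <= 1.0

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            GDYNetConfig(depth=4, base_filters=4, input_size=50)

    def test_hidden_vector_length_matches_config(self):
        cfg = GDYNetConfig(depth=2, base_filters=4, input_size=16,
                           classifier_hidden=64, seed=0)
        model = build_gdynet(cfg)
        assert model.fc1.weight.shape[1] == 64
        assert model.fc2.weight.shape == (64, 1)

    def test_branch_conv_halves_spatial_size(self):
        # input 64 -> masked image pooled to 32 -> stride-2 conv -> 16
        cfg = GDYNetConfig(depth=4, base_filters=4, input_size=64, seed=0)
        out = build_gdynet(cfg)(np.random.default_rng(2).random((64, 64, 3)))
        assert out.branch_conv.shape[2:] == (16, 16)

    def test_parameter_count_monotone_in_depth_and_width(self):
        base = GDYNetConfig(depth=2, base_filters=4, input_size=32,
                            seed=0)
        n_base = build_gdynet(base).n_parameters()
        deeper = GDYNetConfig(depth=3, base_filters=4, input_size=32,
                              seed=0)
        wider = GDYNetConfig(depth=2, base_filters=8, input_size=32,
                             seed=0)
        assert build_gdynet(deeper).n_parameters() > n_base
        assert build_gdynet(wider).n_parameters() > n_base


class TestForwardContracts:
    def test_inference_deterministic(self):
        model = build_gdynet(TINY)
        x = np.random.default_rng(3).random((2, 16, 16, 3))
        o1, o2 = model(x), model(x)
        assert np.array_equal(o1.seg_prob.data, o2.seg_prob.data)
        assert np.array_equal(o1.class_score.data, o2.class_score.data)

    def test_batching_is_order_preserving(self):
        model = build_gdynet(TINY)
        rng = np.random.default_rng(4)
        batch = rng.random((3, 16, 16, 3))
        out = model(batch)
        for i in range(3):
            single = model(batch[i])
            assert np.allclose(single.seg_prob.data[0],
                               out.seg_prob.data[i], atol=1e-5)
            assert np.allclose(single.class_score.data[0],
                               out.class_score.data[i], atol=1e-5)

    def test_all_background_prediction_still_scores(self):
        model = build_gdynet(TINY)
        model.head.bias.data[:] = -50.0   # drive seg_prob to ~0
        out = model(np.random.default_rng(5).random((16, 16, 3)))
        assert out.seg_prob.data.max() < 0.5
        assert 0.0 <= float(out.class_score.data[0]) <= 1.0

    def test_wrong_size_rejected(self):
        model = build_gdynet(TINY)
        with pytest.raises(ShapeError):
            model(np.zeros((8, 8, 3)))


@pytest.mark.usefixtures("float64")
class TestGradientOracle:
    def test_joint_loss_gradients_match_finite_differences(self):
        # soft mask: the default hard binarization is deliberately
        # non-differentiable, so the oracle runs the differentiable path
        from gdynet.training import cls_loss, seg_loss
        model = build_gdynet(dataclasses.replace(TINY, soft_mask=True))
        rng = np.random.default_rng(6)
        x = rng.random((2, 3, 16, 16))
        mask = (rng.random((2, 16, 16)) > 0.7).astype(float)
        labels = np.array([0.0, 1.0])

        def loss_value():
            out = model(Tensor(x))
            return seg_loss(out.seg_prob, mask, 0.5) \
                + cls_loss(out.class_score, labels)

        loss = loss_value()
        model.zero_grad()
        loss.backward()
        params = dict(model.named_parameters())
        # small step: piecewise-linear ops make larger central
        # differences noisy; float64 keeps roundoff ~1e-9 at this eps
        eps = 1e-7
        checked = 0
        for name in np.random.default_rng(7).choice(
                sorted(params), size=8, replace=False):
            p = params[name]
            if p.grad is None:
                continue
            idx = tuple(np.random.default_rng(checked).integers(0, s)
                        for s in p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            f_hi = float(loss_value().data)
            p.data[idx] = orig - eps
            f_lo = float(loss_value().data)
            p.data[idx] = orig
            fd = (f_hi - f_lo) / (2 * eps)
            assert abs(fd - p.grad[idx]) <= 1e-3 * max(1.0, abs(fd)), \
                f"{name}[{idx}]: fd={fd} analytic={p.grad[idx]}"
            checked += 1
        assert checked >= 5


class TestOverfit:
    def test_single_sample_overfits_to_high_dice(self, synth_params):
        """Training on one image drives Dice above 0.99 quickly."""
        from gdynet.metrics import dice
        from gdynet.training import seg_loss
        s = render_sample(synth_params, 1, 7)
        x = s.image.transpose(2, 0, 1)[None]
        mask = s.disc_mask[None].astype(float)
        model = build_gdynet(GDYNetConfig(depth=4, base_filters=4,
                                          input_size=64, seed=0))
        opt = SGDM(model, lr=0.2, momentum=0.9)
        best = 0.0
        for _ in range(200):
            out = model(Tensor(x))
            loss = seg_loss(out.seg_prob, mask, 0.5)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if (out.seg_prob.data >= 0.5).any():
                best = max(best, dice(out.seg_prob.data[0] >= 0.5,
                                      s.disc_mask))
            if best >= 0.99:
                break
        assert best >= 0.99
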