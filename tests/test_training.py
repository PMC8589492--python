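"""Loss closed forms, schedule arithmetic, and the alternating loop."""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pytest

from gdynet import GDYNetConfig, TrainConfig, build_gdynet, lr_at
from gdynet.errors import (ConfigurationError, DomainError, ShapeError,
                           ValidationError)
from gdynet.nn import Tensor
from gdynet.training import (cls_loss, seg_loss, seg_loss_literal, train)

LN2 = float(np.log(2.0))


class TestSegLoss:
    def test_perfect_prediction_near_zero(self):
        mask = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        assert float(seg_loss(mask.copy(), mask, sigma=1.0).data) <= 1e-6

    @pytest.mark.parametrize("sigma", [1.0, 0.5, 0.25])
    def test_uniform_half_gives_ln2_over_sigma(self, sigma):
        mask = np.zeros((4, 4))
        p = np.full((4, 4), 0.5)
        assert float(seg_loss(p, mask, sigma).data) == \
            pytest.approx(LN2 / sigma, rel=1e-6)

    def test_halving_sigma_doubles_loss(self):
        rng = np.random.default_rng(1)
        p = rng.random((6, 6)) * 0.8 + 0.1
        mask = (rng.random((6, 6)) > 0.5).astype(float)
        l1 = float(seg_loss(p, mask, 0.8).data)
        l2 = float(seg_loss(p, mask, 0.4).data)
        assert l2 == pytest.approx(2 * l1, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            seg_loss(np.zeros((4, 4)), np.zeros((5, 5)), 0.5)

    def test_invalid_sigma(self):
        with pytest.raises(DomainError):
            seg_loss(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)

    def test_literal_variant_ignores_foreground(self):
        """The background-weighted squared-error form zeroes foreground."""
        mask = np.ones((4, 4))
        p = np.zeros((4, 4))   # maximally wrong on all-foreground gt
        assert float(seg_loss_literal(p, mask, 1.0).data) == 0.0
        mask0 = np.zeros((4, 4))
        p0 = np.full((4, 4), 0.3)
        assert float(seg_loss_literal(p0, mask0, 1.0).data) == \
            pytest.approx(0.09, rel=1e-5)


class TestClsLoss:
    def test_perfect_and_half(self):
        assert float(cls_loss(np.array([1.0]), np.array([1.0])).data) <= 1e-6
        assert float(cls_loss(np.array([0.5]), np.array([1.0])).data) == \
            pytest.approx(LN2, rel=1e-6)

    def test_monotone_decreasing_in_p_for_positive_label(self):
        ps = np.linspace(0.05, 0.95, 10)
        losses = [float(cls_loss(np.array([p]), np.array([1.0])).data)
                  for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_invalid_label(self):
        with pytest.raises(DomainError):
            cls_loss(np.array([0.5]), np.array([2.0]))


class TestSchedule:
    CFG = TrainConfig(lr0=0.001, lr_decay_factor=2.0, lr_decay_period=20)

    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.001), (19, 0.001), (20, 0.0005), (39, 0.0005),
        (40, 0.00025), (45, 0.00025)])
    def test_halving_schedule(self, epoch, expected):
        assert lr_at(epoch, self.CFG) == pytest.approx(expected, rel=1e-12)

    def test_non_increasing(self):
        lrs = [lr_at(e, self.CFG) for e in range(100)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_constant_when_period_exceeds_epochs(self):
        cfg = TrainConfig(lr0=0.01, lr_decay_period=1000)
        assert lr_at(999, cfg) == 0.01

    def test_negative_epoch_rejected(self):
        with pytest.raises(DomainError):
            lr_at(-1, self.CFG)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(lr0=-1.0)
        with pytest.raises(ConfigurationError):
            TrainConfig(sigma=1.5)
        with pytest.raises(ConfigurationError):
            TrainConfig(lr_decay_factor=1.0)


def _write_tiny_dataset(tmp_path, n_per_class=3, size=16):
    from gdynet import SynthParams, build_dataset
    from gdynet.io import DatasetManifest, write_manifest
    p = SynthParams(image_size=size)
    m1 = build_dataset(n_per_class, n_per_class, p, seed=1,
                       out_dir=tmp_path / "d", split="train")
    m2 = build_dataset(1, 1, p, seed=2, out_dir=tmp_path / "d2",
                       split="test")
    return write_manifest(DatasetManifest(m1.rows + m2.rows),
                          tmp_path / "m.csv")


TINY_TRAIN = TrainConfig(max_epochs=2, batch_size=2, lr0=0.05,
                         momentum=0.9, l2=0.0, lr_decay_factor=2.0,
                         lr_decay_period=20, sigma=0.5, seed=0)
TINY_MODEL = GDYNetConfig(depth=2, base_filters=4, input_size=16, seed=0)


class TestTrainLoop:
    def test_deterministic_weights_checksum(self, tmp_path):
        from gdynet.io import read_manifest
        manifest = read_manifest(_write_tiny_dataset(tmp_path))
        digests = []
        for _ in range(2):
            model = build_gdynet(TINY_MODEL)
            model, _ = train(model, manifest, TINY_TRAIN, val_split=None)
            h = hashlib.sha256()
            for k, v in sorted(model.state_dict().items()):
                h.update(v.tobytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_alternation_bookkeeping(self, tmp_path):
        from gdynet.io import read_manifest
        manifest = read_manifest(_write_tiny_dataset(tmp_path))
        model = build_gdynet(TINY_MODEL)
        _, history = train(model, manifest,
                           dataclasses.replace(TINY_TRAIN, max_epochs=3),
                           val_split=None)
        for rec in history.epochs:
            assert abs(rec["seg_steps"] - rec["cls_steps"]) <= 1

    def test_l2_shrinks_final_weight_norm(self, tmp_path):
        from gdynet.io import read_manifest
        manifest = read_manifest(_write_tiny_dataset(tmp_path))
        norms = []
        for l2 in (0.0, 0.1):
            model = build_gdynet(TINY_MODEL)
            cfg = dataclasses.replace(TINY_TRAIN, l2=l2)
            model, _ = train(model, manifest, cfg, val_split=None)
            norms.append(np.sqrt(sum(
                float(np.sum(p.data ** 2)) for p in model.parameters())))
        assert norms[1] < norms[0]

    def test_missing_mask_or_label_rejected_before_training(self, tmp_path):
        from gdynet.io import (DatasetManifest, ManifestRow, read_manifest,
                               write_manifest)
        manifest = read_manifest(_write_tiny_dataset(tmp_path))
        rows = manifest.rows
        rows[0] = ManifestRow(image_path=rows[0].image_path,
                              disc_mask_path=None, label=0, split="train")
        bad = write_manifest(DatasetManifest(rows), tmp_path / "bad.csv")
        model = build_gdynet(TINY_MODEL)
        with pytest.raises(ValidationError):
            train(model, read_manifest(bad), TINY_TRAIN, val_split=None)

    def test_history_records_losses_and_lr(self, tmp_path):
        from gdynet.io import read_manifest
        manifest = read_manifest(_write_tiny_dataset(tmp_path))
        model = build_gdynet(TINY_MODEL)
        _, history = train(model, manifest, TINY_TRAIN)
        assert len(history.epochs) == TINY_TRAIN.max_epochs
        for rec in history.epochs:
            assert rec["seg_loss"] >= 0 and rec["cls_loss"] >= 0
            assert rec["lr"] == pytest.approx(TINY_TRAIN.lr0)
            assert "val_dice" in rec   # test split present
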