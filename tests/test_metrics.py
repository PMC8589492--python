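"""Metric tests: independent counting oracles, closed forms, and the
structure/enhanced-alignment sanity properties."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import disk

from gdynet.errors import DomainError, ShapeError
from gdynet.metrics import (ConfusionCounts, basic_rates,
                            confusion_from_masks, dice, e_measure,
                            evaluate_classification, evaluate_dataset,
                            jaccard, roc_auc, structure_measure)


def brute_force_confusion(pred, gt):
    tp = fp = tn = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def centered_disc(size=64, radius=12):
    mask = np.zeros((size, size), dtype=np.uint8)
    rr, cc = disk((size // 2, size // 2), radius)
    mask[rr, cc] = 1
    return mask


class TestConfusionAndRates:
    def test_identity_and_complement(self):
        ones = np.ones((3, 3), dtype=np.uint8)
        c = confusion_from_masks(ones, ones)
        assert (c.tp, c.fp, c.tn, c.fn) == (9, 0, 0, 0)
        c2 = confusion_from_masks(1 - ones, ones)
        assert c2.tp == 0 and c2.tn == 0

    def test_counts_match_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred = rng.integers(0, 2, (8, 8))
            gt = rng.integers(0, 2, (8, 8))
            c = confusion_from_masks(pred, gt)
            assert (c.tp, c.fp, c.tn, c.fn) == \
                brute_force_confusion(pred, gt)

    def test_worked_example(self):
        r = basic_rates(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert r.accuracy == pytest.approx(0.8)   # (3 + 5) / 10
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx(5 / 6)
        assert r.precision == pytest.approx(0.75)

    def test_perfect_prediction_all_ones(self):
        r = basic_rates(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
        assert r.accuracy == r.sensitivity == r.specificity == 1.0
        assert r.mcc == pytest.approx(1.0)

    def test_constant_positive_predictor(self):
        r = basic_rates(ConfusionCounts(tp=5, fp=5, tn=0, fn=0))
        assert r.specificity == 0.0 and r.fpr == 1.0

    def test_undefined_rates_flagged_not_zeroed(self):
        r = basic_rates(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.sensitivity is None
        assert "sensitivity" in r.undefined
        assert r.precision is None

    def test_all_zero_counts_domain_error(self):
        with pytest.raises(DomainError):
            basic_rates(ConfusionCounts(0, 0, 0, 0))

    def test_rates_match_direct_arithmetic_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            r = basic_rates(ConfusionCounts(tp, fp, tn, fn))
            assert r.accuracy == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            assert r.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn),
                                         abs=1e-12)
            mcc = ((tp * tn - fp * fn)
                   / np.sqrt(float((tp + fp) * (tp + fn)
                                   * (tn + fp) * (tn + fn))))
            assert r.mcc == pytest.approx(mcc, abs=1e-12)


class TestOverlap:
    def test_identity_masks(self):
        m = centered_disc()
        assert dice(m, m) == 1.0
        assert jaccard(m, m) == 1.0

    def test_counting_example(self):
        gt = np.ones((2, 2), dtype=np.uint8)
        pred = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        assert dice(pred, gt) == pytest.approx(2 / 3)
        assert jaccard(pred, gt) == pytest.approx(0.5)

    def test_dice_jaccard_identity_random(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pred = rng.integers(0, 2, (10, 10))
            gt = rng.integers(0, 2, (10, 10))
            if not (pred | gt).any():
                continue
            j = jaccard(pred, gt)
            assert dice(pred, gt) == pytest.approx(2 * j / (1 + j),
                                                   abs=1e-12)
            assert dice(pred, gt) >= j - 1e-12

    def test_empty_masks_domain_error(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(DomainError):
            dice(z, z)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            dice(np.ones((2, 2)), np.ones((3, 3)))


class TestStructureMeasure:
    def test_perfect_prediction(self):
        gt = centered_disc()
        assert structure_measure(gt.astype(float), gt) == \
            pytest.approx(1.0, abs=1e-6)

    def test_complement_scores_low(self):
        gt = centered_disc()
        inv = 1.0 - gt.astype(float)
        assert structure_measure(inv, gt) <= 0.35

    def test_alpha_endpoint_is_object_term(self):
        rng = np.random.default_rng(3)
        gt = centered_disc(32, 6)
        pred = np.clip(gt + 0.1 * rng.random((32, 32)), 0, 1)
        from gdynet.metrics import _s_object
        assert structure_measure(pred, gt, alpha=1.0) == \
            pytest.approx(np.clip(_s_object(pred, gt > 0), 0, 1))

    def test_degenerate_gts(self):
        pred = np.full((8, 8), 0.25)
        assert structure_measure(pred, np.zeros((8, 8))) == \
            pytest.approx(0.75)
        assert structure_measure(pred, np.ones((8, 8))) == \
            pytest.approx(0.25)

    def test_bounded_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pred = rng.random((12, 12))
            gt = rng.integers(0, 2, (12, 12))
            assert 0.0 <= structure_measure(pred, gt) <= 1.0


class TestEMeasure:
    def test_perfect_alignment(self):
        gt = centered_disc()
        assert e_measure(gt, gt) == pytest.approx(1.0, abs=1e-6)

    def test_complement_scores_low(self):
        gt = centered_disc()
        assert e_measure(1 - gt, gt) <= 0.25

    def test_mean_mode_of_binary_equals_single(self):
        gt = centered_disc(32, 7)
        pred = centered_disc(32, 9).astype(float)
        assert e_measure(pred, gt, mode="mean") == \
            pytest.approx(e_measure(pred, gt, mode="single"), abs=1e-12)

    def test_degenerate_gts(self):
        pred = np.zeros((8, 8))
        assert e_measure(pred, np.zeros((8, 8))) == pytest.approx(1.0)
        assert e_measure(pred, np.ones((8, 8))) == pytest.approx(0.0)

    def test_bounded_on_random_prob_maps(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pred = rng.random((10, 10))
            gt = rng.integers(0, 2, (10, 10))
            assert 0.0 <= e_measure(pred, gt, mode="mean") <= 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        scores = np.round(rng.random(20), 1)   # force some ties
        labels = rng.integers(0, 2, 20)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = ties = 0
        for p in pos:
            for q in neg:
                wins += p > q
                ties += p == q
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_single_class_domain_error(self):
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.9], [1, 1])


class TestAggregation:
    def test_perfect_dataset(self):
        gt = centered_disc(32, 6)
        pairs = [(gt, gt, None)] * 3
        scores = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 1, 0, 0])
        rep = evaluate_dataset(pairs, scores, labels)
        assert rep["segmentation"]["dice"] == 1.0
        assert rep["classification"]["accuracy"] == 1.0
        assert rep["classification"]["mcc"] == pytest.approx(1.0)

    def test_mean_aggregation(self):
        gt = np.ones((2, 2), dtype=np.uint8)
        half = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        rep = evaluate_dataset([(gt, gt, None), (half, gt, None)],
                               None, None)
        # dice values 1.0 and 2/3 -> unweighted mean
        assert rep["segmentation"]["dice"] == pytest.approx((1 + 2 / 3) / 2)

    def test_report_roundtrips_as_json(self, tmp_path):
        from gdynet.io import read_json_report, write_json_report
        gt = centered_disc(16, 4)
        rep = evaluate_dataset([(gt, gt, None)], np.array([0.8, 0.2]),
                               np.array([1, 0]))
        back = read_json_report(write_json_report(rep, tmp_path / "r.json"))
        assert back["segmentation"]["dice"] == 1.0
        assert back["classification"]["auc"] == 1.0


class TestBoundsProperty:
    def test_all_metrics_in_bounds_on_random_masks(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            pred = rng.integers(0, 2, (8, 8))
            gt = rng.integers(0, 2, (8, 8))
            c = confusion_from_masks(pred, gt)
            r = basic_rates(c)
            for name in ("accuracy", "sensitivity", "specificity",
                         "precision", "fpr", "f1"):
                v = getattr(r, name)
                assert v is None or 0.0 <= v <= 1.0
            if r.mcc is not None:
                assert -1.0 <= r.mcc <= 1.0
            if (pred | gt).any():
                assert 0.0 <= jaccard(pred, gt) <= dice(pred, gt) <= 1.0
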