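"""Consensus ground truth, confusion matrices, metrics, balancing, ROC."""

from __future__ import annotations

import numpy as np
import pytest

from ki67seg import evaluation as ev
from ki67seg.formats_io import LABEL_NON_TUMOR, LABEL_TUMOR


def mask_of(rows):
    return np.array(rows, dtype=np.uint8)


class TestConsensus:
    def test_identical_readers(self):
        labels = mask_of([[1, 2], [2, 1]])
        gt = ev.build_consensus(labels, labels.copy(), "C1")
        assert np.array_equal(gt.labels, labels)
        assert not gt.excluded.any()

    def test_total_disagreement_excludes_everything(self):
        a = np.full((4, 4), LABEL_TUMOR, dtype=np.uint8)
        b = np.full((4, 4), LABEL_NON_TUMOR, dtype=np.uint8)
        gt = ev.build_consensus(a, b, "C1")
        assert gt.excluded.all()

    def test_half_tumor_example(self):
        a = np.full((4, 8), LABEL_NON_TUMOR, dtype=np.uint8)
        a[:, :4] = LABEL_TUMOR  # A: tumor on the left half only
        b = np.full((4, 8), LABEL_TUMOR, dtype=np.uint8)  # B: all tumor
        c2 = ev.build_consensus(a, b, "C2_tumor_favouring")
        assert (c2.labels == LABEL_TUMOR).all()
        assert not c2.excluded.any()
        c1 = ev.build_consensus(a, b, "C1")
        assert (c1.labels[:, :4] == LABEL_TUMOR).all()
        assert c1.excluded[:, 4:].all()
        assert not c1.excluded[:, :4].any()

    def test_non_tumor_favouring_union(self):
        a = mask_of([[1, 2]])
        b = mask_of([[2, 2]])
        gt = ev.build_consensus(a, b, "C2_non_tumor_favouring")
        assert np.array_equal(gt.labels, [[2, 2]])

    def test_excluded_count_equals_disagreement(self, rng):
        a = rng.integers(1, 3, (30, 30)).astype(np.uint8)
        b = rng.integers(1, 3, (30, 30)).astype(np.uint8)
        gt = ev.build_consensus(a, b, "C1")
        assert gt.excluded.sum() == (a != b).sum()

    def test_c2_tumor_area_superset_of_c1(self, rng):
        a = rng.integers(1, 3, (30, 30)).astype(np.uint8)
        b = rng.integers(1, 3, (30, 30)).astype(np.uint8)
        c1 = ev.build_consensus(a, b, "C1")
        c2 = ev.build_consensus(a, b, "C2_tumor_favouring")
        c1_tumor = (c1.labels == LABEL_TUMOR) & ~c1.excluded
        c2_tumor = c2.labels == LABEL_TUMOR
        assert not (c1_tumor & ~c2_tumor).any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ev.build_consensus(np.ones((2, 2), dtype=np.uint8), np.ones((3, 3), dtype=np.uint8))


class TestConfusion:
    def test_perfect_prediction(self):
        labels = mask_of([[1, 1], [2, 2]])
        gt = ev.build_consensus(labels, labels, "C1")
        cm = ev.confusion(labels == 1, gt)
        assert (cm.fp, cm.fn) == (0, 0)
        assert (cm.tp, cm.tn) == (2, 2)

    def test_inverted_prediction(self):
        labels = mask_of([[1, 1], [2, 2]])
        gt = ev.build_consensus(labels, labels, "C1")
        cm = ev.confusion(labels != 1, gt)
        assert (cm.tp, cm.tn) == (0, 0)

    def test_hand_enumerated_4x4(self):
        actual = mask_of(
            [[1, 1, 1, 1], [1, 1, 2, 2], [2, 2, 2, 2], [1, 2, 1, 2]]
        )
        pred = np.array(
            [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]], dtype=bool
        )
        gt = ev.build_consensus(actual, actual, "C1")
        cm = ev.confusion(pred, gt)
        # by direct count over the 16 pixels:
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (4, 2, 4, 6)
        assert cm.total == 16

    def test_excluded_pixels_not_counted(self):
        a = mask_of([[1, 1], [2, 2]])
        b = mask_of([[1, 2], [2, 2]])
        gt = ev.build_consensus(a, b, "C1")
        cm = ev.confusion(np.ones((2, 2), dtype=bool), gt)
        assert cm.total == 3


class TestMetrics:
    def test_c2_table_printed_percentages(self):
        cm = ev.ConfusionMatrix(tp=63_287_184, fp=1_536_088, fn=1_448_585, tn=12_231_468)
        report = ev.metrics(cm)
        assert ev.percent_display(report.sensitivity) == "97.8"
        assert ev.percent_display(report.specificity) == "88.8"
        assert ev.percent_display(report.overall_accuracy) == "96.2"
        assert ev.percent_display(report.ppv) == "97.6"
        assert ev.percent_display(report.npv) == "89.4"

    def test_c1_table_printed_percentages(self):
        cm = ev.ConfusionMatrix(tp=64_507_911, fp=328_719, fn=200_560, tn=13_482_410)
        report = ev.metrics(cm)
        assert ev.percent_display(report.ppv) == "99.5"
        assert ev.percent_display(report.npv) == "98.5"
        assert ev.percent_display(report.sensitivity) == "99.7"
        assert ev.percent_display(report.specificity) == "97.6"
        assert ev.percent_display(report.overall_accuracy) == "99.3"

    def test_perfect_counts(self):
        report = ev.metrics(ev.ConfusionMatrix(tp=50, fp=0, fn=0, tn=50))
        for name in ("sensitivity", "specificity", "ppv", "npv", "overall_accuracy"):
            assert getattr(report, name) == 1.0
            assert ev.percent_display(getattr(report, name)) == "100.0"

    def test_zero_denominator_is_undefined_not_zero(self):
        report = ev.metrics(ev.ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert report.sensitivity is None
        assert report.ppv is None
        assert report.specificity == 1.0

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            ev.ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestBalancedSubsample:
    def _gt(self, n_tumor=400, n_non=100, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.full(n_tumor + n_non, LABEL_NON_TUMOR, dtype=np.uint8)
        labels[:n_tumor] = LABEL_TUMOR
        labels = rng.permutation(labels).reshape(25, -1)
        gt = ev.build_consensus(labels, labels, "C1")
        return labels, gt

    def test_equal_class_totals(self, rng):
        labels, gt = self._gt()
        pred = rng.random(labels.shape) < 0.8
        cm = ev.balanced_subsample(pred, gt, seed=1)
        assert cm.tp + cm.fn == 100
        assert cm.fp + cm.tn == 100

    def test_seed_determinism(self, rng):
        labels, gt = self._gt()
        pred = rng.random(labels.shape) < 0.8
        a = ev.balanced_subsample(pred, gt, seed=42)
        b = ev.balanced_subsample(pred, gt, seed=42)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)

    def test_upsample_mode_reaches_majority_count(self, rng):
        labels, gt = self._gt()
        pred = rng.random(labels.shape) < 0.5
        cm = ev.balanced_subsample(pred, gt, seed=0, mode="upsample")
        assert cm.tp + cm.fn == 400
        assert cm.fp + cm.tn == 400

    def test_single_class_rejected(self):
        labels = np.full((10, 10), LABEL_TUMOR, dtype=np.uint8)
        gt = ev.build_consensus(labels, labels, "C1")
        with pytest.raises(ValueError):
            ev.balanced_subsample(np.ones((10, 10), dtype=bool), gt, seed=0)

    def test_mean_balanced_rates_match_unbalanced(self, rng):
        labels, gt = self._gt(n_tumor=2000, n_non=500)
        pred = rng.random(labels.size).reshape(labels.shape) < np.where(labels == 1, 0.9, 0.2)
        unbalanced = ev.metrics(ev.confusion(pred, gt))
        sens, spec = [], []
        for seed in range(200):
            m = ev.metrics(ev.balanced_subsample(pred, gt, seed=seed))
            sens.append(m.sensitivity)
            spec.append(m.specificity)
        assert np.mean(sens) == pytest.approx(unbalanced.sensitivity, abs=0.01)
        assert np.mean(spec) == pytest.approx(unbalanced.specificity, abs=0.01)


class TestRoc:
    def _gt(self, labels):
        return ev.build_consensus(labels, labels, "C1")

    def test_endpoints(self, rng):
        labels = rng.integers(1, 3, (20, 20)).astype(np.uint8)
        points = ev.roc_curve(rng.random((20, 20)), self._gt(labels), [0.0, 1.0 + 1e-9])
        assert (points[0].fpr, points[0].tpr) == (1.0, 1.0)
        assert (points[-1].fpr, points[-1].tpr) == (0.0, 0.0)

    def test_perfect_map_auc_one(self, rng):
        labels = rng.integers(1, 3, (30, 30)).astype(np.uint8)
        perfect = (labels == LABEL_TUMOR).astype(float)
        points = ev.roc_curve(perfect, self._gt(labels))
        assert ev.roc_auc(points) == pytest.approx(1.0)

    def test_random_map_auc_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 3, (200, 200)).astype(np.uint8)
        aucs = []
        for seed in range(5):
            noise = np.random.default_rng(seed).random((200, 200))
            aucs.append(ev.roc_auc(ev.roc_curve(noise, self._gt(labels))))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_curve_monotone(self, rng):
        labels = rng.integers(1, 3, (50, 50)).astype(np.uint8)
        points = ev.roc_curve(rng.random((50, 50)), self._gt(labels))
        fprs = [p.fpr for p in points]
        tprs = [p.tpr for p in points]
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))
        assert all(a >= b for a, b in zip(tprs, tprs[1:]))


class TestReaderAgreement:
    def test_identical_masks(self, rng):
        labels = rng.integers(1, 3, (10, 10)).astype(np.uint8)
        assert ev.reader_agreement(labels, labels, "tumor") == 1.0
        assert ev.reader_agreement(labels, labels, "non_tumor") == 1.0

    def test_disjoint_tumor(self):
        a = mask_of([[1, 2]])
        b = mask_of([[2, 1]])
        assert ev.reader_agreement(a, b, "tumor") == 0.0

    def test_partial_overlap(self):
        a = np.full((10, 20), LABEL_NON_TUMOR, dtype=np.uint8)
        a[:, :10] = LABEL_TUMOR  # A: 100 tumor px
        b = a.copy()
        b[:, 8:10] = LABEL_NON_TUMOR  # B keeps 80 of them
        b[:, 10:12] = LABEL_TUMOR  # and adds 20 new
        assert ev.reader_agreement(a, b, "tumor") == pytest.approx(80 / 120)

    def test_empty_union_undefined(self):
        a = np.full((5, 5), LABEL_NON_TUMOR, dtype=np.uint8)
        assert ev.reader_agreement(a, a, "tumor") is None
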