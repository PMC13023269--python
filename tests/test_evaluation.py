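"""Detection metrics: examples, brute-force AP oracle, invariants."""

import numpy as np
import pytest

from wattdet.evaluation import (Detection, TruthBox, average_precision,
                                confusion_matrix, f1, iou,
                                map_over_thresholds, match_and_count, nms)


def det(cls, box, conf, img=0):
    return Detection(cls, np.asarray(box, float), conf, image_id=img)


def tru(cls, box, img=0):
    return TruthBox(cls, np.asarray(box, float), image_id=img)


# ---------------------------------------------------------------- oracle

def oracle_ap(flags, n_truths, grid=200_001):
    """Independent AP: dense numerical integration of the envelope."""
    if n_truths == 0 or not flags:
        return 0.0
    tp = fp = 0
    points = [(0.0, 1.0)]
    for f in flags:
        tp, fp = tp + bool(f), fp + (not f)
        points.append((tp / n_truths, tp / (tp + fp)))
    rs = np.linspace(0.0, points[-1][0], grid)
    env = np.zeros_like(rs)
    for r, p in points:
        env[rs <= r + 1e-15] = np.maximum(env[rs <= r + 1e-15], p)
    return float(np.trapezoid(env, rs))


class TestIou:
    def test_identical(self):
        assert iou([0, 0, 2, 2], [0, 0, 2, 2]) == 1.0

    def test_disjoint(self):
        assert iou([0, 0, 1, 1], [5, 5, 6, 6]) == 0.0

    def test_closed_form_third(self):
        assert iou([0, 0, 2, 2], [1, 0, 3, 2]) == pytest.approx(1 / 3)

    def test_range(self, rng):
        for _ in range(100):
            a = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0).T.ravel()
            b = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0).T.ravel()
            a = [a[0], a[2], a[1], a[3]]
            b = [b[0], b[2], b[1], b[3]]
            assert 0.0 <= iou(a, b) <= 1.0


class TestNms:
    def test_same_class_high_overlap_keeps_best(self):
        d1 = det(0, [0, 0, 10, 10], 0.9)
        d2 = det(0, [0.5, 0, 10, 10], 0.8)
        kept = nms([d1, d2], iou_thresh=0.7)
        assert kept == [d1]

    def test_different_classes_both_kept(self):
        d1 = det(0, [0, 0, 10, 10], 0.9)
        d2 = det(1, [0, 0, 10, 10], 0.8)
        assert len(nms([d1, d2])) == 2

    def test_low_confidence_dropped(self):
        assert nms([det(0, [0, 0, 1, 1], 0.1)], conf_thresh=0.25) == []

    def test_no_surviving_pair_overlaps(self, rng):
        dets = [det(0, np.sort(rng.uniform(0, 20, 2)).tolist()
                    + np.sort(rng.uniform(0, 20, 2)).tolist(), 0)
                for _ in range(30)]
        dets = [det(0, [b.box[0], b.box[2], b.box[1], b.box[3]],
                    float(rng.uniform(0.3, 1))) for b in dets]
        kept = nms(dets, iou_thresh=0.5)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert iou(a.box, b.box) <= 0.5


class TestMatchAndCount:
    def test_perfect_predictions(self):
        truths = [tru(0, [0, 0, 2, 2]), tru(1, [5, 5, 8, 8])]
        dets = [det(0, [0, 0, 2, 2], 0.9), det(1, [5, 5, 8, 8], 0.8)]
        tp, fp, fn, _ = match_and_count(dets, truths)
        assert (tp, fp, fn) == (2, 0, 0)

    def test_no_detections(self):
        truths = [tru(0, [0, 0, 1, 1])] * 3
        tp, fp, fn, flags = match_and_count([], truths)
        assert (tp, fp, fn) == (0, 0, 3)
        assert flags == []

    def test_ranked_tp_fp_tp(self):
        truths = [tru(0, [0, 0, 4, 4]), tru(0, [10, 10, 14, 14])]
        dets = [det(0, [0, 0, 4, 4], 0.9),          # TP
                det(0, [20, 20, 24, 24], 0.8),      # FP
                det(0, [10, 10, 14, 14], 0.7)]      # TP
        tp, fp, fn, flags = match_and_count(dets, truths)
        assert (tp, fp, fn) == (2, 1, 0)
        assert flags == [True, False, True]

    def test_wrong_class_is_fp(self):
        truths = [tru(0, [0, 0, 4, 4])]
        dets = [det(1, [0, 0, 4, 4], 0.9)]
        assert match_and_count(dets, truths)[:3] == (0, 1, 1)

    def test_one_to_one_matching(self):
        truths = [tru(0, [0, 0, 4, 4])]
        dets = [det(0, [0, 0, 4, 4], 0.9), det(0, [0, 0, 4, 4], 0.8)]
        assert match_and_count(dets, truths)[:3] == (1, 1, 0)


class TestAveragePrecision:
    def test_single_tp_full_ap(self):
        assert average_precision([True], 1) == pytest.approx(1.0)

    def test_tp_fp_tp_is_five_sixths(self):
        assert average_precision([True, False, True], 2) == \
            pytest.approx(5 / 6)

    def test_all_fp_zero(self):
        assert average_precision([False] * 5, 3) == 0.0

    def test_matches_bruteforce_oracle_500_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n_t = int(rng.integers(1, 8))
            n_d = int(rng.integers(0, 20))
            flags = rng.random(n_d) < 0.5
            flags = list(flags[: min(n_d, n_t + n_d)])
            # at most n_t true positives
            while sum(flags) > n_t:
                flags[max(i for i, f in enumerate(flags) if f)] = False
            got = average_precision(flags, n_t)
            ref = oracle_ap(flags, n_t)
            assert got == pytest.approx(ref, abs=2e-4)


class TestMapOverThresholds:
    def _toy(self):
        truths = [tru(0, [0, 0, 10, 10]), tru(1, [20, 20, 28, 28])]
        dets = [det(0, [0, 0, 10, 10], 0.95),
                det(1, [20, 20, 27.5, 28], 0.9)]
        return dets, truths

    def test_restriction_monotonicity(self, rng):
        for _ in range(25):
            truths = [tru(int(rng.integers(2)),
                          np.r_[np.sort(rng.uniform(0, 50, 2)),
                                np.sort(rng.uniform(0, 50, 2))]
                          [[0, 2, 1, 3]], img=int(rng.integers(2)))
                      for _ in range(int(rng.integers(1, 6)))]
            dets = [det(int(rng.integers(2)),
                        np.r_[np.sort(rng.uniform(0, 50, 2)),
                              np.sort(rng.uniform(0, 50, 2))][[0, 2, 1, 3]],
                        float(rng.uniform(0.3, 1)), img=int(rng.integers(2)))
                    for _ in range(int(rng.integers(0, 8)))]
            m50, m5095, _ = map_over_thresholds(dets, truths, num_classes=2)
            assert m5095 <= m50 + 1e-12

    def test_perfect_toy(self):
        dets, truths = self._toy()
        m50, m5095, per = map_over_thresholds(dets, truths, num_classes=6)
        assert m50 == pytest.approx(1.0)
        assert 0 < m5095 <= 1.0

    def test_permutation_invariance(self, rng):
        dets, truths = self._toy()
        dets += [det(0, [3, 3, 9, 9], 0.5), det(1, [19, 21, 29, 27], 0.5)]
        m_a = map_over_thresholds(dets, truths, 6)[:2]
        m_b = map_over_thresholds(dets, truths[::-1], 6)[:2]
        assert m_a == pytest.approx(m_b)


class TestConfusionMatrix:
    def test_perfect_detector_diagonal(self):
        truths = [tru(c, [10 * c, 0, 10 * c + 8, 8]) for c in range(6)]
        dets = [det(c, [10 * c, 0, 10 * c + 8, 8], 0.9) for c in range(6)]
        mat, norm = confusion_matrix(dets, truths)
        assert np.array_equal(np.diag(mat)[:6], np.ones(6))
        assert mat.sum() == 6
        assert np.allclose(norm[:6].sum(axis=1), 1.0)

    def test_no_detections_background_column(self):
        truths = [tru(2, [0, 0, 5, 5]), tru(3, [10, 10, 15, 15])]
        mat, _ = confusion_matrix([], truths)
        assert mat[2, 6] == 1 and mat[3, 6] == 1
        assert mat.sum() == 2

    def test_class_swap_off_diagonal(self):
        truths = [tru(0, [0, 0, 8, 8]), tru(1, [20, 0, 28, 8]),
                  tru(2, [40, 0, 48, 8])]
        dets = [det(0, [0, 0, 8, 8], 0.9), det(4, [20, 0, 28, 8], 0.85),
                det(2, [40, 0, 48, 8], 0.8)]
        mat, _ = confusion_matrix(dets, truths)
        assert mat[1, 4] == 1
        assert mat[0, 0] == 1 and mat[2, 2] == 1

    def test_row_sums_equal_truth_counts(self, rng):
        truths = [tru(int(rng.integers(6)),
                      [i * 10, 0, i * 10 + 6, 6]) for i in range(8)]
        dets = [det(int(rng.integers(6)), [i * 10, 0, i * 10 + 6, 6],
                    float(rng.uniform(0.3, 1))) for i in range(5)]
        mat, _ = confusion_matrix(dets, truths)
        counts = np.bincount([t.class_id for t in truths], minlength=6)
        assert np.array_equal(mat[:6, :].sum(axis=1), counts)


class TestF1:
    def test_equal_p_r(self):
        assert f1(0.7, 0.7) == pytest.approx(0.7)

    def test_zero_precision(self):
        assert f1(0.0, 0.9) == 0.0

    def test_printed_aggregate(self):
        # the rounded inputs give 0.9355; the published table prints 0.936
        # (computed from unrounded precision/recall)
        assert f1(0.937, 0.934) == pytest.approx(0.936, abs=1.5e-3)


def test_gradcam_contract(tiny_baseline_model, rng):
    from wattdet.evaluation import gradcam_heatmap

    img = rng.random((3, 64, 64)).astype(np.float32)
    cam = gradcam_heatmap(tiny_baseline_model, img, layer_tag=9)
    assert cam.shape == (64, 64)
    assert cam.min() >= 0.0 and cam.max() <= 1.0
    cam2 = gradcam_heatmap(tiny_baseline_model, img, layer_tag=9)
    assert np.array_equal(cam, cam2)
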