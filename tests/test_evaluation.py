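import numpy as np
import pytest

from glomkit.core import GlomerulusInstance, LesionClass, MultiClassMask
from glomkit.evaluation import (
    MatchConfig,
    MatchResult,
    average_precision,
    bootstrap_ci,
    dice_per_class,
    evaluate_slides,
    match_instances,
    optimal_match_count,
    weighted_average,
)
from conftest import disk_mask


def _disk_instance(center, radius, iid, lesion=LesionClass.NL, conf=1.0, shape=(200, 200)):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    sel = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return GlomerulusInstance(iid, lesion, np.argwhere(sel), conf)


class TestMatching:
    def test_identical_sets_all_tp(self):
        gts = [_disk_instance((50, 50), 15, 1), _disk_instance((120, 120), 15, 2)]
        results, missed = match_instances(gts, gts)
        assert all(r.is_tp for r in results)
        assert missed == []

    def test_forty_percent_coverage_is_fp_and_fn(self):
        gt = _disk_instance((50, 50), 20, 1)
        pred_pixels = gt.pixels[: int(0.4 * len(gt.pixels))]
        pred = GlomerulusInstance(1, LesionClass.NL, pred_pixels, 0.9)
        results, missed = match_instances([pred], [gt])
        assert not results[0].is_tp
        assert missed == [1]

    def test_greedy_order_hand_example(self):
        # 3 perfect predictions (conf .9/.8/.7) + 1 spurious at .95
        gts = [
            _disk_instance((40, 40), 12, 1),
            _disk_instance((100, 100), 12, 2),
            _disk_instance((160, 160), 12, 3),
        ]
        preds = [
            GlomerulusInstance(10, LesionClass.NL, np.argwhere(np.zeros((200, 200)) == 0)[:100], 0.95),
            GlomerulusInstance(11, LesionClass.NL, gts[0].pixels, 0.9),
            GlomerulusInstance(12, LesionClass.NL, gts[1].pixels, 0.8),
            GlomerulusInstance(13, LesionClass.NL, gts[2].pixels, 0.7),
        ]
        results, missed = match_instances(preds, gts)
        assert [r.is_tp for r in results] == [False, True, True, True]
        assert missed == []

    def test_class_mismatch_blocks_match(self):
        gt = _disk_instance((50, 50), 15, 1, LesionClass.GS)
        pred = _disk_instance((50, 50), 15, 1, LesionClass.NL)
        results, missed = match_instances([pred], [gt])
        assert not results[0].is_tp
        results, _ = match_instances([pred], [gt], MatchConfig(require_class_match=False))
        assert results[0].is_tp

    def test_greedy_equals_exhaustive_on_random_scenes(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_gt = int(rng.integers(1, 7))
            gts, preds = [], []
            placed = []
            for i in range(n_gt):
                # ground-truth instances are disjoint, like a mask partition
                for _attempt in range(50):
                    center = rng.uniform(25, 175, 2)
                    radius = rng.uniform(8, 16)
                    if all(np.hypot(*(center - c)) > radius + r + 2 for c, r in placed):
                        break
                else:
                    continue
                placed.append((center, radius))
                lesion = LesionClass(int(rng.integers(0, 5)))
                gts.append(_disk_instance(center, radius, i + 1, lesion))
                if rng.random() < 0.85:  # jittered prediction
                    jitter = center + rng.normal(0, 4, 2)
                    preds.append(
                        _disk_instance(
                            jitter, radius * rng.uniform(0.8, 1.2), 100 + i, lesion,
                            conf=float(rng.random()),
                        )
                    )
            if rng.random() < 0.4:  # spurious prediction
                preds.append(
                    _disk_instance(rng.uniform(25, 175, 2), 10, 999,
                                   LesionClass(int(rng.integers(0, 5))),
                                   conf=float(rng.random()))
                )
            results, _ = match_instances(preds, gts)
            greedy_tp = sum(r.is_tp for r in results)
            assert greedy_tp == optimal_match_count(preds, gts)


class TestAveragePrecision:
    def _slide(self, flags_confs):
        return [
            MatchResult(i, LesionClass.NL, conf, i if tp else None, tp, 1.0 if tp else 0.0)
            for i, (conf, tp) in enumerate(flags_confs)
        ]

    def test_perfect_predictions_ap_one(self):
        slide = self._slide([(0.9, True), (0.8, True)])
        assert average_precision([slide], 2, LesionClass.NL).ap == 1.0

    def test_no_predictions_ap_zero(self):
        assert average_precision([[]], 3, LesionClass.NL).ap == 0.0

    def test_no_ground_truth_undefined(self):
        assert average_precision([[]], 0, LesionClass.NL) is None

    def test_hand_computed_example(self):
        slide = self._slide([(0.95, False), (0.9, True), (0.8, True), (0.7, True)])
        curve = average_precision([slide], 3, LesionClass.NL)
        want = (1 / 3) * (1 / 2) + (1 / 3) * (2 / 3) + (1 / 3) * (3 / 4)
        assert curve.ap == pytest.approx(want, abs=1e-9)
        np.testing.assert_allclose(curve.recalls, [0, 1 / 3, 2 / 3, 1])
        np.testing.assert_allclose(curve.precisions, [0, 1 / 2, 2 / 3, 3 / 4])

    def test_invariant_to_slide_order(self):
        s1 = self._slide([(0.9, True), (0.5, False)])
        s2 = self._slide([(0.7, True), (0.6, False)])
        a = average_precision([s1, s2], 4, LesionClass.NL).ap
        b = average_precision([s2, s1], 4, LesionClass.NL).ap
        assert a == b


class TestDice:
    def test_identical_masks_one(self):
        m = disk_mask((64, 64), (32, 32), 10)
        assert dice_per_class([m], [m], LesionClass.NL) == 1.0

    def test_disjoint_masks_zero(self):
        a = disk_mask((64, 64), (16, 16), 8)
        b = disk_mask((64, 64), (48, 48), 8)
        assert dice_per_class([a], [b], LesionClass.NL) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((10, 30), dtype=np.uint8)
        b = np.zeros((10, 30), dtype=np.uint8)
        a[0, :10] = 1
        b[0, 5:15] = 1
        got = dice_per_class(
            [MultiClassMask(a, 1.0)], [MultiClassMask(b, 1.0)], LesionClass.NL
        )
        assert got == pytest.approx(2 * 5 / 20)

    def test_absent_class_undefined(self):
        m = disk_mask((16, 16), (8, 8), 3, label=1)
        assert dice_per_class([m], [m], LesionClass.GS) is None


class TestWeightedAverage:
    def test_reproduces_internal_validation_weighted_ap(self):
        ap = [0.834, 0.785, 0.505, 0.446, 0.438]
        counts = [1579, 410, 126, 31, 31]
        assert round(weighted_average(ap, counts), 3) == 0.795

    def test_equal_counts_plain_mean(self):
        assert weighted_average([0.2, 0.4, 0.6], [5, 5, 5]) == pytest.approx(0.4)

    def test_single_nonzero_count(self):
        assert weighted_average([0.2, 0.9], [0, 7]) == 0.9

    def test_missing_class_excluded_with_count(self):
        assert weighted_average([0.5, None], [10, 90]) == 0.5

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            weighted_average([0.5], [0])


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda xs: 0.7, list(range(10)), B=200, seed=0)
        assert lo == hi == 0.7

    def test_same_seed_identical(self):
        data = list(np.random.default_rng(0).normal(size=50))
        a = bootstrap_ci(np.mean, data, B=300, seed=5)
        b = bootstrap_ci(np.mean, data, B=300, seed=5)
        assert a == b

    def test_coverage_of_the_mean(self):
        rng = np.random.default_rng(123)
        hits = 0
        for rep in range(100):
            data = list(rng.normal(size=200))
            lo, hi = bootstrap_ci(np.mean, data, B=200, seed=rep)
            hits += lo <= 0.0 <= hi
        assert hits >= 90


class TestEvaluateSlides:
    def test_identity_evaluation_all_ones(self, tiny_slide):
        from glomkit.instances import instances_from_label_map

        _, mask, man = tiny_slide
        insts = instances_from_label_map(man.label_map, mask)
        report = evaluate_slides(
            [
                {
                    "pred_instances": insts,
                    "gt_instances": insts,
                    "pred_mask": mask,
                    "gt_mask": mask,
                }
            ]
            * 3,
            B=100,
        )
        for cls in LesionClass:
            if report.gt_counts[cls.name]:
                assert report.per_class_ap[cls.name] == 1.0
                assert report.per_class_dsc[cls.name] == 1.0
        assert report.weighted_ap == 1.0
        assert report.weighted_dsc == 1.0
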