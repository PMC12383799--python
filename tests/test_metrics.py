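import numpy as np
import pytest

from cardioseg import (LabelMap, MetricReport, aggregate_cv, assd,
                       dice_multiclass, evaluate_prediction)
from cardioseg.metrics import boundary_mask


def brute_force_boundary(mask):
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.argwhere(mask):
        for axis in range(mask.ndim):
            for step in (-1, 1):
                n = idx.copy()
                n[axis] += step
                if (n < 0).any() or (n >= np.array(mask.shape)).any() \
                        or not mask[tuple(n)]:
                    out[tuple(idx)] = True
                    break
            if out[tuple(idx)]:
                break
    return out


def brute_force_assd(a, b, spacing):
    """All-pairs surface distances between boundary voxel centers."""
    ba = np.argwhere(brute_force_boundary(a)) * np.asarray(spacing)
    bb = np.argwhere(brute_force_boundary(b)) * np.asarray(spacing)
    dists = np.sqrt(((ba[:, None, :] - bb[None, :, :]) ** 2).sum(-1))
    return (dists.min(axis=1).sum() + dists.min(axis=0).sum()) \
        / (len(ba) + len(bb))


class TestDice:
    def test_perfect_and_disjoint(self, rng):
        lab = LabelMap(rng.integers(0, 3, (8, 8)).astype(np.int32), 3)
        per, mean = dice_multiclass(lab, lab)
        assert mean == 100.0 and all(v == 100.0 for v in per.values())
        a = LabelMap(np.array([[1, 1], [0, 0]], np.int32), 2)
        b = LabelMap(np.array([[0, 0], [1, 1]], np.int32), 2)
        _, mean = dice_multiclass(a, b)
        assert mean == 0.0

    def test_counted_overlap(self):
        a = np.zeros((4, 4), np.int32)
        b = np.zeros((4, 4), np.int32)
        a[0, :4] = 1          # |y| = 4
        b[0, 2:] = 1          # |ŷ| = 4, overlap 2
        b[1, :2] = 1
        per, _ = dice_multiclass(LabelMap(a, 2), LabelMap(b, 2))
        assert per[1] == pytest.approx(200.0 * 2 / 8)

    def test_empty_empty_scores_hundred(self):
        a = LabelMap(np.zeros((4, 4), np.int32), 3)
        per, mean = dice_multiclass(a, a, classes=[1, 2])
        assert per[1] == per[2] == 100.0

    def test_symmetry(self, rng):
        a = LabelMap(rng.integers(0, 4, (10, 10)).astype(np.int32), 4)
        b = LabelMap(rng.integers(0, 4, (10, 10)).astype(np.int32), 4)
        assert dice_multiclass(a, b)[1] == dice_multiclass(b, a)[1]


class TestASSD:
    def test_identical_masks_zero(self, rng):
        lab = LabelMap((rng.random((8, 8)) < 0.4).astype(np.int32), 2)
        if not lab.classes.any():
            lab.classes[3, 3] = 1
        _, mean = assd(lab, lab)
        assert mean == 0.0

    def test_single_voxel_distance(self):
        a = np.zeros((8, 8), np.int32)
        b = np.zeros((8, 8), np.int32)
        a[2, 2] = 1
        b[2, 5] = 1
        per, _ = assd(LabelMap(a, 2), LabelMap(b, 2), spacing=(1.0, 1.0))
        assert per[1] == pytest.approx(3.0)

    def test_spacing_linearity(self):
        a = np.zeros((8, 8), np.int32)
        b = np.zeros((8, 8), np.int32)
        a[1:4, 1:4] = 1
        b[4:7, 4:7] = 1
        _, m1 = assd(LabelMap(a, 2), LabelMap(b, 2), spacing=(1, 1))
        _, m2 = assd(LabelMap(a, 2), LabelMap(b, 2), spacing=(2, 2))
        assert m2 == pytest.approx(2 * m1)

    def test_one_sided_empty_reported_missing(self):
        a = np.zeros((6, 6), np.int32)
        a[2, 2] = 1
        with pytest.warns(UserWarning):
            per, _ = assd(LabelMap(a, 2), LabelMap(np.zeros((6, 6), np.int32), 2))
        assert np.isnan(per[1])

    def test_boundary_definition_matches_brute_force(self, rng):
        for _ in range(10):
            mask = rng.random((9, 9)) < 0.5
            np.testing.assert_array_equal(boundary_mask(mask),
                                          brute_force_boundary(mask))

    def test_matches_all_pairs_oracle_2d_and_3d(self, rng):
        for dim in (2, 3):
            for _ in range(5):
                shape = (7,) * dim
                a = (rng.random(shape) < 0.3)
                b = (rng.random(shape) < 0.3)
                if not (a.any() and b.any()):
                    continue
                spacing = tuple(rng.uniform(0.5, 2.0, dim))
                per, _ = assd(LabelMap(a.astype(np.int32), 2),
                              LabelMap(b.astype(np.int32), 2),
                              spacing=spacing)
                ref = brute_force_assd(a, b, spacing)
                assert per[1] == pytest.approx(ref, rel=1e-9)


class TestEvaluatePrediction:
    def test_same_grid_equals_direct_metrics(self, rng):
        gt = LabelMap(rng.integers(0, 3, (16, 16)).astype(np.int32), 3)
        probs = np.moveaxis(rng.dirichlet(np.ones(3), (16, 16)), -1, 0)
        rep = evaluate_prediction(probs, gt, (1.0, 1.0))
        direct = LabelMap(np.argmax(probs, 0).astype(np.int32), 3)
        _, mean_direct = dice_multiclass(gt, direct)
        assert rep.mean_dsc == pytest.approx(mean_direct)

    def test_upsampled_constant_map_unchanged(self):
        gt = LabelMap(np.ones((16, 16), np.int32), 2)
        probs = np.zeros((2, 8, 8))
        probs[1] = 1.0
        rep = evaluate_prediction(probs, gt, (1.0, 1.0))
        assert rep.mean_dsc == pytest.approx(100.0)

    def test_half_resolution_disc_close_to_full(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disc = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 8 ** 2)
        gt = LabelMap(disc.astype(np.int32), 2)
        # rasterize the same disc on the half-resolution grid (center-aligned)
        yh, xh = np.mgrid[0:16, 0:16]
        ch = (16 - 0.5) / 2.0
        disc_h = ((yh - ch) ** 2 + (xh - ch) ** 2 <= 4 ** 2)
        probs = np.stack([(~disc_h).astype(float), disc_h.astype(float)])
        rep = evaluate_prediction(probs, gt, (1.0, 1.0))
        assert rep.mean_dsc > 90.0

    def test_ground_truth_untouched(self, rng):
        gt_arr = rng.integers(0, 2, (16, 16)).astype(np.int32)
        gt = LabelMap(gt_arr.copy(), 2)
        probs = np.moveaxis(rng.dirichlet(np.ones(2), (8, 8)), -1, 0)
        evaluate_prediction(probs, gt, (1.0, 1.0))
        np.testing.assert_array_equal(gt.classes, gt_arr)


class TestAggregate:
    @staticmethod
    def _report(fold, rep, sid, dsc, a=1.0):
        return MetricReport({1: dsc}, dsc, {1: a}, a, sample_id=sid,
                            fold=fold, repetition=rep)

    def test_identical_reports_zero_sigma(self):
        reps = [self._report(f, r, f"s{i}", 80.0)
                for f in range(2) for r in range(3) for i in range(2)]
        out = aggregate_cv(reps)
        assert out.loc["mean_dsc", "mu"] == pytest.approx(80.0)
        assert out.loc["mean_dsc", "sigma"] == pytest.approx(0.0)

    def test_two_fold_hand_computed(self):
        # fold 0, sample a: reps 80/84 -> mean 82 ; fold 1, sample b: 90/86
        reps = [self._report(0, 0, "a", 80.0), self._report(0, 1, "a", 84.0),
                self._report(1, 0, "b", 90.0), self._report(1, 1, "b", 86.0)]
        out = aggregate_cv(reps)
        assert out.loc["mean_dsc", "mu"] == pytest.approx((82 + 88) / 2)
        assert out.loc["mean_dsc", "sigma"] == \
            pytest.approx(np.std([82, 88], ddof=1))
        assert out.loc["mean_dsc", "mean_repetition_sigma"] == \
            pytest.approx((np.std([80, 84]) + np.std([90, 86])) / 2)

    def test_permutation_invariance(self, rng):
        reps = [self._report(f, r, f"s{i}", float(rng.uniform(60, 95)))
                for f in range(2) for r in range(2) for i in range(3)]
        a = aggregate_cv(reps)
        order = rng.permutation(len(reps))
        b = aggregate_cv([reps[i] for i in order])
        assert a.loc["mean_dsc", "mu"] == pytest.approx(b.loc["mean_dsc", "mu"])
        assert a.loc["mean_dsc", "sigma"] == \
            pytest.approx(b.loc["mean_dsc", "sigma"])

    def test_single_repetition_warns(self):
        reps = [self._report(0, 0, "a", 80.0), self._report(1, 0, "b", 85.0)]
        with pytest.warns(UserWarning):
            out = aggregate_cv(reps)
        assert out.loc["mean_dsc", "mean_repetition_sigma"] == 0.0
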