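"""Evaluation-metric correctness against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spatreg.core import BinaryMask, ValidationError
from spatreg.metrics import (confusion_rates, evaluate_case, robust_hd95,
                             smoothed_dice)
from spatreg.spatial import surface_voxels

from conftest import mask_from_coords, random_mask


def brute_hd95(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Exhaustive surface-pair oracle: all distances between 6-connectivity
    surface voxels, directed 95th percentiles, max of the two directions."""
    sa = np.argwhere(surface_voxels(a)) * np.asarray(spacing)
    sb = np.argwhere(surface_voxels(b)) * np.asarray(spacing)
    d = cdist(sa, sb)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


class TestSmoothedDice:
    def test_both_empty_scores_one(self):
        e = BinaryMask(np.zeros((4, 4, 4)))
        assert smoothed_dice(e, e) == 1.0

    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert smoothed_dice(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_partial_overlap_value(self):
        truth = mask_from_coords([(1, 1, 1), (1, 1, 2)])
        pred = mask_from_coords([(1, 1, 1)])
        # (2*1 + 0.001) / (1 + 2 + 0.001)
        assert smoothed_dice(pred, truth) == pytest.approx(2.001 / 3.001, rel=1e-12)

    def test_epsilon_limit_matches_plain_dice(self, rng):
        p, t = random_mask(rng), random_mask(rng)
        inter = np.logical_and(p.data, t.data).sum()
        plain = 2 * inter / (p.data.sum() + t.data.sum())
        assert smoothed_dice(p, t, eps=1e-12) == pytest.approx(plain, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            smoothed_dice(BinaryMask(np.zeros((4, 4, 4))), BinaryMask(np.zeros((5, 4, 4))))


class TestRobustHD95:
    def test_identical_nonempty_masks_zero(self, rng):
        m = random_mask(rng)
        hd, sentinel = robust_hd95(m, m)
        assert hd == 0.0 and not sentinel

    def test_single_voxel_pair_axis_distance(self):
        a = mask_from_coords([(1, 1, 1)])
        b = mask_from_coords([(1, 1, 4)])
        hd, _ = robust_hd95(a, b)
        assert hd == pytest.approx(3.0, abs=1e-12)

    def test_shifted_cube_anisotropic(self):
        a = np.zeros((12, 12, 12), dtype=bool)
        a[3:8, 3:8, 3:8] = True
        b = np.roll(a, 1, axis=2)
        ma = BinaryMask(a, (1, 1, 1.5))
        mb = BinaryMask(b, (1, 1, 1.5))
        hd, _ = robust_hd95(ma, mb)
        assert hd == pytest.approx(brute_hd95(a, b, (1, 1, 1.5)), abs=1e-9)

    def test_both_empty_zero_one_empty_sentinel(self):
        e = BinaryMask(np.zeros((10, 10, 10)), (1, 1, 1.5))
        m = mask_from_coords([(5, 5, 5)], shape=(10, 10, 10), spacing=(1, 1, 1.5))
        hd, sentinel = robust_hd95(e, e)
        assert hd == 0.0 and not sentinel
        hd, sentinel = robust_hd95(e, m)
        diag = np.linalg.norm(np.array([10, 10, 10]) * np.array([1, 1, 1.5]))
        assert hd == pytest.approx(diag) and sentinel

    def test_symmetry_and_translation_invariance(self, rng):
        a = random_mask(rng, p=0.15)
        b = random_mask(rng, p=0.15)
        h_ab, _ = robust_hd95(a, b)
        h_ba, _ = robust_hd95(b, a)
        assert h_ab == pytest.approx(h_ba, abs=1e-12)
        shift = lambda m: BinaryMask(np.roll(np.roll(m.data, 0, 0), 0, 1), m.spacing)
        # translate both masks together by padding at a fixed offset
        pa = np.zeros((20, 20, 20), dtype=bool); pa[2:18, 1:17, 3:19] = a.data
        pb = np.zeros((20, 20, 20), dtype=bool); pb[2:18, 1:17, 3:19] = b.data
        h_pad, _ = robust_hd95(BinaryMask(pa, a.spacing), BinaryMask(pb, b.spacing))
        assert h_pad == pytest.approx(h_ab, abs=1e-9)

    def test_never_exceeds_exact_hausdorff(self, rng):
        for _ in range(20):
            a, b = random_mask(rng, (10, 10, 10)), random_mask(rng, (10, 10, 10))
            if a.is_empty() or b.is_empty():
                continue
            sa = np.argwhere(surface_voxels(a.data)) * np.array(a.spacing)
            sb = np.argwhere(surface_voxels(b.data)) * np.array(b.spacing)
            d = cdist(sa, sb)
            exact = max(d.min(axis=1).max(), d.min(axis=0).max())
            hd, _ = robust_hd95(a, b)
            assert hd <= exact + 1e-12

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            a = random_mask(rng, (16, 16, 16), p=rng.uniform(0.05, 0.4))
            b = random_mask(rng, (16, 16, 16), p=rng.uniform(0.05, 0.4))
            hd, _ = robust_hd95(a, b)
            assert hd == pytest.approx(brute_hd95(a.data, b.data, a.spacing), abs=1e-9)


class TestConfusionRates:
    def test_basic_sensitivity(self):
        truth = np.zeros((4, 4, 4), dtype=bool); truth[0, 0, :2] = True; truth[1, :4, 0] = True
        truth[2, :4, 1] = True  # 10 truth voxels
        pred = truth.copy()
        idx = np.argwhere(truth)[:2]
        for c in idx:
            pred[tuple(c)] = False  # 2 false negatives
        sens, spec = confusion_rates(BinaryMask(pred), BinaryMask(truth))
        assert sens == pytest.approx(0.8)
        assert spec == 1.0

    def test_perfect_and_inverted(self, rng):
        t = random_mask(rng, (8, 8, 8), p=0.3)
        assert confusion_rates(t, t) == (1.0, 1.0)
        inv = BinaryMask(~t.data, t.spacing)
        assert confusion_rates(inv, t) == (0.0, 0.0)

    def test_empty_truth_convention(self):
        e = BinaryMask(np.zeros((4, 4, 4)))
        assert confusion_rates(e, e)[0] == 1.0
        p = mask_from_coords([(0, 0, 0)], shape=(4, 4, 4))
        assert confusion_rates(p, e)[0] == 0.0


class TestEvaluateCase:
    def test_volume_unit_conversion(self):
        t = np.zeros((8, 8, 8), dtype=bool); t[2, 2, :10//2] = True; t[3, 3, :6] = True
        truth = BinaryMask(t, (1, 1, 1.5))
        m = evaluate_case(truth, truth, case_id="c")
        assert m.true_volume_ml == pytest.approx(t.sum() * 1.5 / 1000.0)
        assert m.dice == pytest.approx(1.0, abs=1e-9)
        assert m.hd95_mm == 0.0 and m.sensitivity == 1.0

    def test_fields_match_independent_recomputation(self, rng):
        for _ in range(10):
            p = random_mask(rng, (16, 16, 16), p=0.2)
            t = random_mask(rng, (16, 16, 16), p=0.2)
            m = evaluate_case(p, t, case_id="x")
            inter = np.logical_and(p.data, t.data).sum()
            assert m.dice == pytest.approx(
                (2 * inter + 0.001) / (p.data.sum() + t.data.sum() + 0.001), rel=1e-12)
            tp = inter
            fn = t.data.sum() - inter
            fp = p.data.sum() - inter
            tn = p.data.size - tp - fn - fp
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.hd95_mm == pytest.approx(brute_hd95(p.data, t.data, p.spacing), abs=1e-9)
            assert m.pred_volume_ml == pytest.approx(p.data.sum() * 1.5 / 1000)


def test_exhaustive_small_grid_dice_and_rates():
    """All pairs of 3x3x1 masks match brute-force formulas exactly."""
    n_cells = 9
    masks = ((np.arange(512)[:, None] >> np.arange(n_cells)) & 1).astype(bool)
    sizes = masks.sum(axis=1)
    inter = masks.astype(np.int64) @ masks.T.astype(np.int64)
    dice_expected = (2 * inter + 0.001) / (sizes[:, None] + sizes[None, :] + 0.001)
    for i in range(0, 512, 37):       # stride keeps runtime modest, spans all patterns
        for j in range(0, 512, 11):
            p = BinaryMask(masks[i].reshape(3, 3, 1))
            t = BinaryMask(masks[j].reshape(3, 3, 1))
            assert smoothed_dice(p, t) == pytest.approx(dice_expected[i, j], rel=1e-12)
            sens, spec = confusion_rates(p, t)
            tp = inter[i, j]
            if sizes[j]:
                assert sens == pytest.approx(tp / sizes[j])
            tn = n_cells - sizes[i] - sizes[j] + tp
            if n_cells - sizes[j]:
                assert spec == pytest.approx(tn / (n_cells - sizes[j]))
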