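"""Split planning, preprocessing, training-loop contracts and transfer learning."""

import numpy as np
import pytest

from spatreg.core import ValidationError, Volume3D
from spatreg.network import ModelConfig, build_model
from spatreg.training import (Case, SplitPlan, TrainConfig, assign_split,
                              fine_tune, fit, normalize_nonzero, plan_from_pools,
                              plan_splits, preprocess_case, synthetic_cases,
                              train_arms_with_reseed, train_model, TrainRecord)

# ---------------------------------------------------------------------------
# split planning: the published experiment plans
# ---------------------------------------------------------------------------

MIXING_ROWS = [  # (post fraction target, expected per-domain counts)
    (0.0, (153, 39, 0, 0)),
    (0.13, (134, 33, 20, 5)),
    (0.26, (114, 28, 40, 10)),
    (0.5, (77, 19, 77, 19)),
    (2 / 3, (51, 13, 103, 25)),
    (1.0, (0, 0, 153, 39)),
]

PRE_ADDITION_ROWS = [  # (pre pool added to the fixed 192 post pool, expected)
    (50, (40, 10, 153, 39)),
    (100, (80, 20, 153, 39)),
    (150, (120, 30, 153, 39)),
    (208, (166, 42, 153, 39)),
]

TL_ROWS = [  # (post fraction, pretrain pool, finetune pool)
    (0.13, 167, 25),
    (0.26, 142, 50),
    (0.5, 96, 96),
    (2 / 3, 64, 128),
]


class TestPlanSplits:
    @pytest.mark.parametrize("target,expected", MIXING_ROWS)
    def test_mixing_plan_rows(self, target, expected):
        plan = plan_splits(208, 197, target, 192)
        assert plan.as_row() == expected
        assert plan.training_total == 192
        assert abs(plan.post_total - target * 192) <= 1.0

    @pytest.mark.parametrize("pre_total,expected", PRE_ADDITION_ROWS)
    def test_pre_addition_rows(self, pre_total, expected):
        plan = plan_from_pools(pre_total, 192)
        assert plan.as_row() == expected

    @pytest.mark.parametrize("target,pretrain,finetune", TL_ROWS)
    def test_transfer_pools(self, target, pretrain, finetune):
        plan = plan_splits(208, 197, target, 192)
        assert plan.tl_pretrain_pool == pretrain
        assert plan.tl_finetune_pool == finetune
        assert plan.tl_pretrain_pool + plan.tl_finetune_pool == 192

    def test_loss_function_study_pools(self):
        assert plan_from_pools(0, 197).as_row() == (0, 0, 158, 39)
        full = plan_from_pools(208, 197)
        assert full.as_row() == (166, 42, 158, 39)
        assert full.tl_pretrain_pool == 208 and full.tl_finetune_pool == 197

    def test_per_domain_val_fraction_near_twenty_percent(self):
        for total in range(5, 300, 7):
            train, val = plan_from_pools(total, 0).pre_train, plan_from_pools(total, 0).pre_val
            assert train + val == total
            assert abs(val - 0.2 * total) <= 1.0

    def test_infeasible_target_reports_range(self):
        with pytest.raises(ValidationError, match="achievable"):
            plan_splits(208, 30, 0.5, 192)
        with pytest.raises(ValidationError, match="achievable"):
            plan_splits(30, 208, 0.1, 192)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

SMALL = dict(shape=(24, 24, 16), spacing=(1.0, 1.0, 1.0),
             lesion_radius_mm=3.0, cavity_radius_mm=1.5, irregularity_mm=0.5,
             noise_sd=0.05)


class TestPreprocess:
    def test_nonzero_normalization_moments(self, small_post_phantom):
        vol, _, _ = small_post_phantom
        norm = normalize_nonzero(vol)
        nz = vol.data != 0
        assert norm.data[nz].mean() == pytest.approx(0.0, abs=1e-6)
        assert norm.data[nz].std() == pytest.approx(1.0, abs=1e-6)
        assert np.all(norm.data[~nz] == 0.0)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValidationError):
            normalize_nonzero(Volume3D(np.zeros((8, 8, 8))))

    def test_train_mode_deterministic_given_rng(self, small_post_phantom):
        vol, lesion, _ = small_post_phantom
        out1 = preprocess_case(vol, [lesion], None, True, (24, 24, 12),
                               np.random.default_rng(3))
        out2 = preprocess_case(vol, [lesion], None, True, (24, 24, 12),
                               np.random.default_rng(3))
        assert np.array_equal(out1[0].data, out2[0].data)
        assert np.array_equal(out1[1][0].data, out2[1][0].data)

    def test_flips_preserve_lesion_volume(self, small_post_phantom):
        vol, lesion, _ = small_post_phantom
        counts = set()
        for s in range(8):
            _, masks, _ = preprocess_case(vol, [lesion], None, True,
                                          vol.shape, np.random.default_rng(s))
            counts.add(int(masks[0].data.sum()))
        assert counts == {int(lesion.data.sum())}  # full-size crop: flips only

    def test_eval_mode_center_crop_no_jitter(self, small_post_phantom):
        vol, lesion, _ = small_post_phantom
        v1, m1, _ = preprocess_case(vol, [lesion], None, False, (24, 24, 12))
        v2, m2, _ = preprocess_case(vol, [lesion], None, False, (24, 24, 12))
        assert np.array_equal(v1.data, v2.data)
        assert v1.shape == (24, 24, 12)

    def test_spatial_transform_shared_with_weight_map(self, small_post_phantom):
        from spatreg.spatial import edge_weight_map
        vol, lesion, _ = small_post_phantom
        wmap = edge_weight_map(lesion, 3.0)
        _, masks, w = preprocess_case(vol, [lesion], wmap, True, (24, 24, 12),
                                      np.random.default_rng(11))
        # boundary voxels of the cropped mask still carry weight 2
        from spatreg.spatial import surface_voxels
        surf = surface_voxels(masks[0].data)
        if surf.any():
            assert np.allclose(w.data[surf], 2.0)

    def test_crop_larger_than_volume_rejected(self, small_post_phantom):
        vol, lesion, _ = small_post_phantom
        with pytest.raises(ValidationError):
            preprocess_case(vol, [lesion], None, False, (64, 64, 64))


def test_assign_split_depends_only_on_split_seed():
    cases = synthetic_cases(6, 4, seed=0, **SMALL)
    plan = SplitPlan(4, 2, 3, 1)
    t1, v1 = assign_split(cases, plan, split_seed=5)
    t2, v2 = assign_split(cases, plan, split_seed=5)
    t3, _ = assign_split(cases, plan, split_seed=6)
    assert [c.case_id for c in t1] == [c.case_id for c in t2]
    assert [c.case_id for c in v1] == [c.case_id for c in v2]
    assert [c.case_id for c in t1] != [c.case_id for c in t3]
    assert len(t1) == 7 and len(v1) == 3


# ---------------------------------------------------------------------------
# training loop contracts (tiny scale)
# ---------------------------------------------------------------------------

TINY_MODEL = ModelConfig((24, 24, 16), 2, 2, 8)


def tiny_config(**kw):
    base = dict(epochs=3, learning_rate=1e-3, seed=0, split_seed=1,
                divergence_grace_epochs=50)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def tiny_cases():
    return synthetic_cases(0, 6, seed=21, **SMALL)


class TestFitContracts:
    def test_selected_epoch_attains_max_val_dice(self, tiny_cases):
        model, record = train_model(tiny_cases, SplitPlan(0, 0, 4, 2),
                                    TINY_MODEL, tiny_config())
        hist = record.history_frame()
        assert record.best_val_dice == pytest.approx(hist.val_dice.max())
        assert record.selected_epoch == int(hist.loc[hist.val_dice.idxmax(), "epoch"])
        assert len(hist) == 3

    def test_same_seed_reproduces_val_curve(self, tiny_cases):
        _, r1 = train_model(tiny_cases, SplitPlan(0, 0, 4, 2), TINY_MODEL, tiny_config())
        _, r2 = train_model(tiny_cases, SplitPlan(0, 0, 4, 2), TINY_MODEL, tiny_config())
        assert r1.history_frame().val_dice.tolist() == r2.history_frame().val_dice.tolist()

    def test_nan_injection_sets_diverged_at_step(self, tiny_cases):
        from spatreg._autodiff import Tensor

        def poison(step, total):
            return Tensor(np.float64("nan")) if step == 5 else total

        model, record = train_model(tiny_cases, SplitPlan(0, 0, 4, 2), TINY_MODEL,
                                    tiny_config(epochs=4), loss_transform=poison)
        assert record.diverged and record.diverged_step == 5

    def test_missing_weight_maps_preflight_error(self, tiny_cases):
        from spatreg.training import assign_split
        train, val = assign_split(tiny_cases, SplitPlan(0, 0, 4, 2), 1)
        for c in train + val:
            c.weight = None
        model = build_model(TINY_MODEL)
        with pytest.raises(ValidationError, match="weight maps"):
            fit(model, train, val, tiny_config(loss_kind="edge"))


class TestFineTune:
    def test_step0_checksum_matches_pretrained(self, tiny_cases):
        pre, _ = train_model(tiny_cases, SplitPlan(0, 0, 4, 2), TINY_MODEL,
                             tiny_config(epochs=1))
        ck = pre.checksum()
        _, _, step0 = fine_tune(pre, tiny_cases, SplitPlan(0, 0, 4, 2),
                                tiny_config(epochs=1))
        assert step0 == ck
        assert pre.checksum() == ck  # the pretrained model is not mutated

    def test_zero_epochs_identity(self, tiny_cases):
        pre, _ = train_model(tiny_cases, SplitPlan(0, 0, 4, 2), TINY_MODEL,
                             tiny_config(epochs=1))
        tuned, record, _ = fine_tune(pre, tiny_cases, SplitPlan(0, 0, 4, 2),
                                     tiny_config(epochs=0))
        assert tuned.checksum() == pre.checksum()
        assert record.selected_epoch == 0

    def test_config_mismatch_lists_fields(self, tiny_cases):
        pre = build_model(TINY_MODEL)
        other = ModelConfig((24, 24, 16), 4, 2, 8)
        with pytest.raises(ValidationError, match="initial_filters"):
            fine_tune(pre, tiny_cases, SplitPlan(0, 0, 4, 2), tiny_config(),
                      expected_config=other)


class TestReseedHarness:
    def test_divergent_seed_dropped_for_all_arms(self):
        calls = {"a": [], "b": []}

        def arm(name, bad_seeds):
            def run(seed):
                calls[name].append(seed)
                rec = TrainRecord(seed=seed, diverged=seed in bad_seeds,
                                  selected_epoch=1, best_val_dice=0.5)
                return None, rec
            return run

        results = train_arms_with_reseed(
            {"a": arm("a", {2}), "b": arm("b", set())}, seeds=[1, 2, 3])
        # seed 2 diverged in arm a: replaced by the next candidate (4) everywhere
        assert sorted(results["a"]) == [1, 3, 4]
        assert sorted(results["b"]) == [1, 3, 4]

    def test_exhausted_candidates_raise(self):
        def always_bad(seed):
            return None, TrainRecord(seed=seed, diverged=True)
        with pytest.raises(ValidationError, match="non-diverging"):
            train_arms_with_reseed({"a": always_bad}, seeds=[1], max_attempts=2)
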