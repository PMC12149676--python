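import numpy as np
import pytest

from adaptseg.train import (
    AugmentConfig,
    LeakageError,
    LossConfig,
    Sample,
    UNetSegmenter,
    assert_no_leakage,
    augment_arrays,
    build_training_samples,
    class_weights,
    dice_loss,
    focal_loss,
    make_fold_plan,
    materialize_sample,
    volume_weight_schedule,
    volume_weights,
)

IDS110 = [f"P{i:03d}" for i in range(110)]


@pytest.fixture(scope="module")
def plan110():
    return make_fold_plan(IDS110, k=5, val_fraction=18 / 110, seed=7)


class TestFoldPlan:
    def test_five_folds_of_22_patients(self, plan110):
        assert [len(f) for f in plan110.folds] == [22] * 5

    def test_70_18_22_split_per_run(self, plan110):
        for run in range(5):
            assert len(plan110.test_ids(run)) == 22
            assert len(plan110.validation_ids(run)) == 18
            assert len(plan110.train_ids(run)) == 70

    def test_folds_partition_the_cohort(self, plan110):
        seen = [p for fold in plan110.folds for p in fold]
        assert sorted(seen) == sorted(IDS110)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not set(plan110.folds[i]) & set(plan110.folds[j])

    def test_validation_disjoint_from_test(self, plan110):
        for run in range(5):
            assert not set(plan110.validation_ids(run)) & set(plan110.test_ids(run))

    def test_deterministic_given_seed(self):
        a = make_fold_plan(IDS110, 5, seed=3)
        b = make_fold_plan(IDS110, 5, seed=3)
        assert a.folds == b.folds and a.validation == b.validation

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b"], k=3)
        with pytest.raises(ValueError):
            make_fold_plan(IDS110, k=1)

    def test_uneven_cohort_sizes_differ_by_at_most_one(self):
        plan = make_fold_plan([f"q{i}" for i in range(23)], k=5, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1


class TestSampleConstruction:
    def test_reference_regime_yields_176_samples(self, plan110):
        samples = build_training_samples(IDS110, plan110, 0, "RM")
        assert len(samples) == 176
        assert all(s.kind in ("pre", "mid") for s in samples)

    def test_patient_specific_regime_count_matched_with_22_test_pre(self, plan110):
        samples = build_training_samples(IDS110, plan110, 0, "PSM")
        assert len(samples) == 176
        test = set(plan110.test_ids(0))
        test_samples = [s for s in samples if s.patient_id in test]
        assert len(test_samples) == 22
        assert all(s.kind == "pre" for s in test_samples)

    def test_adaptive_regime_doubles_by_time_reversal(self, plan110):
        samples = build_training_samples(IDS110, plan110, 0, "GAM")
        assert len(samples) == 176
        assert sum(s.kind == "forward" for s in samples) == 88
        assert sum(s.kind == "reversed" for s in samples) == 88

    def test_strict_split_uses_train_patients_only(self, plan110):
        samples = build_training_samples(IDS110, plan110, 0, "RM", strict_split=True)
        assert len(samples) == 140  # 70 train patients x 2 images
        val = set(plan110.validation_ids(0))
        assert not {s.patient_id for s in samples} & val

    def test_no_regime_sees_test_mid_treatment_data(self, plan110):
        for regime in ("RM", "PSM", "GAM"):
            for run in range(5):
                samples = build_training_samples(IDS110, plan110, run, regime)
                test = set(plan110.test_ids(run))
                assert not any(
                    s.patient_id in test and s.target_timepoint == "mid" for s in samples
                )

    def test_leakage_assertion_fires_on_bad_sample(self, plan110):
        bad = [Sample(plan110.test_ids(0)[0], "mid")]
        with pytest.raises(LeakageError):
            assert_no_leakage(bad, plan110.test_ids(0))

    def test_unknown_regime_rejected(self, plan110):
        with pytest.raises(ValueError):
            build_training_samples(IDS110, plan110, 0, "DIR")


class TestLosses:
    def test_perfect_prediction_has_near_zero_dice_loss(self):
        t = np.zeros((1, 6, 6, 6))
        t[0, 2:4, 2:4, 2:4] = 1
        assert dice_loss(t, t, [True]) < 1e-5

    def test_inverted_prediction_has_dice_loss_near_one(self):
        t = np.zeros((1, 6, 6, 6))
        t[0, 2:4, 2:4, 2:4] = 1
        assert dice_loss(1 - t, t, [True]) > 0.999

    def test_uniform_half_prediction_matches_hand_value(self):
        # 100 foreground of 1000 voxels, p = 0.5 everywhere:
        # 1 - 2*50 / (500 + 100) = 0.8333...
        t = np.zeros((1, 10, 10, 10))
        t[0, :1] = 1.0
        p = np.full((1, 10, 10, 10), 0.5)
        assert dice_loss(p, t, [True], eps=0.0) == pytest.approx(1 - 100 / 600, abs=1e-12)

    def test_absent_structures_contribute_nothing(self):
        t = np.zeros((2, 4, 4, 4))
        t[0, :2] = 1
        p = np.full((2, 4, 4, 4), 0.3)
        only_first = dice_loss(p[:1], t[:1], [True])
        both = dice_loss(p, t, [True, False])
        assert both == pytest.approx(only_first, abs=1e-12)
        _, grad = dice_loss(p, t, [True, False], with_grad=True)
        assert not grad[1].any()

    def test_focal_gamma_zero_is_binary_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, (1, 5, 5, 5))
        t = (rng.random((1, 5, 5, 5)) > 0.5).astype(float)
        bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        assert focal_loss(p, t, gamma=0.0) == pytest.approx(bce, rel=1e-9)

    def test_focal_single_voxel_hand_value(self):
        # p = 0.6, target 1, gamma 2: 0.16 * (-ln 0.6) = 0.081722...
        p = np.array([[[[0.6]]]])
        t = np.array([[[[1.0]]]])
        expected = 0.16 * -np.log(0.6)
        assert focal_loss(p, t, gamma=2.0) == pytest.approx(expected, rel=1e-9)

    def test_focal_perfect_prediction_is_near_zero(self):
        t = np.zeros((1, 4, 4, 4))
        t[0, 0] = 1
        p = np.where(t > 0.5, 1.0 - 1e-7, 1e-7)
        assert focal_loss(p, t, gamma=2.0) < 1e-10

    def test_focal_gradient_matches_finite_difference(self, rng):
        p = rng.uniform(0.2, 0.8, (1, 3, 3, 3))
        t = (rng.random((1, 3, 3, 3)) > 0.5).astype(float)
        _, g = focal_loss(p, t, gamma=2.0, with_grad=True)
        eps = 1e-7
        idx = (0, 1, 1, 1)
        pp = p.copy()
        pp[idx] += eps
        pm = p.copy()
        pm[idx] -= eps
        fd = (focal_loss(pp, t, 2.0) - focal_loss(pm, t, 2.0)) / (2 * eps)
        assert g[idx] == pytest.approx(fd, rel=1e-5)

    def test_hybrid_with_zero_focal_weight_recovers_pure_dice(self, rng):
        seg = UNetSegmenter(loss_config=LossConfig(focal_weight=0.0))
        seg._loss_cfg = seg.loss_config
        z = rng.standard_normal((2, 4, 4, 4))
        t = (rng.random((2, 4, 4, 4)) > 0.5).astype(float)
        present = np.array([True, True])
        from adaptseg.model import sigmoid

        loss, _ = seg._loss_and_grad(z, t, present, np.ones(2))
        assert loss == pytest.approx(dice_loss(sigmoid(z), t, present, np.ones(2)), rel=1e-9)


class TestWeights:
    def test_inverse_frequency_ratio(self):
        w = class_weights({"half": [True] * 44 + [False] * 44, "all": [True] * 88})
        assert w["half"] / w["all"] == pytest.approx(2.0, rel=1e-12)
        assert np.mean(list(w.values())) == pytest.approx(1.0)

    def test_all_present_gives_unit_weights(self):
        w = class_weights({"a": [True] * 10, "b": [True] * 10})
        assert w == {"a": 1.0, "b": 1.0}

    def test_never_present_structure_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no labels"):
            w = class_weights({"a": [True] * 5, "gone": [False] * 5})
        assert "gone" not in w

    def test_inverse_volume_ratio(self):
        u = volume_weights({"small": [1.0], "big": [1000.0]})
        assert u["small"] / u["big"] == pytest.approx(1000.0)

    def test_schedule_active_then_off_at_bound(self):
        u = np.array([3.0, 0.5])
        np.testing.assert_array_equal(volume_weight_schedule(0, u, 200), u)
        np.testing.assert_array_equal(volume_weight_schedule(199, u, 200), u)
        np.testing.assert_array_equal(volume_weight_schedule(200, u, 200), np.ones(2))


class TestAugmentation:
    def test_zero_ranges_are_identity(self, rng):
        img = rng.normal(size=(16, 16, 16)).astype(np.float32)
        lbl = rng.random((16, 16, 16)) > 0.8
        cfg = AugmentConfig(translation_mm=0.0, rotation_deg=0.0, scale_range=(1.0, 1.0))
        out_i, out_l = augment_arrays([img], [lbl], (2, 2, 2), cfg, rng)
        np.testing.assert_array_equal(out_i[0], img)
        np.testing.assert_array_equal(out_l[0], lbl)

    def test_fixed_seed_reproduces_transform(self):
        img = np.arange(16 ** 3, dtype=np.float32).reshape(16, 16, 16)
        cfg = AugmentConfig(translation_mm=10, rotation_deg=5, seed=4)
        a, _ = augment_arrays([img], [], (2, 2, 2), cfg, np.random.default_rng(9))
        b, _ = augment_arrays([img], [], (2, 2, 2), cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a[0], b[0])

    def test_pure_scaling_grows_mask_volume_by_cube(self, rng):
        lbl = np.zeros((32, 32, 32), bool)
        idx = np.indices((32, 32, 32)) - 15.5
        lbl[(idx ** 2).sum(axis=0) <= 8 ** 2] = True
        cfg = AugmentConfig(translation_mm=0.0, rotation_deg=0.0, scale_range=(1.2, 1.2))
        _, out = augment_arrays([], [lbl], (1, 1, 1), cfg, rng)
        ratio = out[0].sum() / lbl.sum()
        assert ratio == pytest.approx(1.2 ** 3, abs=0.08)

    def test_identical_transform_applied_to_all_channels(self, rng):
        img = rng.normal(size=(16, 16, 16)).astype(np.float32)
        lbl = np.zeros((16, 16, 16), bool)
        lbl[4:10, 4:10, 4:10] = True
        cfg = AugmentConfig(translation_mm=6.0, rotation_deg=0.0, scale_range=(1.0, 1.0), seed=2)
        out_i, out_l = augment_arrays([img, img.copy()], [lbl, lbl.copy()], (2, 2, 2), cfg, rng)
        np.testing.assert_array_equal(out_i[0], out_i[1])
        np.testing.assert_array_equal(out_l[0], out_l[1])


class TestMaterializeAndFit:
    def _toy_samples(self, rng, n=3, c=1, s=2, shape=(16, 16, 16)):
        samples = []
        for _ in range(n):
            x = rng.random((c,) + shape, dtype=np.float32)
            t = np.zeros((s,) + shape, bool)
            t[:, 4:10, 4:10, 4:10] = True
            samples.append((x, t, np.array([True] * s)))
        return samples

    def test_fit_records_history_and_finite_losses(self, rng):
        samples = self._toy_samples(rng)
        seg = UNetSegmenter(
            structure_names=["a", "b"], in_channels=1, base_width=2,
            loss_config=LossConfig(epochs=3, volume_weight_epochs=1),
            spacing=(2, 2, 2), seed=0,
        )
        seg.fit(samples, val_samples=samples[:1])
        assert len(seg.history_) == 3
        assert np.isfinite(seg.history_["loss"]).all()
        assert "val_dsc_a" in seg.history_
        assert hasattr(seg, "best_epoch_")
        traces = seg.validation_traces()
        assert set(traces) == {"a", "b"} and len(traces["a"]) == 3

    def test_absent_structure_gets_zero_gradient_through_training(self, rng):
        # one structure absent in every sample: its output weights never move
        samples = []
        for _ in range(2):
            x = rng.random((1, 16, 16, 16), dtype=np.float32)
            t = np.zeros((2, 16, 16, 16), bool)
            t[0, 4:8, 4:8, 4:8] = True
            samples.append((x, t, np.array([True, False])))
        seg = UNetSegmenter(
            structure_names=["a", "b"], in_channels=1, base_width=2,
            loss_config=LossConfig(epochs=1, volume_weight_epochs=0),
            spacing=(2, 2, 2), seed=0,
        )
        with pytest.warns(UserWarning):
            seg.fit(samples)
        w_row_b = seg.net_.out.W[1]
        fresh = UNetSegmenter(
            structure_names=["a", "b"], in_channels=1, base_width=2, seed=0
        )
        from adaptseg.model import ModelSpec, UNet3D

        ref = UNet3D(ModelSpec(1, 2, base_width=2), seed=0)
        np.testing.assert_array_equal(w_row_b, ref.out.W[1])

    def test_sklearn_params_roundtrip(self):
        seg = UNetSegmenter(base_width=4, seed=9)
        params = seg.get_params()
        clone = UNetSegmenter(**params)
        assert clone.base_width == 4 and clone.seed == 9

    def test_materialize_paired_sample_channel_order(self, desk_cohort):
        from adaptseg.experiment import align_cohort

        cases, _ = desk_cohort
        case = cases[0]
        aligned = align_cohort([case])
        aligned_tp = {
            case.patient_id: {
                "pre_in_mid": aligned[case.patient_id]["pre_in_mid"],
                "mid_in_pre": aligned[case.patient_id]["mid_in_pre"],
            }
        }
        names = case.pre.structures.names
        x, t, present = materialize_sample(
            Sample(case.patient_id, "forward"), {case.patient_id: case}, names, aligned_tp
        )
        assert x.shape[0] == 2 + len(names)
        assert t.shape[0] == len(names)
        # first channel is the (normalized) mid image
        from adaptseg.train import normalize_image

        np.testing.assert_allclose(x[0], normalize_image(case.mid.image.voxels))
        # label channels are binary
        assert set(np.unique(x[2:])) <= {0.0, 1.0}
        # target is the mid labels with its presence flags
        np.testing.assert_array_equal(present, [case.mid.structures.present[n] for n in names])

    def test_materialize_single_image_sample(self, desk_cohort):
        cases, _ = desk_cohort
        case = cases[1]
        x, t, present = materialize_sample(
            Sample(case.patient_id, "pre"), {case.patient_id: case},
            case.pre.structures.names, None,
        )
        assert x.shape[0] == 1
        assert 0.0 <= x.min() and x.max() <= 1.0
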