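import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from adaptseg.evaluate import (
    comparison_report,
    convergence_audit,
    corrected_resampled_ttest,
    dsc,
    evaluate_predictions,
    msd,
)
from adaptseg.train import FoldPlan
from tests.conftest import random_blob


def brute_force_dsc(a, b):
    """Independent oracle: exhaustive voxel counting over explicit coordinate sets."""
    sa = {tuple(v) for v in np.argwhere(a)}
    sb = {tuple(v) for v in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def brute_force_msd(a, b, spacing):
    """Independent oracle: all-pairs distances between face-connected boundaries."""
    from scipy.ndimage import binary_erosion, generate_binary_structure

    def boundary(m):
        return m & ~binary_erosion(m, generate_binary_structure(3, 1), border_value=0)

    pa = np.argwhere(boundary(a)) * spacing
    pb = np.argwhere(boundary(b)) * spacing
    d = cdist(pa, pb)
    return (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2


class TestDSC:
    def test_identical_nonempty_masks_score_one(self, rng):
        m = random_blob(rng)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[7, 7, 7] = True
        assert dsc(a, b) == 0.0

    def test_half_overlap_hand_value(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dsc(a, b) == pytest.approx(0.5, abs=1e-15)

    def test_both_empty_scores_one(self):
        z = np.zeros((4, 4, 4), bool)
        assert dsc(z, z) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 5), bool))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            a = random_blob(rng)
            b = random_blob(rng)
            assert dsc(a, b) == pytest.approx(brute_force_dsc(a, b), abs=1e-12)


class TestMSD:
    def test_identical_masks_have_zero_distance(self, rng):
        m = random_blob(rng)
        assert msd(m, m, (1, 1, 1)) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert msd(a, b, (1, 1, 1)) == pytest.approx(3.0, abs=1e-12)

    def test_distance_scales_with_spacing(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert msd(a, b, (2.5, 1, 1)) == pytest.approx(7.5, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = random_blob(rng)
        b = random_blob(rng)
        assert msd(a, b, (1, 2, 3)) == pytest.approx(msd(b, a, (1, 2, 3)), abs=1e-12)

    def test_empty_mask_is_undefined(self):
        m = np.zeros((4, 4, 4), bool)
        n = m.copy()
        n[1, 1, 1] = True
        with pytest.raises(ValueError):
            msd(m, n, (1, 1, 1))

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            a = random_blob(rng)
            b = random_blob(rng)
            assert msd(a, b, (1.5, 1.0, 2.0)) == pytest.approx(
                brute_force_msd(a, b, (1.5, 1.0, 2.0)), abs=1e-9
            )


class TestEvaluatePredictions:
    def _refs(self, rng, pids=("P0", "P1")):
        from adaptseg.imaging import ImageVolume, StructureSet, Timepoint

        refs = {}
        for pid in pids:
            img = ImageVolume(rng.normal(size=(16, 16, 16)).astype(np.float32), (2, 2, 2), (0, 0, 0))
            ss = StructureSet.empty_like(img, ["a", "b"])
            ss.masks["a"] = random_blob(rng, (16, 16, 16), (3, 6))
            ss.present["a"] = True
            refs[pid] = Timepoint(img, ss)
        return refs

    def test_identical_prediction_scores_dsc_one(self, rng):
        refs = self._refs(rng)
        preds = {pid: tp.structures for pid, tp in refs.items()}
        table = evaluate_predictions(preds, refs, "RIR")
        assert (table["dsc"] == 1.0).all()
        assert (table["method"] == "RIR").all()

    def test_empty_prediction_scores_zero_with_undefined_msd(self, rng):
        from adaptseg.imaging import StructureSet

        refs = self._refs(rng, pids=("P0",))
        empty = StructureSet(
            (16, 16, 16), (2, 2, 2), (0, 0, 0),
            {"a": np.zeros((16, 16, 16), bool), "b": np.zeros((16, 16, 16), bool)},
            {"a": True, "b": True},
        )
        table = evaluate_predictions({"P0": empty}, refs, "RM")
        row = table.iloc[0]
        assert row["dsc"] == 0.0
        assert not row["msd_defined"] and np.isnan(row["msd"])

    def test_row_count_equals_present_reference_structures(self, rng):
        refs = self._refs(rng)
        preds = {pid: tp.structures for pid, tp in refs.items()}
        table = evaluate_predictions(preds, refs, "X")
        # only structure "a" is present per reference
        assert len(table) == len(refs)

    def test_prediction_resampled_to_reference_grid(self, rng):
        from adaptseg.imaging import StructureSet, resample

        refs = self._refs(rng, pids=("P0",))
        ref_ss = refs["P0"].structures
        fine = resample(ref_ss, (1, 1, 1))
        table = evaluate_predictions({"P0": fine}, refs, "R")
        assert table.iloc[0]["dsc"] >= 0.9  # integer-ratio resample round trip

    def test_missing_channel_raises(self, rng):
        from adaptseg.imaging import StructureSet

        refs = self._refs(rng, pids=("P0",))
        bad = StructureSet((16, 16, 16), (2, 2, 2), (0, 0, 0),
                           {"b": np.zeros((16, 16, 16), bool)}, {"b": True})
        with pytest.raises(KeyError):
            evaluate_predictions({"P0": bad}, refs, "R")


class TestConvergenceAudit:
    def test_flags_follow_threshold_semantics(self):
        traces = {
            "run0": {
                "flat": [0.0, 0.0, 0.0],
                "good": [0.0, 0.3, 0.5],
                "boundary": [0.005, 0.002, 0.0],
            }
        }
        audit = convergence_audit(traces, tau=0.01).set_index("structure")
        assert not audit.loc["flat", "converged"]
        assert audit.loc["good", "converged"]
        assert not audit.loc["boundary", "converged"]  # max 0.005 <= tau


class TestCorrectedTTest:
    def test_identical_scores_give_p_one(self):
        res = corrected_resampled_ttest([0.5] * 5, [0.5] * 5, 88, 22)
        assert res.degenerate and res.t == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        # d = (0.20, 0.10, 0.15, 0.05, 0.10), k=5, n2/n1 = 22/88:
        # c = 1/5 + 0.25 = 0.45; mean d = 0.12; var d = 0.00325
        # t = 0.12 / sqrt(0.45 * 0.00325) = 3.1378
        a = np.array([0.20, 0.10, 0.15, 0.05, 0.10])
        res = corrected_resampled_ttest(a, np.zeros(5), 88, 22)
        assert res.correction == pytest.approx(0.45, abs=1e-12)
        assert res.t == pytest.approx(3.1378, abs=2e-4)
        assert res.df == 4
        assert res.p == pytest.approx(2 * stats.t.sf(3.1378, 4), abs=1e-4)

    def test_vanishing_test_fraction_recovers_naive_paired_ttest(self, rng):
        a = rng.normal(0.7, 0.05, 6)
        b = rng.normal(0.6, 0.05, 6)
        res = corrected_resampled_ttest(a, b, n_train=10 ** 9, n_test=1)
        naive = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(naive.statistic, rel=1e-6)
        assert res.p == pytest.approx(naive.pvalue, rel=1e-6)

    def test_correction_is_anticonservative_guard(self, rng):
        # same data: corrected |t| is strictly smaller than naive |t|
        a = rng.normal(0.7, 0.05, 5)
        b = rng.normal(0.6, 0.05, 5)
        res = corrected_resampled_ttest(a, b, 88, 22)
        naive = stats.ttest_rel(a, b)
        assert abs(res.t) < abs(naive.statistic)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            corrected_resampled_ttest([1.0], [0.5], 88, 22)


class TestComparisonReport:
    def _plan(self, pids, k=2):
        folds = [sorted(pids[j::k]) for j in range(k)]
        return FoldPlan(k, folds, [[] for _ in range(k)], seed=0)

    def _records(self, pids, offsets, rng, sd=0.01):
        rows = []
        for method, off in offsets.items():
            for pid in pids:
                rows.append(
                    {
                        "patient_id": pid,
                        "structure": "organ",
                        "method": method,
                        "dsc": 0.6 + off + rng.normal(0, sd),
                        "msd": 1.0,
                        "msd_defined": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_methods_get_no_markers(self, rng):
        pids = [f"P{i}" for i in range(12)]
        df = self._records(pids, {"A": 0.0}, rng)
        df2 = df.copy()
        df2["method"] = "B"
        records = pd.concat([df, df2])
        rep = comparison_report(records, self._plan(pids), methods=["A", "B"], baseline="A")
        assert (rep["B_vs_A"] == "").all()

    def test_clear_improvement_is_marked_significant(self, rng):
        pids = [f"P{i}" for i in range(12)]
        plan = self._plan(pids, k=4)
        records = self._records(pids, {"A": 0.2, "B": 0.0}, rng, sd=0.005)
        rep = comparison_report(records, plan, methods=["A", "B"], baseline="B")
        assert rep.iloc[0]["A_vs_B"] == "*"
        assert rep.iloc[0]["A_mean"] > rep.iloc[0]["B_mean"]

    def test_marker_invariant_to_patient_order(self, rng):
        pids = [f"P{i}" for i in range(12)]
        plan = self._plan(pids, k=4)
        records = self._records(pids, {"A": 0.1, "B": 0.0}, rng, sd=0.01)
        rep1 = comparison_report(records, plan, methods=["A", "B"], baseline="B")
        shuffled = records.sample(frac=1.0, random_state=5)
        rep2 = comparison_report(shuffled, plan, methods=["A", "B"], baseline="B")
        assert rep1.iloc[0]["A_vs_B"] == rep2.iloc[0]["A_vs_B"]

    def test_single_fold_structure_reports_mean_without_sd(self, rng):
        pids = [f"P{i}" for i in range(4)]
        plan = self._plan(pids, k=2)
        records = self._records(pids, {"A": 0.0}, rng)
        # structure scored only in fold 0
        fold0 = set(plan.folds[0])
        records = records[records["patient_id"].isin(fold0)]
        rep = comparison_report(records, plan, methods=["A"])
        assert np.isfinite(rep.iloc[0]["A_mean"])
        assert np.isnan(rep.iloc[0]["A_sd"])

    def test_absent_method_rejected(self, rng):
        pids = [f"P{i}" for i in range(4)]
        records = self._records(pids, {"A": 0.0}, rng)
        with pytest.raises(ValueError):
            comparison_report(records, self._plan(pids), methods=["A", "Z"])
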