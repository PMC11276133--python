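"""Evaluation protocol: CNR, grading, metrics, ICC, folds, CV bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvscade import evaluate, models, phantom
from pvscade.evaluate import grade_from_count, icc, make_folds, subject_grade


class TestComputeCNR:
    @staticmethod
    def _grids():
        image = np.zeros((10, 10))
        signal = np.zeros((10, 10), bool)
        surround = np.zeros((10, 10), bool)
        background = np.zeros((10, 10), bool)
        signal[2:4, 2:4] = True
        surround[6:8, 2:4] = True
        background[2:8, 6:9] = True
        image[signal] = 0.8
        image[surround] = 0.3
        # background alternating around 0.5 with exact std 0.01
        vals = np.tile([0.51, 0.49], background.sum() // 2)
        image[background] = vals
        return image, signal, surround, background

    def test_hand_constructed_cnr_is_fifty(self):
        image, s, r, b = self._grids()
        res = evaluate.compute_cnr(image, s, r, b)
        assert res.mu_signal1 == pytest.approx(0.8)
        assert res.mu_signal2 == pytest.approx(0.3)
        assert res.sigma_noise == pytest.approx(0.01)
        assert res.cnr == pytest.approx(50.0, abs=1e-9)

    def test_identical_regions_give_zero(self):
        image, s, r, b = self._grids()
        image[s] = 0.3
        assert evaluate.compute_cnr(image, s, r, b).cnr == 0.0

    def test_swapping_signal_and_surround_is_symmetric(self):
        image, s, r, b = self._grids()
        assert evaluate.compute_cnr(image, s, r, b).cnr == pytest.approx(
            evaluate.compute_cnr(image, r, s, b).cnr
        )

    def test_zero_background_variance_rejected(self):
        image, s, r, b = self._grids()
        image[b] = 0.5
        with pytest.raises(ValueError, match="zero variance"):
            evaluate.compute_cnr(image, s, r, b)

    def test_empty_or_overlapping_masks_rejected(self):
        image, s, r, b = self._grids()
        with pytest.raises(ValueError, match="empty"):
            evaluate.compute_cnr(image, np.zeros_like(s), r, b)
        with pytest.raises(ValueError, match="overlap"):
            evaluate.compute_cnr(image, s, s, b)

    def test_affine_rescaling_invariance(self, desk_params, rng):
        raw, mask = phantom.render_part(10, desk_params, rng)
        image = raw.astype(float)
        a = evaluate.part_cnr(image, mask, border=6)
        b = evaluate.part_cnr(3.7 * image + 11.0, mask, border=6)
        assert a.cnr == pytest.approx(b.cnr, rel=1e-9)

    def test_region_geometry_disjoint(self, desk_params, rng):
        _, mask = phantom.render_part(15, desk_params, rng)
        signal, surround, background = evaluate.cnr_regions_from_mask(mask, border=6)
        assert not (signal & surround).any()
        assert not (signal & background).any()
        assert not (surround & background).any()


class TestGrading:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, 0), (1, 1), (10, 1), (11, 2), (20, 2), (21, 3), (40, 3), (41, 4), (48, 4), (200, 4)],
    )
    def test_potter_brackets(self, count, expected):
        assert grade_from_count(count) == expected

    def test_half_up_rounding_of_real_predictions(self):
        assert grade_from_count(10.4) == 1
        assert grade_from_count(10.5) == 2
        assert grade_from_count(0.49) == 0
        assert grade_from_count(0.5) == 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            grade_from_count(-0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.floats(0, 300), b=st.floats(0, 300))
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert grade_from_count(lo) <= grade_from_count(hi)

    def test_subject_grade_examples(self):
        assert subject_grade((1, 2, 2, 3, 1, 0)) == 3
        assert subject_grade((0, 0, 0, 0, 0, 0)) == 0

    def test_subject_grade_permutation_invariant(self):
        grades = (0, 1, 2, 2, 3, 4)
        results = {subject_grade(p) for p in itertools.permutations(grades)}
        assert results == {4}

    def test_subject_grade_cardinality(self):
        with pytest.raises(ValueError):
            subject_grade((1, 2, 3))


class TestErrorMetrics:
    def test_exact_agreement_is_zero(self):
        assert evaluate.mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert evaluate.mse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_extreme_disagreement_hand_values(self):
        assert evaluate.mae([0, 48], [48, 0]) == 48.0
        assert evaluate.mse([0, 48], [48, 0]) == 2304.0

    def test_against_loop_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            t = rng.uniform(0, 48, n)
            p = rng.uniform(0, 48, n)
            mae_oracle = sum(abs(a - b) for a, b in zip(t, p)) / n
            mse_oracle = sum((a - b) ** 2 for a, b in zip(t, p)) / n
            assert abs(evaluate.mae(t, p) - mae_oracle) < 1e-12
            assert abs(evaluate.mse(t, p) - mse_oracle) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate.mae([1, 2], [1])

    def test_grade_accuracy(self):
        assert evaluate.grade_accuracy([1, 2, 3], [1, 2, 3]) == 100.0
        assert evaluate.grade_accuracy([1, 2, 3], [2, 3, 4]) == 0.0
        truth = [1] * 25
        pred = [1] * 22 + [2] * 3
        assert evaluate.grade_accuracy(truth, pred) == pytest.approx(88.0)


class TestICC:
    def test_perfect_agreement_is_one(self):
        t = np.array([0.0, 1, 2, 3, 4, 2])
        est, lo, hi = icc(t, t.copy())
        assert est == pytest.approx(1.0)
        assert lo <= est <= hi

    def test_constant_offset_agreement_below_consistency(self):
        t = np.array([0.0, 1, 2, 3, 4, 2, 1, 3])
        p = t + 1.0
        agreement = icc(t, p)[0]
        consistency = icc(t, p, form="consistency")[0]
        assert agreement < consistency
        assert consistency == pytest.approx(1.0)

    def test_six_pair_hand_anova(self):
        t = np.array([1.0, 2, 3, 4, 2, 0])
        p = np.array([2.0, 2, 4, 3, 3, 1])
        data = np.column_stack([t, p])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mserr = ((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mserr) / (msr + (k - 1) * mserr + k * (msc - mserr) / n)
        assert icc(t, p)[0] == pytest.approx(expected, abs=1e-6)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        t = rng.integers(0, 5, 15).astype(float)
        p = np.clip(t + rng.normal(0, 1, 15).round(), 0, 4)
        est, lo, hi = icc(t, p)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(15), 2),
                "raters": np.repeat(["truth", "pred"], 15),
                "scores": np.concatenate([t, p]),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert est == pytest.approx(row.ICC, abs=1e-9)
        assert lo == pytest.approx(row.CI95[0], abs=0.01)
        assert hi == pytest.approx(row.CI95[1], abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc([1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            icc([1, 2], [1, 2])

    def test_estimate_bounded(self, rng):
        for _ in range(20):
            t = rng.uniform(0, 4, 10)
            p = rng.uniform(0, 4, 10)
            est, lo, hi = icc(t, p)
            assert -1.0 <= est <= 1.0
            assert lo <= est <= hi


class TestFolds:
    def test_seventy_six_subjects_give_nineteen_per_fold(self):
        plan = make_folds([f"S{i}" for i in range(76)], k=4, seed=0)
        sizes = sorted(len(plan.test_subjects(f)) for f in range(4))
        assert sizes == [19, 19, 19, 19]

    def test_remainder_balanced(self):
        plan = make_folds(list("ABCDEFG"), k=4, seed=1)
        sizes = sorted(len(plan.test_subjects(f)) for f in range(4))
        assert sizes == [1, 2, 2, 2]

    def test_exhaustive_partition(self):
        ids = [f"S{i}" for i in range(23)]
        plan = make_folds(ids, k=4, seed=3)
        seen = [s for f in range(4) for s in plan.test_subjects(f)]
        assert sorted(seen) == sorted(ids)
        for f in range(4):
            assert set(plan.test_subjects(f)).isdisjoint(plan.train_subjects(f))
            assert sorted(plan.test_subjects(f) + plan.train_subjects(f)) == sorted(ids)

    def test_seeded_and_validated(self):
        ids = [f"S{i}" for i in range(12)]
        assert make_folds(ids, seed=5).assignments == make_folds(ids, seed=5).assignments
        assert make_folds(ids, seed=5).assignments != make_folds(ids, seed=6).assignments
        with pytest.raises(ValueError):
            make_folds(ids, k=1)
        with pytest.raises(ValueError):
            make_folds(["A", "A", "B", "C"], k=2)


@pytest.fixture(scope="module")
def cv_report(small_cohort_module):
    cfg = models.preset("mini", epochs_enhancer=2, epochs_quantifier=3)
    return evaluate.run_cross_validation(
        small_cohort_module, method="none", train_config=cfg, seed=5, out_shape=(40, 48), cnr_border=6
    )


@pytest.fixture(scope="module")
def small_cohort_module():
    return phantom.generate_cohort(8, phantom.desk_params(), seed=101)


class TestCrossValidation:
    def test_bookkeeping_eight_subjects(self, cv_report):
        assert cv_report.n_images == 48
        assert cv_report.n_subjects == 8
        assert len(cv_report.per_fold_mae) == 4
        assert sorted(cv_report.predictions.fold.unique()) == [0, 1, 2, 3]

    def test_no_subject_leaks_across_folds(self, cv_report):
        by_subject = cv_report.predictions.groupby("subject_id").fold.nunique()
        assert (by_subject == 1).all()
        plan = make_folds(sorted(cv_report.predictions.subject_id.unique()), k=4, seed=5)
        for sid, fold in cv_report.predictions.groupby("subject_id").fold.first().items():
            assert plan.assignments[sid] == fold

    def test_subject_accuracy_matches_brute_force(self, cv_report):
        df = cv_report.predictions
        hits = 0
        subjects = df.subject_id.unique()
        for sid in subjects:
            sub = df[df.subject_id == sid]
            assert len(sub) == 6
            if subject_grade(sub.truth_grade.tolist()) == subject_grade(sub.pred_grade.tolist()):
                hits += 1
        assert cv_report.image_accuracy == pytest.approx(
            100.0 * (df.truth_grade == df.pred_grade).mean()
        )
        assert cv_report.subject_accuracy == pytest.approx(100.0 * hits / len(subjects))

    def test_same_seed_reproduces_report(self, small_cohort_module, cv_report):
        cfg = models.preset("mini", epochs_enhancer=2, epochs_quantifier=3)
        again = evaluate.run_cross_validation(
            small_cohort_module, method="none", train_config=cfg, seed=5, out_shape=(40, 48), cnr_border=6
        )
        assert again.to_json() == cv_report.to_json()
        pd.testing.assert_frame_equal(again.predictions, cv_report.predictions)

    def test_unknown_method_rejected(self, small_cohort_module):
        with pytest.raises(ValueError):
            evaluate.run_cross_validation(small_cohort_module, method="sharpen")
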