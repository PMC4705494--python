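import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvbp import (exhaustive_search, fp_fn_rates, loso_cv, n_subsets,
                   percent_correct, residual_histogram, sigma_est)


def make_dataset(n_subjects=8, n_reps=4, coeffs=None, eps_sd=0.5, seed=0,
                 features=("MeanRR", "STDNN", "RMSSD", "HF", "LF", "RPDET")):
    """Synthetic predictive table with independent pseudo-features; the
    outcome is linear in ``coeffs`` (feature-name -> weight)."""
    rng = np.random.default_rng(seed)
    coeffs = coeffs or {}
    rows = []
    for sub in range(1, n_subjects + 1):
        centers = {f: rng.uniform(-10, 10) for f in features}
        for rep in range(1, n_reps + 1):
            vals = {f: centers[f] + rng.standard_normal() for f in features}
            y = -5.0 + sum(coeffs.get(f, 0.0) * v for f, v in vals.items())
            rows.append({"sub_id": sub, "test_id": rep, "symptom_id": 0,
                         "delta_sys": y + eps_sd * rng.standard_normal(),
                         "delta_dia": 0.0, **vals})
    return pd.DataFrame(rows)


class TestSigmaEst:
    def test_zero_for_perfect_prediction(self):
        assert sigma_est([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        assert sigma_est([10, 12, 8], [11, 11, 9]) == pytest.approx(
            np.sqrt(3.0))

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=20),
           st.floats(0.1, 4.0))
    def test_homogeneity(self, resid, c):
        y = np.zeros(len(resid))
        r = np.asarray(resid)
        assert sigma_est(y, c * r) == pytest.approx(c * sigma_est(y, r),
                                                    rel=1e-9, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sigma_est([1, 2], [1, 2])


class TestMetrics:
    def test_percent_correct_hand_case(self):
        y = np.zeros(4)
        yp = np.array([0.0, 4.0, 5.0, 10.0])
        assert percent_correct(y, yp, 4.5) == 50.0

    def test_percent_correct_boundary_strict(self):
        assert percent_correct([0.0], [4.5], 4.5) == 0.0
        assert percent_correct([1.0, 2.0], [1.0, 2.0], 4.5) == 100.0
        assert percent_correct([1.0], [3.0], 0.0) == 0.0

    def test_fp_fn_definitions(self):
        # underestimated drop (predicted below measured - 5) -> FN
        fn, fp = fp_fn_rates([-5.0], [-12.0])
        assert (fn, fp) == (100.0, 0.0)
        # overestimated (predicted above measured + 5) -> FP
        fn, fp = fp_fn_rates([-10.0], [-2.0])
        assert (fn, fp) == (0.0, 100.0)
        fn, fp = fp_fn_rates([3.0, -4.0], [3.0, -4.0])
        assert (fn, fp) == (0.0, 0.0)

    def test_rates_partition_instances(self, rng):
        y = rng.uniform(-20, 10, 80)
        yp = y + rng.uniform(-8, 8, 80)
        margin = threshold = 5.0
        fn, fp = fp_fn_rates(y, yp, margin)
        pc = percent_correct(y, yp, threshold)
        on_boundary = 100.0 * np.mean(np.abs(y - yp) == threshold)
        assert pc + fn + fp + on_boundary == pytest.approx(100.0)

    def test_residual_histogram_cases(self, rng):
        h = residual_histogram(np.zeros(10))
        assert h.loc[h.bin_center == 0, "percent"].iloc[0] == 100.0
        h = residual_histogram(np.array([-3.0, 0.0, 0.0, 3.0]))
        assert h.loc[h.bin_center == 0, "percent"].iloc[0] == 50.0
        h = residual_histogram(rng.standard_normal(333) * 4)
        assert h["percent"].sum() == pytest.approx(100.0)


class TestLoso:
    def test_fold_structure(self):
        df = make_dataset(10, 4, {"RMSSD": 1.0}, eps_sd=0.1)
        seen = []
        score, preds, _ = loso_cv(df, ["RMSSD"], return_details=True)
        assert np.isfinite(preds).all()
        assert df["sub_id"].nunique() == 10
        assert score > 0

    def test_duplicate_subjects_noiseless_score_zero(self):
        df = make_dataset(2, 4, {"RMSSD": 2.0}, eps_sd=0.0, seed=3)
        df2 = pd.concat([df, df.assign(sub_id=df.sub_id + 2),
                         df.assign(sub_id=df.sub_id + 4)],
                        ignore_index=True)
        assert loso_cv(df2, ["RMSSD"]) == pytest.approx(0.0, abs=1e-8)

    def test_subject_order_invariance(self):
        df = make_dataset(6, 3, {"HF": -0.8}, eps_sd=0.4, seed=4)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert loso_cv(df, ["HF"]) == pytest.approx(
            loso_cv(shuffled, ["HF"]), abs=1e-12)

    def test_pooled_mode_differs_from_per_fold(self):
        # 3 instances per fold: the per-fold estimate divides by N-2 = 1
        # and so sits above the pooled estimate (denominator N_total - 2)
        df = make_dataset(6, 3, {"HF": -0.8}, eps_sd=0.4, seed=5)
        a = loso_cv(df, ["HF"], cv_mode="per_fold")
        b = loso_cv(df, ["HF"], cv_mode="pooled")
        assert 0 < b < a

    def test_too_few_subjects_rejected(self):
        df = make_dataset(2, 4, {"RMSSD": 1.0})
        with pytest.raises(ValueError, match="3 subjects"):
            loso_cv(df, ["RMSSD"])


class TestExhaustiveSearch:
    def test_subset_count_formula(self):
        assert n_subsets(22, 5) == 35442
        assert n_subsets(10, 5) == 637
        assert n_subsets(6, 2) == 21

    def test_matches_brute_force_enumeration(self):
        """Same winner and score as an independent re-enumeration on a
        6-feature, max_k=2 problem (21 subsets)."""
        feats = ["MeanRR", "STDNN", "RMSSD", "HF", "LF", "RPDET"]
        df = make_dataset(6, 3, {"RMSSD": 1.5, "HF": -1.0}, eps_sd=0.3,
                          seed=6, features=tuple(feats))
        res = exhaustive_search(df, max_k=2, candidate_features=feats)
        assert res.n_subsets_evaluated == 21
        scored = []
        for k in (1, 2):
            for comb in itertools.combinations(sorted(feats), k):
                scored.append((loso_cv(df, list(comb)), len(comb), comb))
        want = min(scored)
        assert res.best_subset == want[2]
        assert res.best_score == pytest.approx(want[0], abs=1e-12)

    def test_single_feature_planted_truth(self):
        df = make_dataset(8, 4, {"MeanRR": 1.2}, eps_sd=0.3, seed=7)
        res = exhaustive_search(df, max_k=1)
        assert res.best_subset == ("MeanRR",)

    def test_failed_subsets_scored_infinite(self):
        df = make_dataset(6, 3, {"RMSSD": 1.0}, eps_sd=0.2, seed=8)
        df["DEAD"] = np.nan
        res = exhaustive_search(
            df, max_k=1, candidate_features=["RMSSD", "DEAD"])
        assert res.best_subset == ("RMSSD",)

    def test_report_is_internally_consistent(self):
        df = make_dataset(8, 4, {"RMSSD": 1.0, "HF": -0.5}, eps_sd=0.5,
                          seed=9)
        res = exhaustive_search(df, max_k=2)
        rep = res.report
        np.testing.assert_allclose(rep.residuals,
                                   rep.measured - rep.predicted)
        assert rep.sigma_est_test == pytest.approx(res.best_score)
        assert 0 <= rep.percent_correct <= 100
        assert rep.sigma_est_full <= rep.sigma_est_test * 1.5
        assert len(rep.predictions_frame()) == len(df)
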