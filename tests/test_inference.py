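import numpy as np
import pandas as pd
import pytest
from scipy import stats

from attnet.inference import (
    CohortDesign,
    ancova_metric,
    clinical_regression,
    compare_global_curves,
    demographics_table,
    fdr_correct,
    significant_ranges,
)


def make_design(n_per_group=20, seed=0, age_shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, label in enumerate(["control", "patient"]):
        for k in range(n_per_group):
            rows.append(
                dict(
                    subject_id=f"s{g}{k:02d}",
                    group=label,
                    age=rng.normal(12 + g * age_shift, 2),
                    sex="M" if rng.random() < 0.5 else "F",
                    iq=rng.normal(110, 15),
                    dsm_inattentive=rng.normal(60, 10),
                    dsm_hyperactive=rng.normal(58, 9),
                    dsm_total=rng.normal(59, 9),
                )
            )
    return CohortDesign(pd.DataFrame(rows))


class TestAncova:
    def test_group_indicator_metric_gives_tiny_p(self):
        design = make_design(seed=1)
        values = (design.table["group"] == "patient").astype(float).to_numpy()
        f, _, p = ancova_metric(values, design)
        assert p < 1e-12

    def test_matches_residual_sum_of_squares_oracle(self):
        design = make_design(n_per_group=12, seed=2)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(design.n_subjects)
        f, (d1, d2), p = ancova_metric(y, design)

        # oracle: explicit RSS comparison of nested least-squares fits
        tab = design.table
        x_red = np.column_stack(
            [
                np.ones(len(tab)),
                tab["age"],
                tab["iq"],
                (tab["sex"] == "M").astype(float),
            ]
        )
        x_full = np.column_stack([x_red, (tab["group"] == "patient").astype(float)])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        f_expected = (rss(x_red) - rss(x_full)) / (rss(x_full) / (len(tab) - x_full.shape[1]))
        assert f == pytest.approx(f_expected, abs=1e-8)
        assert (d1, d2) == (1, len(tab) - x_full.shape[1])
        assert p == pytest.approx(stats.f.sf(f_expected, d1, d2), abs=1e-10)

    def test_null_rejection_rate_near_nominal(self):
        design = make_design(seed=4)
        rng = np.random.default_rng(5)
        hits = sum(
            ancova_metric(rng.standard_normal(design.n_subjects), design)[2] < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_zero_variance_covariates_reduce_to_two_sample_test(self):
        design = make_design(n_per_group=15, seed=6)
        tab = design.table.copy()
        tab["age"] = 12.0
        tab["iq"] = 100.0
        tab["sex"] = "M"
        rng = np.random.default_rng(7)
        y = rng.standard_normal(len(tab)) + 0.8 * (tab["group"] == "patient")
        with pytest.raises(ValueError, match="collinear"):
            # constant age/iq columns are collinear with the intercept: named
            ancova_metric(y.to_numpy(), CohortDesign(tab))
        # dropping them reduces the partial F to the two-sample pooled t^2
        f, _, p = ancova_metric(y.to_numpy(), CohortDesign(tab), covariates=())
        t, p_t = stats.ttest_ind(
            y[tab["group"] == "control"], y[tab["group"] == "patient"]
        )
        assert f == pytest.approx(t**2, abs=1e-8)
        assert p == pytest.approx(p_t, abs=1e-10)

    def test_subject_order_invariance(self):
        design = make_design(n_per_group=10, seed=8)
        rng = np.random.default_rng(9)
        y = rng.standard_normal(design.n_subjects)
        perm = rng.permutation(design.n_subjects)
        shuffled = CohortDesign(design.table.iloc[perm].reset_index(drop=True))
        f1, _, _ = ancova_metric(y, design)
        f2, _, _ = ancova_metric(y[perm], shuffled)
        assert f1 == pytest.approx(f2, abs=1e-9)


class TestFdr:
    def test_step_up_rule_by_hand(self):
        reject, _ = fdr_correct(np.array([0.001, 0.02, 0.03, 0.5]), alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])

    def test_all_ones_no_rejections(self):
        reject, _ = fdr_correct(np.ones(6))
        assert not reject.any()

    def test_single_p_reduces_to_raw_comparison(self):
        reject, _ = fdr_correct(np.array([0.04]), alpha=0.05)
        assert reject[0]

    def test_rejections_are_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 40)
        reject, _ = fdr_correct(p)
        if reject.any():
            assert reject[p <= p[reject].max()].all()


class TestClinicalRegression:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        score = rng.normal(70, 10, 20)
        eff = np.column_stack([2.0 * score, rng.standard_normal(20)])
        out = clinical_regression(eff, pd.DataFrame({"dsm_inattentive": score}))
        row = out[out["node"] == "0"].iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["p"] < 1e-12

    def test_negative_relation_gives_negative_slope(self):
        rng = np.random.default_rng(1)
        score = rng.normal(70, 10, 25)
        eff = (-0.0007 * score + rng.normal(0, 0.001, 25))[:, None]
        out = clinical_regression(eff, pd.DataFrame({"dsm_inattentive": score}))
        assert out.iloc[0]["slope"] < 0

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(2)
        hits, sims = 0, 1000
        for _ in range(sims):
            eff = rng.standard_normal((22, 1))
            score = rng.normal(70, 10, 22)
            out = clinical_regression(eff, pd.DataFrame({"s": score}))
            hits += out.iloc[0]["p"] < 0.05
        assert 0.03 <= hits / sims <= 0.07

    def test_zero_score_variance_flagged(self):
        eff = np.random.default_rng(3).standard_normal((10, 2))
        out = clinical_regression(eff, pd.DataFrame({"s": np.full(10, 70.0)}))
        assert out["undefined"].all()


class TestGlobalCurves:
    def test_planted_group_difference_detected_in_range(self):
        design = make_design(n_per_group=20, seed=10)
        costs = np.round(np.arange(0.1, 0.51, 0.05), 2)
        rng = np.random.default_rng(12)
        curves = rng.normal(0.5, 0.02, size=(design.n_subjects, costs.size))
        patient = design.group_mask("patient")
        curves[np.ix_(patient, np.arange(3, 6))] -= 0.05  # depressed mid-range
        out = compare_global_curves(curves, costs, design)
        flagged = set(out.loc[out["fdr_reject"], "cost"])
        assert {costs[3], costs[4], costs[5]} <= flagged  # planted range detected
        assert len(flagged - {costs[3], costs[4], costs[5]}) <= 1  # few spillovers
        ranges = significant_ranges(out)
        assert any(lo <= costs[3] and hi >= costs[5] for lo, hi in ranges)

    def test_null_curves_rarely_significant(self):
        design = make_design(n_per_group=15, seed=12)
        costs = np.round(np.arange(0.1, 0.31, 0.05), 2)
        rng = np.random.default_rng(13)
        curves = rng.normal(0.5, 0.02, size=(design.n_subjects, costs.size))
        out = compare_global_curves(curves, costs, design)
        assert out["fdr_reject"].sum() <= 1

    def test_grid_mismatch_rejected(self):
        design = make_design(n_per_group=5, seed=14)
        with pytest.raises(ValueError, match="costs"):
            compare_global_curves(np.zeros((10, 4)), np.zeros(5), design)


class TestDesignValidation:
    def test_unknown_group_label_names_row(self):
        tab = make_design(n_per_group=3).table
        tab.loc[2, "group"] = "sibling"
        with pytest.raises(ValueError, match="sibling"):
            CohortDesign(tab)

    def test_duplicate_subjects_rejected(self):
        tab = make_design(n_per_group=3).table
        tab.loc[1, "subject_id"] = tab.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="duplicate"):
            CohortDesign(tab)

    def test_demographics_table_runs_all_measures(self):
        tab = demographics_table(make_design(n_per_group=15, seed=15))
        assert set(tab["test"]) == {"chi2", "t"}
        assert "age" in set(tab["measure"])
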