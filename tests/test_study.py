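import dataclasses

import numpy as np
import pandas as pd
import pytest

from cvrkit import (
    CohortConfig,
    CVRSpec,
    GAConfig,
    column_ratio,
    default_region_params,
    generate_cohort,
    normalize_scores,
    run_study,
    sensitivity_trim,
    stratified_split,
)
from cvrkit.study import METRICS, evaluate_biomarker

TINY_GA = GAConfig(population_size=8, elitism=2, max_generations=3,
                   patience=3, n_restarts=1)


def uniform_covariate_table(n_subjects):
    """Table whose subjects all fall into a single stratum."""
    rows = []
    for i in range(n_subjects):
        for t in (0.0, 1.0):
            rows.append({
                "subject_id": f"s{i}", "visit_time": t, "age_bl": 70.0,
                "sex": 1, "DX": 1, "AB": 1, "APOE4": 0, "education": 16,
                "value": 1.0,
            })
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_even_stratum_splits_in_half(self):
        res = stratified_split(uniform_covariate_table(4), seed=0)
        counts = res.assignments.value_counts()
        assert counts[1] == 2 and counts[2] == 2

    def test_same_seed_reproduces_assignment(self, planted_table):
        a = stratified_split(planted_table, seed=3).assignments
        b = stratified_split(planted_table, seed=3).assignments
        pd.testing.assert_series_equal(a, b)

    def test_stratum_counts_differ_by_at_most_one(self, planted_table):
        res = stratified_split(planted_table, seed=1)
        assert (res.stratum_counts["n1"] - res.stratum_counts["n2"]).abs().max() <= 1
        # every subject lands in exactly one subset
        assert set(res.assignments.unique()) <= {1, 2}
        assert len(res.assignments) == planted_table["subject_id"].nunique()

    def test_balance_by_construction(self, small_atlas):
        """Stratified assignment keeps baseline covariates balanced: across
        seeds the balance p-values are almost always comfortably high."""
        table = generate_cohort(CohortConfig(n_subjects=600, seed=13),
                                small_atlas)
        all_ok = 0
        for seed in range(10):
            res = stratified_split(table, seed=seed)
            ps = [p for p in res.balance.values() if np.isfinite(p)]
            all_ok += all(p > 0.05 for p in ps)
        assert all_ok >= 8

    def test_empty_table_rejected(self, planted_table):
        with pytest.raises(ValueError, match="empty"):
            stratified_split(planted_table.iloc[:0], seed=0)


class TestNormalizeScores:
    def test_orientation_lower_better_for_sse(self):
        m = pd.DataFrame({"sse_ci": [100.0, 300.0]}, index=["a", "b"])
        s = normalize_scores(m)
        assert s.loc["a", "sse_ci"] == 1.0 and s.loc["b", "sse_ci"] == 0.0

    def test_orientation_higher_better_for_t(self):
        m = pd.DataFrame({"t_ab": [2.0, 4.0]}, index=["a", "b"])
        s = normalize_scores(m)
        assert s.loc["a", "t_ab"] == 0.0 and s.loc["b", "t_ab"] == 1.0

    def test_interior_biomarker_leaves_endpoints(self):
        m = pd.DataFrame({"error_pct": [1.0, 2.0, 5.0]}, index=list("abc"))
        s = normalize_scores(m)
        assert s.loc["a", "error_pct"] == 1.0
        assert s.loc["c", "error_pct"] == 0.0
        assert 0.0 < s.loc["b", "error_pct"] < 1.0

    def test_constant_column_maps_to_half_with_warning(self):
        m = pd.DataFrame({"sse_ci": [5.0, 5.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            s = normalize_scores(m)
        assert (s["sse_ci"] == 0.5).all()

    def test_single_biomarker_rejected(self):
        with pytest.raises(ValueError, match="two"):
            normalize_scores(pd.DataFrame({"sse_ci": [1.0]}, index=["a"]))


class TestSensitivityTrim:
    def test_no_extreme_residuals_is_identity(self, hv_series):
        res = sensitivity_trim(hv_series, threshold=np.inf)
        assert res.n_excluded_subjects == 0
        assert (res.shifts == 0).all()
        assert not res.level_lost

    def test_planted_outlier_subjects_are_caught(self, two_region_atlas):
        """Subjects with 10x inflated measurement noise are flagged by the
        Pearson-residual screen and their removal barely moves the fixed
        effects."""
        for seed in (31, 32, 33):
            cfg = CohortConfig(n_subjects=400, seed=seed)
            t = generate_cohort(cfg, two_region_atlas)
            series = column_ratio(t, "hippocampus", "icv")
            planted = sorted(series["subject_id"].unique())[:5]
            rng = np.random.default_rng(seed)
            noisy = series.copy()
            mask = noisy["subject_id"].isin(planted)
            # ~10x sigma_e extra multiplicative noise on planted subjects
            noisy.loc[mask, "value"] *= np.exp(
                rng.normal(0.0, 0.4, int(mask.sum()))
            )
            res = sensitivity_trim(noisy, threshold=3.0)
            caught = set(res.excluded_subjects) & set(planted)
            assert len(caught) >= 4
            assert res.shifts.max() < 1.0  # robust fixed effects

    def test_all_fixed_effects_robust_on_clean_data(self, hv_series):
        res = sensitivity_trim(hv_series, threshold=3.0)
        assert res.shifts.max() < 1.0


class TestEvaluateBiomarker:
    def test_group_cells_and_metrics_present(self, planted_table):
        series = column_ratio(planted_table, "lateral_ventricle", "icv",
                              "ventricles_icv")
        out = evaluate_biomarker(series, "ventricles_icv")
        assert set(METRICS) <= set(out)
        assert out["sse_all"] >= 1 and out["sse_ci"] >= 1
        assert out["error_pct"] > 0
        lo, hi = out["sse_ci_ci"]
        assert lo <= out["sse_ci"] <= hi or lo <= out["sse_ci"] * 1.01

    def test_missing_group_marks_cell_unavailable(self, planted_table):
        cu_only = planted_table[planted_table["DX"] == 0]
        series = column_ratio(cu_only, "lateral_ventricle", "icv")
        with pytest.warns(UserWarning):
            out = evaluate_biomarker(series, "x")
        assert out["sse_ci"] is None  # no CI subgroup present
        assert out["sse_all"] is None  # full variant needs both DX levels


@pytest.fixture(scope="module")
def report(planted_table, small_atlas):
    return run_study(planted_table, small_atlas, TINY_GA, seed=5, n_boot=0)


class TestRunStudy:

    def test_out_of_fold_rule_respected(self, report):
        report.assert_out_of_fold()  # does not raise
        cvr_rows = report.metrics.dropna(subset=["discovery_subset"])
        assert len(cvr_rows) == 4  # 2 CVRs x 2 evaluation subsets
        assert (cvr_rows["discovery_subset"] != cvr_rows["eval_subset"]).all()

    def test_audit_catches_in_fold_rows(self, report):
        bad = report.metrics.copy()
        bad.loc[bad.index[0], "discovery_subset"] = bad.loc[
            bad.index[0], "eval_subset"
        ]
        broken = dataclasses.replace(report, metrics=bad)
        with pytest.raises(AssertionError, match="in-fold"):
            broken.assert_out_of_fold()

    def test_baseline_metrics_match_direct_evaluation(self, report,
                                                      planted_table):
        """run_study's baseline cells equal a direct evaluation on the same
        subset."""
        half1 = report.split.subset(planted_table, 1)
        series = column_ratio(half1, "lateral_ventricle", "icv",
                              "ventricles_icv")
        direct = evaluate_biomarker(series, "ventricles_icv")
        row = report.metrics[
            (report.metrics["biomarker"] == "ventricles_icv")
            & (report.metrics["eval_subset"] == 1)
        ].iloc[0]
        for key in ("sse_all", "sse_ci", "error_pct", "t_ab", "t_dx"):
            assert row[key] == pytest.approx(direct[key], rel=1e-9), key

    def test_singleton_cvr_equals_simple_ratio_everywhere(self, report,
                                                          planted_table):
        """The ventricles/hippocampus baseline is definitionally the CVR
        with singleton composites; their metric rows agree."""
        half2 = report.split.subset(planted_table, 2)
        from cvrkit import compute_cvr

        as_cvr = compute_cvr(
            half2, CVRSpec(("lateral_ventricle",), ("hippocampus",))
        )
        direct = evaluate_biomarker(as_cvr, "x")
        row = report.metrics[
            (report.metrics["biomarker"] == "ventricles_hippocampus")
            & (report.metrics["eval_subset"] == 2)
        ].iloc[0]
        for key in ("sse_all", "sse_ci", "sse_cu", "error_pct", "t_ab", "t_dx"):
            if row[key] is not None:
                assert row[key] == pytest.approx(direct[key], rel=1e-9), key

    def test_heatmap_scores_span_unit_interval(self, report):
        scores = report.heatmap_scores(1)
        vals = scores.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0
        # each metric column has a best (1) and worst (0)
        for col in scores.columns:
            col_vals = scores[col].dropna()
            if col_vals.nunique() > 1:
                assert col_vals.max() == 1.0 and col_vals.min() == 0.0

    def test_end_to_end_determinism(self, report, planted_table, small_atlas):
        again = run_study(planted_table, small_atlas, TINY_GA, seed=5,
                          n_boot=0)
        pd.testing.assert_frame_equal(report.metrics, again.metrics)
        assert report.specs == again.specs
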