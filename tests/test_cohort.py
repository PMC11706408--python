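"""Cohort statistics: outliers, standardisation, group tests, PCA, delay calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gspcmitosis.cohort import (
    build_heatmap_matrix,
    classify_delayed,
    compare_groups_to_control,
    correlate_features_with_duration,
    load_cohort,
    remove_outliers_per_group,
    run_pca,
    standardize,
)
from gspcmitosis.features import FEATURE_COLUMNS


def random_cohort(n_per_group=25, groups=("control", "mutA", "mutB"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n_per_group):
            rows.append({"cell_id": f"{g}_{i}", "group": g, "gonad_id": f"{g}_g{i // 5}",
                         **{f: rng.normal(10, 2) for f in FEATURE_COLUMNS}})
    return pd.DataFrame(rows)


class TestOutlierRemoval:
    def test_forced_example_iqr_zero(self):
        vals = [5, 5, 5, 5, 5, 5, 5, 100]
        df = pd.DataFrame({"group": "g", "cell_id": range(8),
                           **{f: vals for f in FEATURE_COLUMNS}})
        out, log = remove_outliers_per_group(df)
        assert out["A"].isna().sum() == 1
        assert out.loc[out["A"].isna(), "cell_id"].iloc[0] == 7
        # duration (B) is never filtered
        assert out["B"].notna().all()
        assert (log["action"] == "removed").sum() == len(FEATURE_COLUMNS) - 1

    def test_small_group_skipped_and_logged(self):
        df = pd.DataFrame({"group": "g", "cell_id": range(3),
                           **{f: [1.0, 2.0, 3.0] for f in FEATURE_COLUMNS}})
        out, log = remove_outliers_per_group(df)
        assert out[FEATURE_COLUMNS].notna().all().all()
        assert (log["action"] == "skipped").all()

    def test_mask_equals_brute_force_double_loop(self):
        df = random_cohort(seed=3)
        # plant some extremes
        df.loc[3, "C"] = 120.0
        df.loc[40, "E"] = -90.0
        out, _ = remove_outliers_per_group(df)
        for g, sub in df.groupby("group"):
            for f in FEATURE_COLUMNS:
                if f == "B":
                    continue
                vals = sorted(sub[f])
                q1, q3 = np.percentile(vals, 25), np.percentile(vals, 75)
                lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
                for idx in sub.index:
                    expect_removed = df.at[idx, f] < lo or df.at[idx, f] > hi
                    assert pd.isna(out.at[idx, f]) == expect_removed

    def test_single_pass_uses_original_fences_only(self):
        # one-pass semantics: fences come from the unfiltered data, so values
        # inside the original fences survive even if refiltering would not keep them
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(10, 1, 20), [25.0]])
        df = pd.DataFrame({"group": "g", "cell_id": range(21),
                           **{f: vals for f in FEATURE_COLUMNS}})
        out, _ = remove_outliers_per_group(df)
        q1, q3 = np.percentile(vals, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        kept = out["A"].notna()
        assert kept.sum() == ((vals >= lo) & (vals <= hi)).sum()


class TestStandardize:
    def test_control_reference_example(self):
        df = pd.DataFrame({"group": ["control"] * 4 + ["mut"],
                           **{f: [8.0, 10.0, 10.0, 12.0, 14.0] for f in FEATURE_COLUMNS}})
        mu, sd = 10.0, np.std([8, 10, 10, 12], ddof=1)
        out, _ = standardize(df, reference="control", control_group="control")
        assert out.loc[4, "A"] == pytest.approx((14 - mu) / sd)

    def test_pooled_gives_zero_mean_unit_sd(self):
        df = random_cohort(seed=5)
        out, _ = standardize(df, reference="pooled")
        for f in FEATURE_COLUMNS:
            assert out[f].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[f].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_sigma_feature_dropped(self):
        df = random_cohort(seed=6)
        df["D"] = 3.14
        out, dropped = standardize(df, reference="pooled")
        assert dropped == ["D"] and "D" not in out.columns

    def test_matches_brute_force(self):
        df = random_cohort(seed=7)
        out, _ = standardize(df, reference="pooled")
        x = df["F"].to_numpy()
        np.testing.assert_allclose(out["F"], (x - x.mean()) / x.std(ddof=1))


class TestGroupComparisons:
    def test_identical_value_multisets_not_significant(self):
        base = list(np.arange(10.0))
        df = pd.DataFrame({"group": ["control"] * 10 + ["mut"] * 10,
                           **{f: base + base for f in FEATURE_COLUMNS}})
        res = compare_groups_to_control(df, "control")
        assert not res["significant"].any()

    def test_ten_sd_shift_significant(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"group": ["control"] * 30 + ["mut"] * 30,
                           **{f: np.concatenate([rng.normal(0, 1, 30),
                                                 rng.normal(10, 1, 30)])
                              for f in FEATURE_COLUMNS}})
        res = compare_groups_to_control(df, "control")
        assert res["significant"].all()
        assert (res["effect"] > 5).all()

    def test_all_tied_flagged_degenerate(self):
        df = pd.DataFrame({"group": ["control"] * 5 + ["mut"] * 5,
                           **{f: [1.0] * 10 for f in FEATURE_COLUMNS}})
        res = compare_groups_to_control(df, "control")
        assert res["degenerate"].all() and not res["significant"].any()

    def test_small_n_permutation_p_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 5), rng.normal(1.2, 1, 5)
        df = pd.DataFrame({"group": ["control"] * 5 + ["mut"] * 5,
                           **{f: np.concatenate([a, b]) for f in FEATURE_COLUMNS}})
        res = compare_groups_to_control(df, "control", feature_columns=["A"],
                                        omnibus="permutation",
                                        n_permutations=20000, seed=1)
        p_pkg = res.loc[0, "p_omnibus"]
        # independent brute-force permutation null of the H statistic
        pooled = np.concatenate([a, b])
        h_obs = stats.kruskal(a, b).statistic
        rng2 = np.random.default_rng(999)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = rng2.permutation(pooled)
            if stats.kruskal(perm[:5], perm[5:]).statistic >= h_obs - 1e-12:
                count += 1
        p_oracle = (count + 1) / (n_perm + 1)
        mc_sd = 3 * np.sqrt(p_oracle * (1 - p_oracle) / n_perm)
        assert abs(p_pkg - p_oracle) <= 2 * mc_sd + 1e-3


class TestHeatmap:
    def test_entries_follow_definition(self):
        df = random_cohort(seed=10)
        ctrl = df[df["group"] == "control"]
        mat, _ = build_heatmap_matrix(df, "control")
        for f in ("A", "E"):
            want = (df.loc[df["group"] == "mutA", f].mean() - ctrl[f].mean()) / ctrl[f].std(ddof=1)
            assert mat.at[f, "mutA"] == pytest.approx(want)
        np.testing.assert_allclose(mat["control"], 0.0, atol=1e-12)

    def test_shift_by_two_control_sds_gives_entry_two(self):
        rng = np.random.default_rng(11)
        ctrl = rng.normal(10, 2, 200)
        df = pd.DataFrame({"group": ["control"] * 200 + ["mut"] * 200,
                           **{f: np.concatenate([ctrl, ctrl + 2 * np.std(ctrl, ddof=1)])
                              for f in FEATURE_COLUMNS}})
        mat, _ = build_heatmap_matrix(df, "control")
        assert mat.at["C", "mut"] == pytest.approx(2.0)

    def test_invariant_to_affine_unit_rescale(self):
        df = random_cohort(seed=12)
        mat1, _ = build_heatmap_matrix(df, "control")
        df2 = df.copy()
        for f in FEATURE_COLUMNS:
            df2[f] = df2[f] * 1000.0 + 5.0
        mat2, _ = build_heatmap_matrix(df2, "control")
        pd.testing.assert_frame_equal(mat1, mat2)


class TestCorrelations:
    def test_feature_equal_to_negative_duration(self):
        df = random_cohort(seed=13)
        df["I"] = -df["B"]
        res = correlate_features_with_duration(df)
        row = res[res["feature"] == "I"].iloc[0]
        assert row["r"] == pytest.approx(-1.0)
        assert row["reported"] == pytest.approx(-1.0)

    def test_constant_feature_reported_zero_flagged(self):
        df = random_cohort(seed=14)
        df["H"] = 2.0
        res = correlate_features_with_duration(df)
        row = res[res["feature"] == "H"].iloc[0]
        assert row["reported"] == 0.0 and row["flag"] == "undefined"

    def test_bonferroni_multiplier_is_number_of_features(self):
        df = random_cohort(seed=15)
        res = correlate_features_with_duration(df)
        assert len(res) == 8  # A, C..I
        ok = res["p"].notna()
        np.testing.assert_allclose(res.loc[ok, "p_adj"],
                                   np.minimum(1.0, res.loc[ok, "p"] * 8))


class TestPCA:
    def test_single_direction_pc1_explains_everything(self):
        rng = np.random.default_rng(16)
        u = rng.normal(size=9)
        coef = rng.normal(size=40)
        df = pd.DataFrame(np.outer(coef, u) + 5.0, columns=FEATURE_COLUMNS)
        df["group"] = "g"
        _, _, explained, _ = run_pca(df)
        assert explained[0] == pytest.approx(100.0)

    def test_explained_variance_sums_to_100(self):
        df, _ = standardize(random_cohort(seed=17), reference="pooled")
        _, _, explained, _ = run_pca(df)
        assert explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_scores_match_independent_eigensolver_up_to_sign(self):
        df, _ = standardize(random_cohort(seed=18), reference="pooled")
        scores, loadings, _, _ = run_pca(df)
        X = df[FEATURE_COLUMNS].to_numpy(float)
        Xc = X - X.mean(axis=0)
        # independent route: SVD of the centred matrix
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(9):
            got = scores[f"PC{k + 1}"].to_numpy()
            want = Xc @ vt[k]
            assert (np.allclose(got, want, atol=1e-8)
                    or np.allclose(got, -want, atol=1e-8)), f"PC{k + 1}"

    def test_incomplete_rows_dropped_and_reported(self):
        df = random_cohort(seed=19)
        df.loc[5, "C"] = np.nan
        scores, _, _, dropped = run_pca(df)
        assert dropped == [5] and 5 not in scores.index

    def test_fewer_cells_than_features_rejected(self):
        df = random_cohort(n_per_group=3, groups=("g",), seed=20)
        with pytest.raises(ValueError, match="more cells"):
            run_pca(df)


class TestClassifyDelayed:
    def test_integer_control_forced_by_interpolation_convention(self):
        control = np.arange(1.0, 11.0)  # P90 = 9.1
        assert classify_delayed([10.0], control).tolist() == [True]
        assert classify_delayed([9.05], control).tolist() == [False]

    def test_below_control_median_never_delayed(self):
        rng = np.random.default_rng(21)
        control = rng.normal(5, 1, 100)
        med = np.median(control)
        dur = rng.uniform(0, med, 50)
        assert not classify_delayed(dur, control).any()

    def test_monotone_in_duration(self):
        control = np.random.default_rng(22).normal(5, 1, 50)
        dur = np.linspace(0, 10, 101)
        calls = classify_delayed(dur, control)
        assert np.all(np.diff(calls.astype(int)) >= 0)

    def test_requires_ten_controls(self):
        with pytest.raises(ValueError, match=">= 10"):
            classify_delayed([5.0], np.arange(5.0))
        with pytest.raises(ValueError, match="empty"):
            classify_delayed([5.0], [])


class TestLoadCohort:
    def test_csv_and_xlsx_round_trip(self, tmp_path):
        df = random_cohort(n_per_group=5, seed=23)
        csv, xlsx = tmp_path / "t.csv", tmp_path / "t.xlsx"
        df.to_csv(csv, index=False)
        df.to_excel(xlsx, index=False)
        for path in (csv, xlsx):
            loaded = load_cohort(path)
            np.testing.assert_allclose(loaded[FEATURE_COLUMNS], df[FEATURE_COLUMNS])

    def test_missing_feature_column_rejected(self, tmp_path):
        df = random_cohort(n_per_group=5, seed=24).drop(columns=["E"])
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="E"):
            load_cohort(p)
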