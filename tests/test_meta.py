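"""Summaries, paired regression, decomposition, components, factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inavarmeta import CohortConfig, dataset, generate_cohort, meta
from inavarmeta.exceptions import DatasetError, SchemaError, TruncationWarning

from conftest import frame, make_row


def paired_frame(x, y, n_a=10, n_i=10, sd=4.0):
    rows = []
    for j, (xi, yi) in enumerate(zip(x, y)):
        rows.append(make_row("S", f"E{j}", mu_a=xi, mu_i=yi,
                             sd_a=sd, sd_i=sd, n_a=n_a, n_i=n_i))
    return frame(rows)


def small_cohort(seed=0, n=150, **kwargs):
    cfg = CohortConfig(n_experiments=n, fraction_both=1.0,
                       fraction_act_only=0.0, fraction_inact_only=0.0,
                       seed=seed, **kwargs)
    records, truth = generate_cohort(cfg)
    return dataset.resolve_sd(records), truth


class TestSummaries:
    def test_single_record_degenerate(self):
        df = frame([make_row()])
        s = meta.summarize_means(df, "inactivation")
        assert s.median == s.min == s.max == -85.0
        assert s.range == 0.0 and s.p5_p95_range == 0.0

    def test_summary_invariants(self, default_cohort):
        records, _ = default_cohort
        for side in ("activation", "inactivation"):
            for s in (meta.summarize_means(records, side),
                      meta.summarize_sds(records, side),
                      meta.summarize_counts(records, side)):
                assert s.min <= s.median <= s.max
                assert s.p5_p95_range <= s.range
                assert s.count >= 1

    def test_percentile_convention_is_linear_interpolation(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = frame([make_row("S", f"E{j}", mu_a=v) for j, v in
                    enumerate(values)])
        s = meta.summarize_means(df, "activation")
        lo, hi = np.percentile(values, [5, 95])
        assert s.p5_p95_range == pytest.approx(hi - lo)

    def test_empty_selection_is_error(self):
        df = frame([make_row(mu_i=np.nan, sd_i=np.nan, n_i=np.nan)])
        with pytest.raises(DatasetError):
            meta.summarize_means(df, "inactivation")

    def test_constant_sds_have_zero_range(self):
        df = frame([make_row("S", f"E{j}") for j in range(4)])
        assert meta.summarize_sds(df, "activation").range == 0.0


class TestNormal90Width:
    def test_zero_sigma(self):
        assert meta.normal_90_width(0.0) == 0.0

    @pytest.mark.parametrize("sigma,approx", [(3.6, 12), (4.0, 13)])
    def test_typical_within_experiment_ranges(self, sigma, approx):
        width = meta.normal_90_width(sigma)
        assert round(width) == approx
        assert width == pytest.approx(2 * 1.6449 * sigma)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            meta.normal_90_width(-1.0)


class TestPairedRegression:
    def test_collinear_points(self):
        df = paired_frame([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        r = meta.paired_regression(df)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(r.pearson_r**2, abs=1e-12)

    def test_matches_independent_linregress_and_t_interval(self, default_cohort):
        records, _ = default_cohort
        r = meta.paired_regression(records)
        paired = records.dropna(subset=["mu_a", "mu_i"])
        lr = stats.linregress(paired["mu_a"], paired["mu_i"])
        assert r.slope == pytest.approx(lr.slope, rel=1e-10)
        assert r.intercept == pytest.approx(lr.intercept, rel=1e-10)
        assert r.pearson_r == pytest.approx(lr.rvalue, rel=1e-10)
        half = stats.t.ppf(0.975, len(paired) - 2) * lr.stderr
        assert r.slope_ci_low == pytest.approx(lr.slope - half, rel=1e-9)
        assert r.slope_ci_high == pytest.approx(lr.slope + half, rel=1e-9)

    def test_zero_variance_singular(self):
        df = paired_frame([-40.0] * 5, [-80.0, -81, -82, -83, -84])
        with pytest.raises(DatasetError):
            meta.paired_regression(df)

    def test_too_few_pairs(self):
        df = paired_frame([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(DatasetError):
            meta.paired_regression(df)

    def test_r2_invariant_to_common_affine_rescaling(self, default_cohort):
        records, _ = default_cohort
        scaled = records.copy()
        scaled["mu_a"] = 2.5 * scaled["mu_a"] + 7.0
        scaled["mu_i"] = 2.5 * scaled["mu_i"] + 7.0
        r1 = meta.paired_regression(records)
        r2 = meta.paired_regression(scaled)
        assert r2.r_squared == pytest.approx(r1.r_squared, rel=1e-9)

    def test_permutation_destroys_correlation(self):
        records, _ = small_cohort(seed=21)
        rng = np.random.default_rng(21)
        r2s = []
        for _ in range(100):
            perm = records.copy()
            perm["mu_i"] = rng.permutation(perm["mu_i"].to_numpy())
            r2s.append(meta.paired_regression(perm).r_squared)
        assert np.median(r2s) < 0.05


class TestFixedSlopeRegression:
    def test_exact_offset_data(self):
        x = np.array([-50.0, -45.0, -40.0, -35.0])
        df = paired_frame(x, x - 45.0)
        fs = meta.fixed_slope_regression(df, slope=1.0)
        assert fs.intercept == pytest.approx(-45.0)

    def test_intercept_identity_at_slope_one(self, default_cohort):
        records, _ = default_cohort
        fs = meta.fixed_slope_regression(records, slope=1.0)
        paired = records.dropna(subset=["mu_a", "mu_i"])
        assert fs.intercept == pytest.approx(
            paired["mu_i"].mean() - paired["mu_a"].mean(), abs=1e-12
        )

    def test_uncorrelated_cohort_rejects_slope_one(self):
        """With no shared shift and large independent shifts, the free
        slope concentrates near zero and excludes 1 in most cohorts."""
        rejected = 0
        for seed in range(10):
            records, _ = small_cohort(seed=seed, tau_corr=0.0,
                                      tau_unc_a=8.0, tau_unc_i=8.0)
            fs = meta.fixed_slope_regression(records, slope=1.0)
            rejected += not fs.slope_in_free_ci
        assert rejected >= 8


class TestDecomposition:
    def test_point_on_best_fit_line_has_zero_pc2(self):
        x = np.array([-50.0, -45.0, -40.0, -35.0, -30.0])
        df = paired_frame(x, 0.9 * x - 45.0)
        dec = meta.decompose(df)
        assert np.allclose(dec.pc2, 0.0, atol=1e-9)

    def test_conservation_of_squared_distances(self, default_cohort):
        records, _ = default_cohort
        dec = meta.decompose(records)
        paired = records.dropna(subset=["mu_a", "mu_i"])
        dx = paired["mu_a"].to_numpy() - dec.center[0]
        dy = paired["mu_i"].to_numpy() - dec.center[1]
        assert np.allclose(dec.pc1**2 + dec.pc2**2, dx**2 + dy**2, atol=1e-9)

    def test_components_are_centered(self, default_cohort):
        records, _ = default_cohort
        dec = meta.decompose(records)
        assert abs(dec.pc1.mean()) < 1e-9
        assert abs(dec.pc2.mean()) < 1e-9

    def test_sign_conventions(self):
        x = np.array([-50.0, -45.0, -40.0, -35.0, -30.0])
        df = paired_frame(x, x - 45.0)
        dec = meta.decompose(df)
        # most depolarized mu_a point carries the largest positive pc1
        assert dec.pc1[np.argmax(x)] == dec.pc1.max() > 0

    def test_pca_axis_option(self, default_cohort):
        records, _ = default_cohort
        ols = meta.decompose(records, axis="ols")
        pca = meta.decompose(records, axis="pca")
        # both are unit axes; PCA tilts slightly away from the OLS line
        assert np.linalg.norm(pca.axis) == pytest.approx(1.0)
        assert not np.allclose(pca.axis, ols.axis)
        cov = np.cov(records.dropna(subset=["mu_a", "mu_i"])[["mu_a", "mu_i"]].T,
                     ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        assert abs(np.dot(lead, pca.axis)) == pytest.approx(1.0)

    def test_correlated_artifact_cohort_lands_in_pc1(self):
        """When between-experiment variability is a shared shift only,
        the perpendicular component stays at the sampling floor."""
        records, _ = small_cohort(seed=13, tau_corr=8.0, tau_unc_a=0.0,
                                  tau_unc_i=0.0, sigma_within_a=1.0,
                                  sigma_within_i=1.0)
        dec = meta.decompose(records)
        assert np.median(np.abs(dec.pc2)) < 1.0
        assert dec.regression.slope == pytest.approx(1.0, abs=0.1)


class TestFunnel:
    def test_sqrt_size(self):
        x = np.array([-50.0, -40.0, -30.0])
        df = paired_frame(x, x - 45.0, n_a=8, n_i=8)
        dec = meta.decompose(df)
        tab = meta.funnel_table(dec)
        assert (tab["size"] == 16).all()
        assert (tab["sqrt_size"] == 4.0).all()

    def test_pure_sampling_noise_narrows_with_size(self):
        """With no between-experiment components the spread of pc1 is
        sampling noise, which shrinks as 1/sqrt(n)."""
        records, _ = small_cohort(seed=3, n=2000, tau_corr=0.0,
                                  tau_unc_a=2.0, tau_unc_i=2.0)
        # tiny tau_unc keeps the regression defined; sampling still dominates
        dec = meta.decompose(records)
        tab = meta.funnel_table(dec)
        q1, q3 = tab["size"].quantile([0.25, 0.75])
        sd_small = tab.loc[tab["size"] <= q1, "pc1"].std(ddof=1)
        sd_large = tab.loc[tab["size"] >= q3, "pc1"].std(ddof=1)
        assert sd_large <= sd_small

    def test_between_experiment_variance_shows_no_funnel(self):
        records, _ = small_cohort(seed=4, n=2000, tau_corr=10.0,
                                  sigma_within_a=1.0, sigma_within_i=1.0)
        dec = meta.decompose(records)
        tab = meta.funnel_table(dec)
        q1, q3 = tab["size"].quantile([0.25, 0.75])
        sd_small = tab.loc[tab["size"] <= q1, "pc1"].std(ddof=1)
        sd_large = tab.loc[tab["size"] >= q3, "pc1"].std(ddof=1)
        assert sd_large / sd_small == pytest.approx(1.0, abs=0.15)


class TestEstimateComponents:
    def test_recovers_generating_values(self):
        records, _ = small_cohort(seed=17, n=1500)
        est = meta.estimate_components(records, n_bootstrap=500, seed=1)
        assert est.tau_corr == pytest.approx(8.0, abs=0.8)
        assert est.tau_unc_a == pytest.approx(4.0, abs=1.2)
        assert est.tau_unc_i == pytest.approx(4.0, abs=1.2)

    def test_consistency_with_cohort_size(self):
        errs = []
        for n in (150, 1500, 15000):
            records, _ = small_cohort(seed=29, n=n)
            est = meta.estimate_components(records, n_bootstrap=50, seed=0)
            errs.append(abs(est.tau_corr - 8.0))
        assert errs[2] < errs[0]
        assert errs[2] < 0.3

    def test_null_shared_component_ci_covers_zero(self):
        records, _ = small_cohort(seed=23, tau_corr=0.0)
        est = meta.estimate_components(records, n_bootstrap=500, seed=2)
        assert est.ci["tau_corr"][0] == pytest.approx(0.0, abs=1e-9)

    def test_identical_records_give_zero_estimates(self):
        df = frame([make_row("S", f"E{j}") for j in range(12)])
        with pytest.warns(TruncationWarning):
            est = meta.estimate_components(df, n_bootstrap=50, seed=0)
        assert est.tau_corr == 0.0
        assert est.tau_unc_a == 0.0 and est.truncated["tau_unc_a"]

    def test_insufficient_records(self):
        df = frame([make_row("S", f"E{j}") for j in range(5)])
        with pytest.raises(DatasetError):
            meta.estimate_components(df)


class TestSubgroups:
    def test_two_study_toy_partition(self):
        rows = [make_row("S1", f"E{j}") for j in range(3)]
        rows += [make_row("S2", f"E{j}") for j in range(2)]
        out = meta.subgroup_summary(frame(rows), "study_id")
        assert {k: v.n for k, v in out.items()} == {"S1": 3, "S2": 2}

    def test_independent_labels_do_not_cluster(self, default_cohort):
        """Metadata drawn independently of the shifts: group medians stay
        well inside one between-experiment SD of each other."""
        records, _ = default_cohort
        overall_sd = records["mu_i"].std(ddof=1)
        out = meta.subgroup_summary(records, "alpha_subunit")
        medians = [g.inactivation.median for g in out.values()
                   if g.inactivation and g.n >= 5]
        assert max(medians) - min(medians) < overall_sd

    def test_constructed_shift_is_detected(self):
        base, _ = small_cohort(seed=31, n=60)
        shifted, _ = small_cohort(seed=32, n=60)
        shifted = shifted.copy()
        shifted["mu_i"] -= 10.0
        shifted["cell_type"] = "CHO"
        base["cell_type"] = "HEK"
        shifted["experiment_id"] = "X" + shifted["experiment_id"]
        df = pd.concat([base, shifted], ignore_index=True)
        out = meta.subgroup_summary(df, "cell_type")
        assert out["CHO"].inactivation.median < out["HEK"].inactivation.median - 5

    def test_unknown_key_is_schema_error(self, default_cohort):
        records, _ = default_cohort
        with pytest.raises(SchemaError):
            meta.subgroup_summary(records, "nope")

    def test_subgroup_ranges_bounded_by_full_range(self, default_cohort):
        records, _ = default_cohort
        full = meta.summarize_means(records, "inactivation").range
        for key in ("alpha_subunit", "beta1", "cell_type", "study_id"):
            for g in meta.subgroup_summary(records, key).values():
                if g.inactivation:
                    assert g.inactivation.range <= full + 1e-12


class TestFactorRegression:
    def test_identity_factor_r2_is_one(self):
        records, _ = small_cohort(seed=37, n=30)
        res = meta.factor_regression(records, "mu_a", "mu_a")
        assert res.r_squared == pytest.approx(1.0)

    def test_constructed_linear_factor(self):
        records, _ = small_cohort(seed=41, n=50)
        records = records.copy()
        rng = np.random.default_rng(41)
        records["v_hold_a"] = -120.0 + 0.5 * records["mu_a"] + rng.normal(
            0, 0.5, len(records))
        res = meta.factor_regression(records, "v_hold_a", "mu_a")
        assert res.r_squared > 0.8
        assert res.n_points == 50

    def test_complete_case_counting(self):
        records, _ = small_cohort(seed=43, n=20)
        records = records.copy()
        records.loc[records.index[:12], "k_a"] = 7.0 + 0.1 * np.arange(12)
        res = meta.factor_regression(records, "k_a", "mu_a")
        assert res.n_points == 12

    def test_all_missing_factor_is_error(self):
        records, _ = small_cohort(seed=47, n=20)
        with pytest.raises(DatasetError):
            meta.factor_regression(records, "v_peak", "mu_a")

    def test_unknown_factor_is_schema_error(self, default_cohort):
        records, _ = default_cohort
        with pytest.raises(SchemaError):
            meta.factor_regression(records, "foo", "mu_a")

    def test_ljp_status_group_summaries(self, default_cohort):
        records, _ = default_cohort
        out = meta.factor_regression(records, "ljp_status", "mu_i")
        assert set(out) <= {"corrected", "uncorrected", "unreported"}
        assert all(hasattr(s, "median") for s in out.values())
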