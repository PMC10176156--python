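"""4PL chart fitting, goodness-of-fit groupings, LME correction, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

import motorchart as mc

TRUE = mc.SigmoidParams(L=4.0, U=18.0, x0=11.0, k=0.8)


def grid_oracle_sse(ages, values, best_sse):
    """Coarse brute-force lattice over (L, U, x0, k): the optimizer's SSE
    must not be beaten by more than numerical tolerance."""
    ages = np.asarray(ages)
    values = np.asarray(values)
    lattice = itertools.product(
        np.linspace(values.min() - 2, values.min() + 2, 7),
        np.linspace(values.max() - 2, values.max() + 2, 7),
        np.linspace(ages.min(), ages.max(), 9),
        np.linspace(0.1, 2.0, 9),
    )
    worst = np.inf
    for L, U, x0, k in lattice:
        sse = float(np.sum((mc.sigmoid(ages, L, U, x0, k) - values) ** 2))
        worst = min(worst, sse)
    return worst


class TestSigmoidFit:
    def test_noiseless_recovery_to_1e4(self):
        ages = np.linspace(4, 18, 29)
        values = TRUE(ages)
        est = mc.fit_sigmoid(ages, values)
        np.testing.assert_allclose(est.as_array(), TRUE.as_array(), atol=1e-4)
        gof = mc.goodness_of_fit(est, ages, values, "raw")
        assert gof["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_grid_oracle_never_beats_optimizer(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(4, 18, 40)
        values = TRUE(ages) + rng.normal(0, 0.3, 40)
        est = mc.fit_sigmoid(ages, values)
        assert grid_oracle_sse(ages, values, est.sse) >= est.sse - 1e-6

    def test_constant_values_degenerate_without_error(self):
        ages = np.linspace(4, 18, 20)
        values = np.full(20, 7.5)
        est = mc.fit_sigmoid(ages, values)
        np.testing.assert_allclose(est(ages), 7.5, atol=1e-6)
        gof = mc.goodness_of_fit(est, ages, values, "raw")
        assert gof["r2"] == 0.0 and gof["zero_variance"]

    def test_noisy_fit_converges_pointwise(self):
        """With n=300 noisy points the fitted curve sits within 3*sigma/sqrt(n)
        of the generating curve (least-squares consistency)."""
        rng = np.random.default_rng(2)
        ages = rng.uniform(4, 18, 300)
        values = TRUE(ages) + rng.normal(0, 0.5, 300)
        est = mc.fit_sigmoid(ages, values)
        grid = np.linspace(4, 18, 50)
        assert np.abs(est(grid) - TRUE(grid)).max() < 3 * 0.5 / np.sqrt(300)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(4, 18, 60)
        values = TRUE(ages) + rng.normal(0, 0.4, 60)
        a = mc.fit_sigmoid(ages, values)
        perm = rng.permutation(60)
        b = mc.fit_sigmoid(ages[perm], values[perm])
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-6)

    def test_canonical_orientation(self):
        est = mc.fit_sigmoid(np.linspace(4, 18, 30), TRUE(np.linspace(4, 18, 30)))
        assert est.U >= est.L

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">= 5"):
            mc.fit_sigmoid([4, 5, 6], [1, 2, 3])
        with pytest.raises(ValueError, match="varying"):
            mc.fit_sigmoid([5] * 6, [1, 2, 3, 4, 5, 6])


class TestGoodnessOfFit:
    def test_alternating_unit_residuals_give_sigma_one(self):
        ages = np.linspace(4, 18, 40)
        values = TRUE(ages) + np.resize([1.0, -1.0], 40)
        gof = mc.goodness_of_fit(TRUE, ages, values, "raw")
        assert gof["sigma"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_curve_perfect_for_all_groupings(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(4, 18, 100)
        values = TRUE(ages)
        subj = np.repeat([f"s{i}" for i in range(25)], 4)
        for grouping in ("raw", "id_controlled"):
            gof = mc.goodness_of_fit(TRUE, ages, values, grouping, subject_ids=subj)
            assert gof["r2"] == pytest.approx(1.0, abs=1e-6)
            assert gof["sigma"] == pytest.approx(0.0, abs=1e-6)
        # bin means of a nonlinear curve differ from the curve at the bin-mean
        # age by a small Jensen gap, so the grouped metric is near- but not
        # exactly perfect even on noiseless data
        gof = mc.goodness_of_fit(TRUE, ages, values, "monthly_means", subject_ids=subj)
        assert gof["r2"] > 0.999
        assert gof["sigma"] < 0.05

    def test_monthly_means_shrink_independent_noise(self):
        rng = np.random.default_rng(5)
        ages = np.repeat(np.arange(4, 18) + 0.5, 30)
        values = TRUE(ages) + rng.normal(0, 1.0, len(ages))
        raw = mc.goodness_of_fit(TRUE, ages, values, "raw")
        grouped = mc.goodness_of_fit(TRUE, ages, values, "monthly_means")
        assert grouped["r2"] >= raw["r2"]
        assert grouped["sigma"] <= raw["sigma"]


class TestLMECorrection:
    def make_panel(self, n_subjects, per_subject, b_sd, e_sd, seed):
        rng = np.random.default_rng(seed)
        subj = np.repeat([f"s{i}" for i in range(n_subjects)], per_subject)
        ages = np.tile(np.linspace(5, 17, per_subject), n_subjects)
        b = np.repeat(rng.normal(0, b_sd, n_subjects), per_subject)
        e = rng.normal(0, e_sd, len(subj))
        return ages, TRUE(ages) + b + e, subj

    def test_pure_offsets_removed_almost_entirely(self):
        """With zero within-subject noise the REML intercepts absorb the
        offsets; only shrinkage residue remains."""
        ages, values, subj = self.make_panel(50, 4, 1.0, 0.0, seed=1)
        corr = mc.lme_correction(ages, values, subj, TRUE)
        assert corr.sigma_idcontrolled < 0.05

    def test_variance_component_recovery(self):
        """REML recovers both variance components of b_i + e_ij; the RMS of
        the corrected residuals is necessarily a shade below the noise SD
        because the fitted intercepts absorb part of each subject's noise."""
        ages, values, subj = self.make_panel(500, 4, 1.0, 0.5, seed=2)
        corr = mc.lme_correction(ages, values, subj, TRUE)
        assert corr.intercept_var == pytest.approx(1.0, rel=0.15)
        assert np.sqrt(corr.residual_var) == pytest.approx(0.5, rel=0.10)
        assert corr.sigma_idcontrolled <= 0.5 * 1.05

    @pytest.mark.parametrize("seed", range(5))
    def test_correction_never_inflates_sigma(self, seed):
        ages, values, subj = self.make_panel(40, 3, 0.8, 0.6, seed=seed)
        corr = mc.lme_correction(ages, values, subj, TRUE)
        raw_sigma = float(np.sqrt(np.mean((values - TRUE(ages)) ** 2)))
        assert corr.sigma_idcontrolled <= raw_sigma + 1e-9

    def test_singletons_fall_back_to_raw_residuals(self):
        ages = np.linspace(4, 18, 20)
        values = TRUE(ages) + 0.3
        subj = np.array([f"s{i}" for i in range(20)])
        corr = mc.lme_correction(ages, values, subj, TRUE)
        assert not corr.used_lme
        np.testing.assert_allclose(corr.corrected_residuals, 0.3, atol=1e-12)


class TestBootstrap:
    def test_degenerate_sample_gives_point_interval(self):
        data = pd.DataFrame({"v": [5.0, 5.0, 5.0, 5.0]})
        ci = mc.bootstrap_ci(lambda t: t["v"].mean(), data, n_boot=200, seed=0)
        assert (ci.lo, ci.hi) == (5.0, 5.0)

    def test_clt_width_for_the_mean(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame({"v": rng.normal(0, 1, 400)})
        ci = mc.bootstrap_ci(lambda t: t["v"].mean(), data, n_boot=2000, seed=1)
        width = ci.hi - ci.lo
        assert width == pytest.approx(2 * 1.96 / np.sqrt(400), rel=0.2)

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"v": rng.normal(size=50)})
        a = mc.bootstrap_ci(lambda t: t["v"].mean(), data, n_boot=300, seed=9)
        b = mc.bootstrap_ci(lambda t: t["v"].mean(), data, n_boot=300, seed=9)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError, match="100"):
            mc.bootstrap_ci(lambda t: 0.0, pd.DataFrame({"v": [1.0]}), n_boot=50)

    def test_undefined_metric_redrawn_and_counted(self):
        data = pd.DataFrame({"v": [0.0, 1.0, 2.0, 3.0]})

        def flaky(t):
            return float("nan") if t["v"].iloc[0] == 0.0 else t["v"].mean()

        ci = mc.bootstrap_ci(flaky, data, n_boot=200, seed=2)
        assert ci.n_redrawn > 0 and np.isfinite(ci.lo)

    def test_subject_unit_resamples_whole_subjects(self):
        data = pd.DataFrame({"v": [1.0, 1.0, 5.0, 5.0],
                             "subject_id": ["a", "a", "b", "b"]})
        # with whole-subject resampling the mean is always 1, 3, or 5
        ci = mc.bootstrap_ci(lambda t: t["v"].mean(), data, n_boot=500,
                             unit="subject", seed=3)
        assert set([ci.lo, ci.hi]) <= {1.0, 3.0, 5.0}


class TestBuildChart:
    def make_table(self, n=240, noise=0.8, b_sd=0.6, seed=8):
        rng = np.random.default_rng(seed)
        n_subj = n // 4
        subj = np.repeat([f"s{i}" for i in range(n_subj)], 4)
        ages = rng.uniform(4, 18, n)
        b = np.repeat(rng.normal(0, b_sd, n_subj), 4)
        return pd.DataFrame({
            "subject_id": subj, "age_months": ages,
            "dap_months": TRUE(ages) + b + rng.normal(0, noise, n),
        })

    def test_insufficient_span_rejected(self):
        table = self.make_table(n=20)
        table["age_months"] = np.linspace(5, 6.9, 20)
        with pytest.raises(ValueError, match="insufficient span"):
            mc.build_chart(table, "motor", n_boot=100, n_boot_id=100)

    def test_noiseless_chart_has_zero_sigma(self):
        table = self.make_table(noise=1e-9, b_sd=0.0)
        chart = mc.build_chart(table, "length", n_boot=100, n_boot_id=100)
        assert chart.quality["raw"]["sigma"] < 1e-6
        assert chart.quality["raw"]["r2"] > 0.999999

    def test_quality_orderings_and_cis(self):
        chart = mc.build_chart(self.make_table(), "motor", n_boot=150, n_boot_id=100)
        q = chart.quality
        # subject offsets exist: removing them tightens the fit
        assert q["id_controlled"]["sigma"] <= q["raw"]["sigma"]
        assert q["id_controlled"]["r2"] >= q["raw"]["r2"]
        assert q["monthly_means"]["r2"] >= q["raw"]["r2"]
        for entry in q.values():
            assert entry["sigma_ci"].lo <= entry["sigma"] <= entry["sigma_ci"].hi
        for name in ("L", "U", "x0", "k"):
            assert chart.param_ci[name].lo <= chart.param_ci[name].hi

    def test_doubling_noise_raises_sigma(self):
        lo = mc.build_chart(self.make_table(noise=0.5, seed=10), "m",
                            n_boot=100, n_boot_id=100)
        hi = mc.build_chart(self.make_table(noise=1.0, seed=10), "m",
                            n_boot=100, n_boot_id=100)
        assert hi.sigma_band > lo.sigma_band

    def test_band_is_fit_plus_minus_sigma(self):
        chart = mc.build_chart(self.make_table(), "motor", n_boot=100, n_boot_id=100)
        x = np.array([6.0, 12.0])
        lo, hi = chart.band(x)
        np.testing.assert_allclose(hi - lo, 2 * chart.sigma_band)
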