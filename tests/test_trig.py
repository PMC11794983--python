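import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit
from scipy.stats import chi2

from dielact.occasions import aggregate_binomial, bin_detections
from dielact.sim import SimParams, simulate_detections
from dielact.trig import (TrigFit, TrigModelSpec, aic, amplitude_phase,
                          compare_aic, fit_trig, harmonic_design, lrt,
                          nll_integrated, wald_test)


class TestHarmonicDesign:
    def test_single_period_at_midnight(self):
        X = harmonic_design([0.0], [24])
        assert X.iloc[0].tolist() == pytest.approx([1.0, 1.0, 0.0])

    def test_two_periods_at_six(self):
        X = harmonic_design([6.0], [24, 12])
        assert X.iloc[0].tolist() == pytest.approx([1, 0, 1, -1, 0], abs=1e-12)

    def test_interaction_columns_with_binary_covariate(self):
        cov = pd.DataFrame({"season": ["a", "b", "a"]})
        X = harmonic_design([0.0, 6.0, 12.0], [24, 12], cov, interactions=True)
        # intercept + 4 harmonics + 1 dummy + 4 interactions = 10 columns
        assert X.shape[1] == 10
        base = X[X["season[b]"] == 0]
        inter_cols = [c for c in X.columns if ":" in c]
        assert (base[inter_cols] == 0).all().all()

    def test_duplicate_periods_rejected(self):
        with pytest.raises(ValueError):
            harmonic_design([0.0], [24, 24])

    def test_periodicity_in_time(self, rng):
        t = rng.uniform(0, 24, 50)
        a = harmonic_design(t, [24, 12]).to_numpy()
        b = harmonic_design((t + 24) % 24, [24, 12]).to_numpy()
        assert np.allclose(a, b, atol=1e-9)


class TestIntegratedLikelihood:
    def test_vanishing_re_sd_matches_plain_glm(self, toy_occasions):
        import statsmodels.api as sm
        spec = TrigModelSpec(periods=(24.0,), quad_points=11)
        X = harmonic_design(toy_occasions["time"], [24]).to_numpy()
        glm = sm.GLM(np.c_[toy_occasions["success"], toy_occasions["failure"]],
                     X, family=sm.families.Binomial()).fit()
        theta = np.r_[glm.params, math.log(1e-8)]
        assert nll_integrated(spec, theta, toy_occasions) == pytest.approx(
            -glm.llf, abs=1e-4)

    def test_all_failures_closed_form(self, toy_occasions):
        # success=0 everywhere at beta0=0, sd->0: each Bernoulli cell
        # contributes log 2, so nll = total_trials * log 2
        occ = toy_occasions.copy()
        occ["success"] = 0
        occ["failure"] = 10
        spec = TrigModelSpec(periods=(), quad_points=11)
        val = nll_integrated(spec, np.array([0.0, math.log(1e-8)]), occ)
        assert val == pytest.approx(80 * math.log(2), abs=1e-6)

    def test_node_count_convergence(self, toy_occasions):
        theta = np.r_[[-1.0, 0.8, -0.5], math.log(0.8)]
        vals = [nll_integrated(TrigModelSpec(periods=(24.0,), quad_points=k),
                               theta, toy_occasions) for k in (25, 51)]
        assert abs(vals[0] - vals[1]) <= 1e-6

    def test_wrong_length_theta_rejected(self, toy_occasions):
        with pytest.raises(ValueError):
            nll_integrated(TrigModelSpec(periods=(24.0,)), np.zeros(3),
                           toy_occasions)


class TestFit:
    def test_recovers_truth_within_wald_intervals(self, bimodal_fit,
                                                  bimodal_params):
        p = bimodal_params
        truth = {
            "(Intercept)": p.beta0,
            "cos24": p.beta1 * math.cos(p.theta0),
            "sin24": -p.beta1 * math.sin(p.theta0),
            "cos12": p.beta2 * math.cos(p.theta1),
            "sin12": -p.beta2 * math.sin(p.theta1),
        }
        se = np.sqrt(np.diag(bimodal_fit.fixed_vcov))
        for i, (name, tv) in enumerate(truth.items()):
            est = bimodal_fit.alpha[name]
            assert abs(est - tv) < 3.5 * se[i], name
        # sigma_tau on the log scale
        k = len(bimodal_fit.alpha)
        se_log = math.sqrt(bimodal_fit.vcov.iloc[k, k])
        assert abs(math.log(bimodal_fit.re_sd.iloc[0])
                   - math.log(p.sigma_tau)) < 3.5 * se_log

    def test_perturbed_start_reproduces_loglik(self, bimodal_occasions,
                                               bimodal_fit):
        occ, _ = bimodal_occasions
        start = bimodal_fit.theta + 0.3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit = fit_trig(TrigModelSpec(), occ, start=start,
                             compute_vcov=False)
        assert refit.loglik == pytest.approx(bimodal_fit.loglik, abs=1e-4)

    def test_pooled_intercept_equals_logit_frequency(self):
        # identical sites: the random-intercept SD collapses and the
        # intercept matches the pooled empirical logit
        occ = pd.DataFrame({
            "site": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "time": [0.0, 6.0, 12.0, 18.0] * 3,
            "success": [2] * 12,
            "failure": [8] * 12,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit_trig(TrigModelSpec(periods=()), occ)
        assert f.alpha["(Intercept)"] == pytest.approx(logit(0.2), abs=1e-3)

    def test_single_site_rejected_and_few_sites_warn(self, toy_occasions):
        solo = toy_occasions[toy_occasions["site"] == "A"]
        with pytest.raises(ValueError):
            fit_trig(TrigModelSpec(periods=()), solo)
        with pytest.warns(UserWarning, match="sites"):
            fit_trig(TrigModelSpec(periods=()), toy_occasions,
                     compute_vcov=False)

    def test_null_model_df_is_two(self, toy_occasions):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit_trig(TrigModelSpec(periods=()), toy_occasions,
                         compute_vcov=False)
        assert f.df == 2  # intercept + sigma_tau

    def test_random_slope_structure_fits(self):
        p = SimParams(sigma_gamma=0.3, sigma_tau=0.8, beta2=0.0)
        det, eff, _ = simulate_detections(p, 15, 25, 1.0, seed=21)
        occ = aggregate_binomial(bin_detections(det, eff, 1.0))
        spec = TrigModelSpec(periods=(24.0,),
                             random_structure="intercept_plus_diagonal_slopes",
                             quad_points=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit_trig(spec, occ, compute_vcov=False)
        assert f.df == len(f.alpha) + 3
        assert (f.re_sd >= 0).all()
        assert f.blups.shape == (15, 3)


class TestModelComparison:
    def test_aic_arithmetic(self, bimodal_fit):
        fake = TrigFit(spec=bimodal_fit.spec, alpha=bimodal_fit.alpha,
                       re_sd=bimodal_fit.re_sd, re_corr=None, loglik=-100.0,
                       df=4, vcov=bimodal_fit.vcov, converged=True,
                       grad_norm=0.0, blups=bimodal_fit.blups, n_sites=2,
                       n_obs=8, fingerprint=1)
        assert aic(fake) == pytest.approx(208.0)

    def test_identical_fits_have_zero_delta(self, bimodal_fit):
        tab = compare_aic({"m1": bimodal_fit, "m2": bimodal_fit})
        assert (tab["deltaAIC"] == 0).all()

    def test_differing_data_rejected(self, bimodal_fit):
        import dataclasses
        other = dataclasses.replace(bimodal_fit, fingerprint=999)
        with pytest.raises(ValueError):
            compare_aic({"a": bimodal_fit, "b": other})
        with pytest.raises(ValueError):
            lrt(dataclasses.replace(other, df=2), bimodal_fit)

    def test_bimodal_data_ranks_bimodal_first(self, bimodal_occasions):
        from dielact.analysis import shape_analysis
        occ, _ = bimodal_occasions
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = shape_analysis(occ, ci_seed=0)
        assert res["best"] == "bimodal"
        assert list(res["aic_table"].index) == ["bimodal", "unimodal", "null_mod"]

    def test_lrt_identical_loglik_gives_p_one(self, bimodal_fit):
        import dataclasses
        nested = dataclasses.replace(bimodal_fit, df=bimodal_fit.df - 2)
        stat, df, p = lrt(nested, bimodal_fit)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_lrt_chi_square_oracle(self, bimodal_fit):
        import dataclasses
        nested = dataclasses.replace(bimodal_fit, df=bimodal_fit.df - 2,
                                     loglik=bimodal_fit.loglik - 5.99 / 2)
        stat, df, p = lrt(nested, bimodal_fit)
        assert stat == pytest.approx(5.99)
        assert p == pytest.approx(chi2.sf(5.99, 2), abs=1e-12)
        assert p == pytest.approx(0.0500, abs=2e-4)

    def test_lrt_nesting_violation_detected(self, bimodal_fit):
        import dataclasses
        nested = dataclasses.replace(bimodal_fit, df=bimodal_fit.df - 2,
                                     loglik=bimodal_fit.loglik + 1.0)
        with pytest.raises(ValueError, match="nesting"):
            lrt(nested, bimodal_fit)

    def test_lrt_type_i_error_near_nominal(self):
        # cathemeral truth: the 24h-harmonic LRT should reject ~5% of the time
        p = SimParams(beta0=-2.0, beta1=0.0, beta2=0.0, sigma_tau=0.7,
                      sigma_gamma=0.0)
        n_rep, rejections = 100, 0
        stats = []
        for r in range(n_rep):
            det, eff, _ = simulate_detections(p, 25, 15, 1.0, seed=50_000 + r)
            occ = aggregate_binomial(bin_detections(det, eff, 1.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f0 = fit_trig(TrigModelSpec(periods=()), occ, compute_vcov=False)
                f1 = fit_trig(TrigModelSpec(periods=(24.0,)), occ,
                              compute_vcov=False)
            stat, _, pval = lrt(f0, f1)
            stats.append(stat)
            rejections += pval < 0.05
        # binomial 3*SE band around the nominal level
        assert abs(rejections / n_rep - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / n_rep)
        # the statistic's mean should sit near the chi-square(2) mean of 2
        assert abs(np.mean(stats) - 2.0) <= 3 * np.std(stats) / math.sqrt(n_rep)


class TestAmplitudePhase:
    @pytest.mark.parametrize("ac,as_,amp,phase", [
        (1.0, 0.0, 1.0, 0.0),
        (0.0, -1.0, 1.0, math.pi / 2),
        (0.5, 0.5, math.sqrt(0.5), -math.pi / 4),
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_known_inversions(self, ac, as_, amp, phase):
        b, th = amplitude_phase(ac, as_)
        assert b == pytest.approx(amp, abs=1e-12)
        assert th == pytest.approx(phase, abs=1e-12)

    def test_peak_hour_matches_curve_argmax(self):
        b, th = amplitude_phase(0.5, 0.5)
        peak = (-th * 24 / (2 * math.pi)) % 24
        grid = np.arange(0, 24, 1 / 60)
        curve = 0.5 * np.cos(2 * np.pi * grid / 24) + 0.5 * np.sin(2 * np.pi * grid / 24)
        assert peak == pytest.approx(grid[np.argmax(curve)], abs=1 / 60)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False))
    def test_reconstruction_roundtrip(self, ac, as_):
        b, th = amplitude_phase(ac, as_)
        assert b >= 0 and -math.pi < th <= math.pi
        assert b * math.cos(th) == pytest.approx(ac, abs=1e-12)
        assert -b * math.sin(th) == pytest.approx(as_, abs=1e-12)


def test_wald_test_detects_strong_effect(bimodal_fit):
    stat, df, p = wald_test(bimodal_fit, ["cos12", "sin12"])
    assert df == 2 and p < 1e-6
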