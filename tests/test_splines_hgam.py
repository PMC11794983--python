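import subprocess
import warnings

import numpy as np
import pytest

from dielact.hgam import HGAMSpec, build_design, fit_hgam, hgam_aic_compare, season_structures
from dielact.occasions import aggregate_binomial, bin_detections
from dielact.sim import SimParams, simulate_detections
from dielact.splines import CyclicSplineSpec, cyclic_basis, cyclic_knots


@pytest.fixture(scope="module")
def small_occasions():
    det, eff, _ = simulate_detections(SimParams(sigma_gamma=0, sigma_tau=0.7),
                                      20, 30, 1.0, seed=7)
    return aggregate_binomial(bin_detections(det, eff, 1.0))


class TestCyclicBasis:
    def test_wrap_point_values_match(self, rng):
        spec = CyclicSplineSpec(K=12)          # knots 0..23
        X, _ = cyclic_basis(np.array([0.0, 23.0]), spec)
        for _ in range(5):
            coef = rng.standard_normal(X.shape[1])
            assert abs(X[0] @ coef - X[1] @ coef) <= 1e-10

    def test_penalty_null_space_is_constants(self):
        _, S = cyclic_basis(np.arange(24.0), CyclicSplineSpec(K=12))
        ones = np.ones(S.shape[0])
        assert np.max(np.abs(S @ ones)) <= 1e-12
        ev = np.linalg.eigvalsh(S)
        assert np.sum(ev < 1e-9 * ev.max()) == 1       # rank K-2
        assert ev.min() > -1e-9 * ev.max()             # PSD

    def test_interpolates_cosine_at_knots(self):
        t = np.arange(24.0)
        spec = CyclicSplineSpec(K=13, knots=tuple(np.linspace(0, 24, 13)))
        X, _ = cyclic_basis(t, spec)
        y = np.cos(2 * np.pi * t / 24)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        kn = np.linspace(0, 24, 13)[:-1]
        Xk, _ = cyclic_basis(kn, spec)
        assert np.max(np.abs(Xk @ coef - np.cos(2 * np.pi * kn / 24))) <= 1e-3

    def test_times_reduced_modulo_period(self):
        spec = CyclicSplineSpec(K=13, knots=tuple(np.linspace(0, 24, 13)))
        Xa, _ = cyclic_basis(np.array([3.0]), spec)
        Xb, _ = cyclic_basis(np.array([27.0]), spec)
        assert np.allclose(Xa, Xb)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            CyclicSplineSpec(K=3).resolved_knots()
        with pytest.raises(ValueError):
            CyclicSplineSpec(knots=(0.0, 1.0, 1.0, 2.0)).resolved_knots()


class TestBuildDesign:
    def test_by_factor_creates_block_per_level(self, small_occasions):
        occ = small_occasions.copy()
        occ["season"] = np.where(occ["site"] < "S011", "fall", "spring")
        spec = HGAMSpec(parametric=("season",),
                        smooths=(CyclicSplineSpec(label="s(t)", by="season"),))
        des = build_design(occ, spec)
        assert len(des.blocks) == 2
        assert des.n_lambda == 2

    def test_random_effect_smooth_identity_penalty(self, small_occasions):
        spec = HGAMSpec(smooths=(CyclicSplineSpec(label="s(site)",
                                                  is_random_effect=True),))
        des = build_design(small_occasions, spec)
        b = des.blocks[0]
        assert b.S.shape == (20, 20)
        assert np.array_equal(b.S, np.eye(20))

    def test_global_plus_by_site_column_bookkeeping(self, small_occasions):
        # 11 free knot values minus 1 centering constraint = 10 columns per
        # cyclic smooth; intercept + global + 20 site replicates + site ridge
        spec = HGAMSpec(smooths=(
            CyclicSplineSpec(label="g"),
            CyclicSplineSpec(label="bysite", by="site", share_lambda=True),
            CyclicSplineSpec(label="re", is_random_effect=True),
        ))
        des = build_design(small_occasions, spec)
        assert des.X.shape[1] == 1 + 10 + 20 * 10 + 20
        assert des.n_lambda == 3  # global, shared by-site, ridge

    def test_single_level_by_factor_rejected(self, small_occasions):
        occ = small_occasions.copy()
        occ["season"] = "spring"
        spec = HGAMSpec(smooths=(CyclicSplineSpec(label="s", by="season"),))
        with pytest.raises(ValueError, match="levels"):
            build_design(occ, spec)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            HGAMSpec(smooths=(CyclicSplineSpec(label="a"),
                              CyclicSplineSpec(label="a")))


class TestFitHGAM:
    def test_infinite_penalty_collapses_to_parametric_glm(self, small_occasions):
        import statsmodels.api as sm
        spec = HGAMSpec(smooths=(CyclicSplineSpec(label="s(time)"),))
        f = fit_hgam(small_occasions, spec, lambdas=np.array([1e12]))
        glm = sm.GLM(np.c_[small_occasions["success"], small_occasions["failure"]],
                     np.ones((len(small_occasions), 1)),
                     family=sm.families.Binomial()).fit()
        assert f.loglik == pytest.approx(glm.llf, abs=1e-4)

    def test_zero_penalty_matches_unpenalized_glm(self, small_occasions):
        import statsmodels.api as sm
        spec = HGAMSpec(smooths=(CyclicSplineSpec(label="s(time)"),))
        des = build_design(small_occasions, spec)
        f = fit_hgam(small_occasions, spec, lambdas=np.array([0.0]))
        glm = sm.GLM(np.c_[small_occasions["success"], small_occasions["failure"]],
                     des.X, family=sm.families.Binomial()).fit()
        assert f.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_reml_lambda_within_grid_bracket(self, small_occasions):
        # the REML optimum must beat a 41-point log-grid search of the same
        # criterion, up to grid resolution
        from dielact.hgam import _pirls
        spec = HGAMSpec(smooths=(CyclicSplineSpec(label="s(time)"),
                                 CyclicSplineSpec(label="s(site)",
                                                  is_random_effect=True)))
        f = fit_hgam(small_occasions, spec)
        des = f.design
        succ = small_occasions["success"].to_numpy(float)
        fail = small_occasions["failure"].to_numpy(float)

        def laml(rho):
            lam = np.exp(rho)
            S_lam = des.penalty(lam)
            beta, H, ll, _ = _pirls(des.X, S_lam, succ, fail)
            _, logdet_A = np.linalg.slogdet(H + S_lam)
            return (-ll + 0.5 * beta @ S_lam @ beta + 0.5 * logdet_A
                    - 0.5 * des.log_pdet_pen(rho))

        rho_hat = np.log([f.lambdas["s(time)"], f.lambdas["s(site)"]])
        v_hat = laml(rho_hat)
        grid = np.linspace(-8, 8, 41)
        best = min(laml(np.array([r, rho_hat[1]])) for r in grid)
        assert v_hat <= best + 1e-3

    def test_fitted_curve_is_periodic(self, small_occasions):
        f = fit_hgam(small_occasions, HGAMSpec())
        eta = f.linpred(np.array([0.0, 23.0]))
        assert abs(eta[0] - eta[1]) <= 1e-10

    def test_edf_decreases_with_lambda(self, small_occasions):
        spec = HGAMSpec(smooths=(CyclicSplineSpec(label="s(time)"),))
        edfs = [fit_hgam(small_occasions, spec,
                         lambdas=np.array([lam])).edf["s(time)"]
                for lam in (0.01, 1.0, 100.0, 1e4)]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_edf_bounded_by_basis_dimension(self, small_occasions):
        f = fit_hgam(small_occasions, HGAMSpec())
        assert 0 <= f.edf["s(time)"] <= 10
        assert 0 <= f.edf["s(site)"] <= 20

    def test_matches_mgcv_oracle(self, small_occasions, tmp_path):
        # independent reference fit of the same model in R mgcv
        f = fit_hgam(small_occasions, HGAMSpec())
        occ_path = tmp_path / "occ.csv"
        small_occasions.to_csv(occ_path, index=False)
        rcode = f'''
        suppressMessages(library(mgcv))
        d <- read.csv("{occ_path}")
        d$site <- factor(d$site)
        m <- gam(cbind(success, failure) ~ s(time, bs="cc", k=12) + s(site, bs="re"),
                 knots=list(time=c(0,23)), family=binomial, method="REML", data=d)
        nd <- data.frame(time=0:23, site=d$site[1])
        p <- predict(m, nd, type="link", exclude="s(site)", newdata.guaranteed=TRUE)
        cat(sprintf("%.10f\\n", p))
        cat(sprintf("%.10f\\n", sqrt(1/m$sp[["s(site)"]])))
        '''
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        vals = [float(x) for x in res.stdout.split()]
        mgcv_eta, mgcv_sigma = np.array(vals[:24]), vals[24]
        ours = f.linpred(np.arange(24.0))
        assert np.max(np.abs(ours - mgcv_eta)) < 1e-3
        assert f.implied_sigma_tau() == pytest.approx(mgcv_sigma, rel=1e-3)

    def test_site_ridge_sigma_consistent_with_trig_model(self, small_occasions):
        # cross-module: the ridge smoothing parameter implies a site SD that
        # agrees with the trigonometric random-intercept estimate within 5%
        from dielact.trig import TrigModelSpec, fit_trig
        hf = fit_hgam(small_occasions, HGAMSpec())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tf = fit_trig(TrigModelSpec(), small_occasions, compute_vcov=False)
        assert hf.implied_sigma_tau() == pytest.approx(tf.re_sd.iloc[0],
                                                       rel=0.05)


class TestHGAMComparison:
    def test_identical_fits_zero_delta(self, small_occasions):
        f = fit_hgam(small_occasions, HGAMSpec())
        assert hgam_aic_compare(f, f) == 0.0

    def test_different_data_rejected(self, small_occasions):
        f1 = fit_hgam(small_occasions, HGAMSpec())
        f2 = fit_hgam(small_occasions.iloc[:-24], HGAMSpec())
        with pytest.raises(ValueError):
            hgam_aic_compare(f1, f2)

    def test_global_smoother_comparison_warns(self):
        det, eff, _ = simulate_detections(
            SimParams(sigma_gamma=0.2, sigma_tau=0.7), 10, 25, 1.0, seed=8)
        occ = aggregate_binomial(bin_detections(det, eff, 1.0))
        occ["season"] = np.where(occ["site"] < "S006", "fall", "spring")
        spec1, spec2 = season_structures("season")
        f1 = fit_hgam(occ, spec1)
        f2 = fit_hgam(occ, spec2)
        with pytest.warns(UserWarning, match="global"):
            hgam_aic_compare(f1, f2)
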