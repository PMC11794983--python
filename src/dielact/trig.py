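"""Trigonometric hierarchical logistic models for diel activity.

The nonlinear two-harmonic activity model

    logit p_it = beta0 + beta1*cos(2*pi*t/24 + theta0 + gamma_i)
                       + beta2*cos(2*pi*t/12 + theta1 + gamma_i) + tau_i

is linearized by the compound-angle identities into

    logit p_it = beta0 + a1*cos(2*pi*t/24) + a2*sin(2*pi*t/24)
                       + a3*cos(2*pi*t/12) + a4*sin(2*pi*t/12) + tau_i

with a1 = beta1*cos(theta0), a2 = -beta1*sin(theta0) (and likewise a3, a4 for
the second harmonic); site-level phase variability appears as random slopes on
the cos/sin columns. The marginal likelihood integrates the site random
effects out numerically by adaptive Gauss-Hermite quadrature (AGH) centred and
scaled at each site's posterior mode; a single node is the Laplace
approximation. Model comparison uses marginal AIC and likelihood-ratio tests;
``amplitude_phase`` inverts the linearization back to amplitude/phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit, logsumexp
from scipy.stats import chi2

__all__ = [
    "TrigModelSpec", "TrigFit", "harmonic_design", "nll_integrated",
    "fit_trig", "aic", "compare_aic", "lrt", "amplitude_phase", "wald_test",
]

_RANDOM_STRUCTURES = (
    "intercept_only",
    "intercept_plus_diagonal_slopes",
    "intercept_plus_correlated_slopes",
)


@dataclass(frozen=True)
class TrigModelSpec:
    """Specification of a trigonometric hierarchical logistic model.

    ``periods=[]`` is the cathemeral null (no diel variation), ``[24]``
    unimodal, ``[24, 12]`` bimodal. ``quad_points`` is the number of
    Gauss-Hermite nodes per random-effect dimension (odd; 1 = Laplace).
    A product grid is used up to 3 random-effect dimensions, Laplace beyond.
    """

    periods: tuple = (24.0, 12.0)
    covariates: tuple = ()
    interactions: bool = False
    random_structure: str = "intercept_only"
    quad_points: int = 11

    def __post_init__(self):
        per = tuple(float(p) for p in self.periods)
        if any(p <= 0 for p in per):
            raise ValueError("harmonic periods must be positive")
        if len(set(per)) != len(per):
            raise ValueError("harmonic periods must be distinct")
        object.__setattr__(self, "periods", tuple(sorted(per, reverse=True)))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.random_structure not in _RANDOM_STRUCTURES:
            raise ValueError(f"unknown random_structure {self.random_structure!r}")
        if self.quad_points < 1 or self.quad_points % 2 == 0:
            raise ValueError("quad_points must be odd and >= 1")

    @property
    def n_random(self) -> int:
        if self.random_structure == "intercept_only":
            return 1
        return 1 + 2 * len(self.periods)


def harmonic_design(times, periods, covariates: pd.DataFrame | None = None,
                    interactions: bool = False,
                    categories: dict | None = None) -> pd.DataFrame:
    """Fixed-effects design matrix: intercept, cos/sin per period, covariates.

    Harmonic columns are ordered cos-then-sin per period, periods descending,
    so coefficient indices match the a1..a4 convention. Categorical covariates
    are dummy-coded against their first level; ``categories`` pins the level
    sets (needed so prediction designs align with training designs).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(t >= 24):
        raise ValueError("times must lie in [0, 24)")
    per = [float(p) for p in periods]
    if any(p <= 0 for p in per):
        raise ValueError("periods must be positive")
    if len(set(per)) != len(per):
        raise ValueError("duplicate periods")
    per = sorted(per, reverse=True)

    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones_like(t)}
    harm_names = []
    for w in per:
        cname, sname = f"cos{w:g}", f"sin{w:g}"
        cols[cname] = np.cos(2 * np.pi * t / w)
        cols[sname] = np.sin(2 * np.pi * t / w)
        harm_names += [cname, sname]

    cov_cols: dict[str, np.ndarray] = {}
    if covariates is not None and len(covariates.columns):
        for c in covariates.columns:
            v = covariates[c]
            if pd.api.types.is_numeric_dtype(v) and not isinstance(v.dtype, pd.CategoricalDtype):
                cov_cols[c] = v.to_numpy(dtype=float)
            else:
                levels = (categories or {}).get(c)
                cat = pd.Categorical(v, categories=levels)
                if cat.isna().any() and not pd.isna(v).any():
                    raise ValueError(f"covariate {c!r} has levels outside {list(cat.categories)}")
                for lev in cat.categories[1:]:
                    cov_cols[f"{c}[{lev}]"] = (cat == lev).astype(float)
    cols.update(cov_cols)
    if interactions:
        for cn, cv in cov_cols.items():
            for hn in harm_names:
                cols[f"{cn}:{hn}"] = cv * cols[hn]
    return pd.DataFrame(cols)


def _random_design(times, spec: TrigModelSpec) -> pd.DataFrame:
    t = np.asarray(times, dtype=float)
    cols = {"(Intercept)": np.ones_like(t)}
    if spec.random_structure != "intercept_only":
        for w in spec.periods:
            cols[f"cos{w:g}"] = np.cos(2 * np.pi * t / w)
            cols[f"sin{w:g}"] = np.sin(2 * np.pi * t / w)
    return pd.DataFrame(cols)


class _ModelData:
    """Prepared matrices for likelihood evaluation."""

    def __init__(self, spec: TrigModelSpec, data: pd.DataFrame):
        req = {"site", "time", "success", "failure"}
        missing = req - set(data.columns)
        if missing:
            raise ValueError(f"occasion table lacks columns: {sorted(missing)}")
        if len(data) == 0:
            raise ValueError("occasion table is empty")
        data = data.reset_index(drop=True)
        self.spec = spec
        self.categories = {}
        cov = None
        if spec.covariates:
            cov = data[list(spec.covariates)]
            for c in spec.covariates:
                if not pd.api.types.is_numeric_dtype(cov[c]):
                    self.categories[c] = list(pd.unique(cov[c].astype(str).sort_values()))
                    cov = cov.assign(**{c: cov[c].astype(str)})
        Xdf = harmonic_design(data["time"], spec.periods, cov,
                              spec.interactions, self.categories)
        self.xnames = list(Xdf.columns)
        self.X = Xdf.to_numpy(dtype=float)
        Zdf = _random_design(data["time"], spec)
        self.znames = list(Zdf.columns)
        self.Z = Zdf.to_numpy(dtype=float)
        self.succ = data["success"].to_numpy(dtype=float)
        self.fail = data["failure"].to_numpy(dtype=float)
        if (self.succ < 0).any() or (self.fail < 0).any():
            raise ValueError("success/failure counts must be >= 0")
        self.ntr = self.succ + self.fail
        codes, uniques = pd.factorize(data["site"], sort=True)
        self.site_codes = codes
        self.sites = list(uniques)
        self.n_sites = len(uniques)
        self.const = float(np.sum(gammaln(self.ntr + 1) - gammaln(self.succ + 1)
                                  - gammaln(self.fail + 1)))
        self.fingerprint = int(pd.util.hash_pandas_object(
            data[sorted(data.columns.intersection(
                ["site", "time", "success", "failure", *spec.covariates]))]
        ).sum())

    # --- parameter packing -------------------------------------------------
    @property
    def p(self):
        return self.X.shape[1]

    @property
    def q(self):
        return self.Z.shape[1]

    @property
    def n_varpar(self):
        q = self.q
        if self.spec.random_structure == "intercept_plus_correlated_slopes":
            return q + q * (q - 1) // 2
        return q

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite parameter vector")
        p, q = self.p, self.q
        beta = theta[:p]
        if self.spec.random_structure == "intercept_plus_correlated_slopes":
            L = np.zeros((q, q))
            L[np.diag_indices(q)] = np.exp(np.clip(theta[p:p + q], -30, 30))
            if q > 1:
                L[np.tril_indices(q, -1)] = theta[p + q:]
        else:
            L = np.diag(np.exp(np.clip(theta[p:p + q], -30, 30)))
        return beta, L

    def param_names(self):
        names = list(self.xnames)
        if self.spec.random_structure == "intercept_plus_correlated_slopes":
            names += [f"log_sd({z})" for z in self.znames]
            q = self.q
            ii, jj = np.tril_indices(q, -1)
            names += [f"chol({self.znames[i]},{self.znames[j]})"
                      for i, j in zip(ii, jj)]
        else:
            names += [f"log_sd({z})" for z in self.znames]
        return names


# --- integrated likelihood -------------------------------------------------

_BARRIER = 1e10


def _site_loglik_terms(md, eta):
    """Per-row binomial log-likelihood kernel (no combinatorial constant)."""
    return md.succ * log_expit(eta) + md.fail * log_expit(-eta)


def _nll_q1(md, beta, sd, quad_points):
    """Vectorized integrated NLL for a single random intercept."""
    eta0 = md.X @ beta
    s_codes = md.site_codes
    ns = md.n_sites
    # warm-start the posterior modes: successive optimizer evaluations move
    # theta very little, so the previous modes are excellent initial values
    u = getattr(md, "_u_cache", None)
    u = np.zeros(ns) if u is None or u.shape != (ns,) else u.copy()

    def site_g(u):
        eta = eta0 + sd * u[s_codes]
        ll = np.bincount(s_codes, weights=_site_loglik_terms(md, eta), minlength=ns)
        return ll - 0.5 * u * u

    g = site_g(u)
    for _ in range(100):
        eta = eta0 + sd * u[s_codes]
        p = expit(eta)
        grad = sd * np.bincount(s_codes, weights=md.succ - md.ntr * p,
                                minlength=ns) - u
        w = md.ntr * p * (1 - p)
        h = sd * sd * np.bincount(s_codes, weights=w, minlength=ns) + 1.0
        step = grad / h
        # damped Newton: halve where the site objective would decrease
        for _ in range(40):
            g_new = site_g(u + step)
            bad = g_new < g - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        u = u + step
        g = site_g(u)
        if np.max(np.abs(grad)) < 1e-9:
            break

    md._u_cache = u
    eta = eta0 + sd * u[s_codes]
    p = expit(eta)
    w = md.ntr * p * (1 - p)
    h = sd * sd * np.bincount(s_codes, weights=w, minlength=ns) + 1.0
    # marginal likelihood per site: (2*pi)^{-1/2} * int exp(g(u)) du
    if quad_points == 1:
        log_int = g - 0.5 * np.log(h)
    else:
        x, wq = np.polynomial.hermite.hermgauss(quad_points)
        sigma = 1.0 / np.sqrt(h)
        terms = np.empty((quad_points, ns))
        for k in range(quad_points):
            uk = u + math.sqrt(2.0) * sigma * x[k]
            terms[k] = math.log(wq[k]) + x[k] ** 2 + site_g(uk)
        log_int = (0.5 * math.log(2.0) - 0.5 * math.log(2 * math.pi)
                   + np.log(sigma) + logsumexp(terms, axis=0))
    return -(md.const + float(np.sum(log_int)))


def _nll_general(md, beta, L, quad_points):
    """Per-site loop for multi-dimensional random effects (AGH <=3 dims)."""
    eta0 = md.X @ beta
    q = md.q
    use_agq = quad_points > 1 and q <= 3
    if use_agq:
        x1, w1 = np.polynomial.hermite.hermgauss(quad_points)
        grids = np.meshgrid(*([x1] * q), indexing="ij")
        nodes = np.stack([g.ravel() for g in grids], axis=1)  # (K^q, q)
        wgrids = np.meshgrid(*([w1] * q), indexing="ij")
        logw = np.sum([np.log(w.ravel()) for w in wgrids], axis=0)
        sq = np.sum(nodes ** 2, axis=1)
    ucache = getattr(md, "_uq_cache", None)
    if ucache is None or ucache.shape != (md.n_sites, q):
        ucache = np.zeros((md.n_sites, q))
    total = 0.0
    for i in range(md.n_sites):
        rows = md.site_codes == i
        Zi = md.Z[rows] @ L  # (ni, q)
        e0 = eta0[rows]
        s, f, n = md.succ[rows], md.fail[rows], md.ntr[rows]

        def g_fun(u):
            eta = e0 + Zi @ u
            return float(np.sum(s * log_expit(eta) + f * log_expit(-eta))
                         - 0.5 * u @ u)

        u = ucache[i].copy()
        g = g_fun(u)
        for _ in range(100):
            eta = e0 + Zi @ u
            p = expit(eta)
            grad = Zi.T @ (s - n * p) - u
            W = n * p * (1 - p)
            H = Zi.T @ (Zi * W[:, None]) + np.eye(q)
            step = np.linalg.solve(H, grad)
            alpha = 1.0
            for _ in range(40):
                g_new = g_fun(u + alpha * step)
                if g_new >= g - 1e-12:
                    break
                alpha *= 0.5
            u = u + alpha * step
            g = g_fun(u)
            if np.max(np.abs(grad)) < 1e-9:
                break
        ucache[i] = u
        eta = e0 + Zi @ u
        p = expit(eta)
        W = n * p * (1 - p)
        H = Zi.T @ (Zi * W[:, None]) + np.eye(q)
        Cl = np.linalg.cholesky(H)
        logdet_half = float(np.sum(np.log(np.diag(Cl))))
        # marginal likelihood per site: (2*pi)^{-q/2} * int exp(g(u)) du
        if not use_agq:
            total += g - logdet_half
        else:
            # u_k = u_hat + sqrt(2) * H^{-1/2} x_k, H^{-1/2} via Cholesky
            Y = np.linalg.solve(Cl.T, nodes.T).T  # (K^q, q)
            U = u[None, :] + math.sqrt(2.0) * Y
            eta_all = e0[:, None] + Zi @ U.T      # (ni, K^q)
            terms = (np.sum(s[:, None] * log_expit(eta_all)
                            + f[:, None] * log_expit(-eta_all), axis=0)
                     - 0.5 * np.sum(U * U, axis=1))
            total += (0.5 * q * math.log(2.0) - 0.5 * q * math.log(2 * math.pi)
                      - logdet_half + logsumexp(logw + sq + terms))
    md._uq_cache = ucache
    return -(md.const + total)


def _nll(md, theta):
    try:
        beta, L = md.unpack(theta)
    except ValueError:
        return _BARRIER
    sds = np.diag(L)
    if np.any(sds > 1e6) or not np.all(np.isfinite(L)):
        return _BARRIER
    if md.q == 1:
        val = _nll_q1(md, beta, float(L[0, 0]), md.spec.quad_points)
    else:
        val = _nll_general(md, beta, L, md.spec.quad_points)
    if not np.isfinite(val):
        return _BARRIER
    return val


def nll_integrated(spec: TrigModelSpec, theta, data: pd.DataFrame) -> float:
    """Integrated (marginal) negative log-likelihood at packed parameters.

    ``theta`` packs fixed effects first, then random-effect SDs on the log
    scale (plus free Cholesky off-diagonals for the correlated structure).
    """
    md = _ModelData(spec, data)
    theta = np.asarray(theta, dtype=float)
    expected = md.p + md.n_varpar
    if theta.shape != (expected,):
        raise ValueError(f"theta must have length {expected}")
    return _nll(md, theta)


# --- fitting ----------------------------------------------------------------

@dataclass
class TrigFit:
    """Maximum-likelihood fit of a trigonometric hierarchical model."""

    spec: TrigModelSpec
    alpha: pd.Series                 # fixed effects
    re_sd: pd.Series                 # random-effect SDs (natural scale)
    re_corr: pd.DataFrame | None
    loglik: float
    df: int
    vcov: pd.DataFrame               # packed scale: beta, log_sd (, chol)
    converged: bool
    grad_norm: float
    blups: pd.DataFrame              # per-site posterior modes (natural scale)
    n_sites: int
    n_obs: int
    fingerprint: int
    theta: np.ndarray = field(repr=False, default=None)
    categories: dict = field(default_factory=dict, repr=False)

    # --- prediction hooks used by the curves module -----------------------
    def design(self, times, covariates: dict | None = None) -> pd.DataFrame:
        cov = None
        if self.spec.covariates:
            if covariates is None:
                raise ValueError("fit includes covariates; pass their values")
            t = np.asarray(times, dtype=float)
            cov = pd.DataFrame({c: np.repeat(covariates[c], t.size)
                                for c in self.spec.covariates})
        Xdf = harmonic_design(times, self.spec.periods, cov,
                              self.spec.interactions, self.categories)
        return Xdf.reindex(columns=self.alpha.index, fill_value=0.0)

    def linpred(self, times, covariates: dict | None = None,
                site: str | None = None) -> np.ndarray:
        X = self.design(times, covariates).to_numpy()
        eta = X @ self.alpha.to_numpy()
        if site is not None:
            if site not in self.blups.index:
                raise KeyError(f"unknown site {site!r}")
            b = self.blups.loc[site]
            Z = _random_design(times, self.spec).to_numpy()
            eta = eta + Z @ b.to_numpy()
        return eta

    def linpred_se(self, times, covariates: dict | None = None) -> np.ndarray:
        X = self.design(times, covariates).to_numpy()
        Vb = self.vcov.iloc[:len(self.alpha), :len(self.alpha)].to_numpy()
        var = np.einsum("ij,jk,ik->i", X, Vb, X)
        return np.sqrt(np.maximum(var, 0.0))

    def re_scale(self, times) -> np.ndarray:
        """SD of the site-level contribution z(t)'b at each time."""
        Z = _random_design(times, self.spec).to_numpy()
        D = self.re_cov()
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, D, Z), 0.0))

    def re_cov(self) -> np.ndarray:
        sd = self.re_sd.to_numpy()
        if self.re_corr is not None:
            R = self.re_corr.to_numpy()
            return np.outer(sd, sd) * R
        return np.diag(sd ** 2)

    @property
    def fixed_vcov(self) -> pd.DataFrame:
        k = len(self.alpha)
        return self.vcov.iloc[:k, :k]


def _num_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def fit_trig(spec: TrigModelSpec, data: pd.DataFrame,
             start: np.ndarray | None = None,
             compute_vcov: bool = True) -> TrigFit:
    """Fit by quasi-Newton maximization of the AGH-integrated likelihood.

    Starting values: fixed effects from the no-random-effect binomial GLM,
    all random-effect SDs at 0.3.
    """
    md = _ModelData(spec, data)
    if md.n_sites < 2:
        raise ValueError("random-effect estimation needs >= 2 sites")
    if md.n_sites < 10:
        warnings.warn(f"only {md.n_sites} sites; hierarchical variance "
                      "estimates are unreliable below ~10 clusters")

    if start is None:
        import statsmodels.api as sm
        try:
            glm = sm.GLM(np.c_[md.succ, md.fail], md.X,
                         family=sm.families.Binomial()).fit()
            beta0 = np.asarray(glm.params, dtype=float)
        except Exception:
            beta0 = np.zeros(md.p)
        start = np.concatenate([
            beta0,
            np.full(md.q, math.log(0.3)),
            np.zeros(md.n_varpar - md.q),
        ])
    start = np.asarray(start, dtype=float)

    res = minimize(lambda th: _nll(md, th), start, method="BFGS",
                   jac="3-point", options={"gtol": 1e-5, "maxiter": 1000})
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm <= 1e-4)
    if not converged:
        warnings.warn(f"optimizer did not converge (grad sup-norm {grad_norm:.2e})")

    beta, L = md.unpack(theta)
    D = L @ L.T
    sd = np.sqrt(np.diag(D))
    names = md.param_names()
    if compute_vcov:
        H = _num_hessian(lambda th: _nll(md, th), theta)
        try:
            V = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            V = np.full((len(theta), len(theta)), np.nan)
    else:
        V = np.full((len(theta), len(theta)), np.nan)
    vcov = pd.DataFrame(V, index=names, columns=names)

    re_corr = None
    if spec.random_structure == "intercept_plus_correlated_slopes" and md.q > 1:
        with np.errstate(invalid="ignore"):
            R = D / np.outer(sd, sd)
        re_corr = pd.DataFrame(R, index=md.znames, columns=md.znames)

    blups = _posterior_modes(md, beta, L)
    return TrigFit(
        spec=spec,
        alpha=pd.Series(beta, index=md.xnames),
        re_sd=pd.Series(sd, index=md.znames),
        re_corr=re_corr,
        loglik=-float(res.fun),
        df=md.p + md.n_varpar,
        vcov=vcov,
        converged=converged,
        grad_norm=grad_norm,
        blups=blups,
        n_sites=md.n_sites,
        n_obs=len(md.succ),
        fingerprint=md.fingerprint,
        theta=theta,
        categories=md.categories,
    )


def _posterior_modes(md, beta, L) -> pd.DataFrame:
    eta0 = md.X @ beta
    q = md.q
    out = np.zeros((md.n_sites, q))
    for i in range(md.n_sites):
        rows = md.site_codes == i
        Zi = md.Z[rows] @ L
        e0 = eta0[rows]
        s, n = md.succ[rows], md.ntr[rows]
        u = np.zeros(q)
        for _ in range(100):
            p = expit(e0 + Zi @ u)
            grad = Zi.T @ (s - n * p) - u
            H = Zi.T @ (Zi * (n * p * (1 - p))[:, None]) + np.eye(q)
            step = np.linalg.solve(H, grad)
            u = u + step
            if np.max(np.abs(grad)) < 1e-9:
                break
        out[i] = L @ u
    return pd.DataFrame(out, index=pd.Index(md.sites, name="site"),
                        columns=md.znames)


# --- model comparison -------------------------------------------------------

def aic(fit: TrigFit) -> float:
    """Marginal AIC = -2*loglik + 2*df (df = fixed + variance parameters)."""
    return -2.0 * fit.loglik + 2.0 * fit.df


def compare_aic(fits: dict) -> pd.DataFrame:
    """AIC table sorted ascending, with deltaAIC relative to the best model."""
    fps = {f.fingerprint for f in fits.values()}
    if len(fps) > 1:
        raise ValueError("fits were not computed on the same data")
    for name, f in fits.items():
        if not f.converged:
            warnings.warn(f"model {name!r} did not converge; AIC may be unreliable")
    tab = pd.DataFrame({
        "df": {k: f.df for k, f in fits.items()},
        "AIC": {k: aic(f) for k, f in fits.items()},
    }).sort_values("AIC", kind="stable")
    tab["deltaAIC"] = tab["AIC"] - tab["AIC"].min()
    return tab


def lrt(nested: TrigFit, full: TrigFit):
    """Likelihood-ratio test of a nested model against a fuller one."""
    if nested.fingerprint != full.fingerprint:
        raise ValueError("fits were not computed on the same data")
    if nested.df >= full.df:
        raise ValueError("nested model must have fewer parameters")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6:
        raise ValueError("nesting violated: full model has lower likelihood")
    stat = max(stat, 0.0)
    ddf = full.df - nested.df
    return stat, ddf, float(chi2.sf(stat, ddf))


def wald_test(fit: TrigFit, names: list[str]):
    """Joint Wald chi-square test that the named fixed effects are all zero."""
    idx = [list(fit.alpha.index).index(n) for n in names]
    b = fit.alpha.to_numpy()[idx]
    V = fit.fixed_vcov.to_numpy()[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    return stat, len(idx), float(chi2.sf(stat, len(idx)))


def amplitude_phase(a_cos: float, a_sin: float):
    """Invert the compound-angle linearization back to (amplitude, phase).

    Returns (beta, theta) with beta >= 0 and theta in (-pi, pi] such that
    a_cos = beta*cos(theta) and a_sin = -beta*sin(theta). The peak of
    beta*cos(2*pi*t/omega + theta) falls at t = -theta*omega/(2*pi) mod omega.
    """
    beta = math.hypot(a_cos, a_sin)
    if beta == 0.0:
        return 0.0, 0.0
    theta = math.atan2(-a_sin, a_cos)
    if theta <= -math.pi:
        theta = math.pi
    return beta, theta
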