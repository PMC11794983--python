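"""Hierarchical GAMs built from cyclic cubic spline smoothers.

Two structures are the workhorses for diel-activity data with a covariate
such as season:

1. random-intercept-only: ``Season + s(time, by=Season) + s(site, ridge)`` —
   a per-season cyclic smooth plus a site random intercept expressed as a
   ridge-penalized indicator smoother (penalty lambda maps to an implied
   random-intercept variance 1/lambda);
2. random-curve: adds a global cyclic smoother and a by-site cyclic smoother
   so site-specific activity curves are shrunk towards a common shape.

Fitting alternates penalized IRLS for the coefficients given the smoothing
parameters with quasi-Newton optimization of the Laplace-approximate REML
criterion over log-smoothing-parameters, so the data determine the degree of
smoothing. Effective degrees of freedom are traces of the influence matrix;
AIC is -2*loglik + 2*edf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit

from .splines import CyclicSplineSpec, cyclic_basis

__all__ = ["HGAMSpec", "HGAMFit", "build_design", "fit_hgam",
           "hgam_aic_compare", "season_structures"]


@dataclass(frozen=True)
class HGAMSpec:
    """Parametric terms plus a list of cyclic/ridge smooth terms."""

    parametric: tuple = ()
    smooths: tuple = (CyclicSplineSpec(label="s(time)"),
                      CyclicSplineSpec(label="s(site)", is_random_effect=True))
    time_col: str = "time"
    site_col: str = "site"

    def __post_init__(self):
        labels = [s.label for s in self.smooths]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate smooth labels")


class _Block:
    """One penalized block of the design: columns, penalty, lambda index."""

    def __init__(self, label, sl, S, lam_index, kind, meta):
        self.label = label
        self.sl = sl                # slice into the full column space
        self.S = S
        self.lam_index = lam_index
        self.kind = kind            # 'cyclic' | 're'
        self.meta = meta            # prediction info


class _Design:
    def __init__(self, X, colnames, blocks, n_lambda, para_info, spec):
        self.X = X
        self.colnames = colnames
        self.blocks = blocks
        self.n_lambda = n_lambda
        self.para_info = para_info
        self.spec = spec

    def penalty(self, lam):
        S = np.zeros((self.X.shape[1], self.X.shape[1]))
        for b in self.blocks:
            S[b.sl, b.sl] += lam[b.lam_index] * b.S
        return S

    def log_pdet_pen(self, rho):
        """log of the product of positive eigenvalues of the total penalty."""
        tot = 0.0
        for b in self.blocks:
            tot += b.S.shape[0] * rho[b.lam_index] + b.meta["logdet_S"]
        return tot


def _constraint_null(c):
    """Orthonormal basis of the null space of the row vector c."""
    c = np.asarray(c, dtype=float)[None, :]
    _, _, vh = np.linalg.svd(c, full_matrices=True)
    return vh[1:].T


def _encode_parametric(data, names, categories=None):
    cols, catinfo = {}, {}
    for c in names:
        v = data[c]
        if pd.api.types.is_numeric_dtype(v) and not isinstance(v.dtype, pd.CategoricalDtype):
            cols[c] = v.to_numpy(dtype=float)
        else:
            levels = (categories or {}).get(c)
            cat = pd.Categorical(v.astype(str), categories=levels)
            catinfo[c] = list(cat.categories)
            for lev in cat.categories[1:]:
                cols[f"{c}[{lev}]"] = (cat == lev).astype(float)
    return cols, catinfo


def build_design(data: pd.DataFrame, spec: HGAMSpec,
                 categories: dict | None = None) -> "_Design":
    """Assemble the block design matrix and block-diagonal penalty list.

    Cyclic smooths get a sum-to-zero (centering) constraint so they are
    identifiable next to the intercept; by-factor smooths replicate the
    centred basis per level with zeros off-level (one penalty block per
    level, or one shared smoothing parameter with ``share_lambda``); the
    random-effect smoother contributes one indicator column per site with an
    identity penalty.
    """
    n = len(data)
    cols = {"(Intercept)": np.ones(n)}
    pcols, catinfo = _encode_parametric(data, spec.parametric, categories)
    cols.update(pcols)
    X_parts = [np.column_stack(list(cols.values()))]
    colnames = list(cols.keys())
    blocks = []
    lam_counter = 0
    t = data[spec.time_col].to_numpy(dtype=float)

    for sm in spec.smooths:
        if sm.is_random_effect:
            codes, levels = pd.factorize(data[spec.site_col], sort=True)
            Xs = np.zeros((n, len(levels)))
            Xs[np.arange(n), codes] = 1.0
            S = np.eye(len(levels))
            sl = slice(len(colnames), len(colnames) + len(levels))
            blocks.append(_Block(sm.label, sl, S, lam_counter, "re",
                                 {"levels": list(levels), "logdet_S": 0.0}))
            lam_counter += 1
            X_parts.append(Xs)
            colnames += [f"{sm.label}[{lv}]" for lv in levels]
            continue

        Xraw, Sraw = cyclic_basis(t, sm)
        Z = _constraint_null(Xraw.sum(axis=0))
        Xc = Xraw @ Z
        Sc = Z.T @ Sraw @ Z
        Sc = 0.5 * (Sc + Sc.T)
        ev = np.linalg.eigvalsh(Sc)
        logdet_S = float(np.sum(np.log(ev[ev > 1e-10 * ev.max()])))
        meta_common = {"knots": sm.resolved_knots(), "Z": Z, "spec": sm,
                       "logdet_S": logdet_S}
        if sm.by is None:
            sl = slice(len(colnames), len(colnames) + Xc.shape[1])
            blocks.append(_Block(sm.label, sl, Sc, lam_counter, "cyclic",
                                 dict(meta_common, by_level=None)))
            lam_counter += 1
            X_parts.append(Xc)
            colnames += [f"{sm.label}.{j}" for j in range(Xc.shape[1])]
        else:
            byv = data[sm.by].astype(str)
            levels = sorted(byv.unique())
            if len(levels) < 2:
                raise ValueError(f"by-factor {sm.by!r} needs >= 2 levels")
            shared = lam_counter if sm.share_lambda else None
            for lev in levels:
                mask = (byv == lev).to_numpy(dtype=float)
                Xl = Xc * mask[:, None]
                sl = slice(len(colnames), len(colnames) + Xl.shape[1])
                li = shared if shared is not None else lam_counter
                blocks.append(_Block(f"{sm.label}:{sm.by}={lev}", sl, Sc, li,
                                     "cyclic", dict(meta_common, by_level=(sm.by, lev))))
                if shared is None:
                    lam_counter += 1
                X_parts.append(Xl)
                colnames += [f"{sm.label}:{sm.by}={lev}.{j}"
                             for j in range(Xl.shape[1])]
            if shared is not None:
                lam_counter += 1

    X = np.column_stack(X_parts) if len(X_parts) > 1 else X_parts[0]
    return _Design(X, colnames, blocks, lam_counter,
                   {"names": list(spec.parametric), "categories": catinfo},
                   spec)


# --- fitting -----------------------------------------------------------------

def _pirls(X, S_lam, succ, fail, max_iter=200, tol=1e-10):
    n_tr = succ + fail
    eta = np.log((succ + 0.5) / (fail + 0.5))
    beta = None
    pdev = np.inf

    def penalized_dev(b):
        e = X @ b
        ll = float(np.sum(succ * log_expit(e) + fail * log_expit(-e)))
        return -2.0 * ll + float(b @ S_lam @ b), ll

    for it in range(max_iter):
        mu = expit(eta)
        w = np.maximum(n_tr * mu * (1 - mu), 1e-10)
        z = eta + (succ - n_tr * mu) / w
        A = X.T @ (X * w[:, None]) + S_lam
        try:
            cf = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            raise RuntimeError("IRLS normal equations not positive definite")
        beta_new = cho_solve(cf, X.T @ (w * z))
        pdev_new, ll = penalized_dev(beta_new)
        halv = 0
        while beta is not None and pdev_new > pdev + 1e-9 and halv < 30:
            beta_new = 0.5 * (beta_new + beta)
            pdev_new, ll = penalized_dev(beta_new)
            halv += 1
        converged_step = beta is not None and abs(pdev - pdev_new) < tol * (abs(pdev_new) + 1)
        beta, pdev = beta_new, pdev_new
        eta = X @ beta
        if converged_step:
            break
    else:
        warnings.warn("penalized IRLS hit the iteration cap")
    mu = expit(eta)
    w = np.maximum(n_tr * mu * (1 - mu), 1e-10)
    H = X.T @ (X * w[:, None])
    return beta, H, ll, pdev


@dataclass
class HGAMFit:
    """Penalized-likelihood fit of a cyclic-spline hierarchical GAM.

    ``vcov`` is the Bayesian posterior covariance (X'WX + S_lambda)^{-1}.
    """

    spec: HGAMSpec
    coef: pd.Series
    lambdas: dict
    edf: dict
    edf_total: float
    loglik: float
    penalized_loglik: float
    vcov: pd.DataFrame
    converged: bool
    n_obs: int
    fingerprint: int
    design: "_Design" = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.edf_total

    def implied_sigma_tau(self) -> float:
        """Random-intercept SD implied by the site ridge smoother's lambda."""
        for b in self.design.blocks:
            if b.kind == "re":
                return 1.0 / math.sqrt(self.lambdas[b.label])
        raise ValueError("fit has no random-effect smoother")

    # --- prediction --------------------------------------------------------
    def _prediction_matrix(self, times, covariates=None, site=None):
        times = np.asarray(times, dtype=float)
        n = times.size
        cols = {"(Intercept)": np.ones(n)}
        covariates = covariates or {}
        pdata = pd.DataFrame({c: np.repeat(covariates[c], n)
                              for c in self.design.para_info["names"]})
        pcols, _ = _encode_parametric(pdata, self.design.para_info["names"],
                                      self.design.para_info["categories"])
        cols.update(pcols)
        X = np.zeros((n, len(self.coef)))
        X[:, 0] = 1.0
        names = list(self.coef.index)
        for cn, cv in pcols.items():
            X[:, names.index(cn)] = cv
        for b in self.design.blocks:
            if b.kind == "re":
                if site is not None:
                    levels = b.meta["levels"]
                    if site not in levels:
                        raise KeyError(f"unknown site {site!r}")
                    X[:, b.sl.start + levels.index(site)] = 1.0
                continue
            by_level = b.meta["by_level"]
            if by_level is not None:
                by_name, lev = by_level
                if by_name == self.design.spec.site_col:
                    if site is None or str(site) != lev:
                        continue
                elif str(covariates.get(by_name)) != lev:
                    continue
            Xraw, _ = cyclic_basis(times, b.meta["spec"])
            X[:, b.sl] = Xraw @ b.meta["Z"]
        return X

    def linpred(self, times, covariates: dict | None = None,
                site: str | None = None) -> np.ndarray:
        X = self._prediction_matrix(times, covariates, site)
        return X @ self.coef.to_numpy()

    def linpred_se(self, times, covariates: dict | None = None,
                   site: str | None = None) -> np.ndarray:
        X = self._prediction_matrix(times, covariates, site)
        V = self.vcov.to_numpy()
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, V, X), 0.0))

    def re_scale(self, times) -> np.ndarray:
        """SD of the site random intercept, constant over the day."""
        return np.full(np.asarray(times, dtype=float).size,
                       self.implied_sigma_tau())

    def re_cov(self) -> np.ndarray:
        return np.array([[self.implied_sigma_tau() ** 2]])


def fit_hgam(data: pd.DataFrame, spec: HGAMSpec,
             lambdas: np.ndarray | None = None,
             design: "_Design" = None) -> HGAMFit:
    """Fit by penalized IRLS with Laplace-REML-selected smoothing parameters.

    Pass ``lambdas`` to skip the outer REML optimization and fit at fixed
    smoothing parameters (0 = unpenalized, large = collapse to parametric).
    """
    for c in ("success", "failure"):
        if c not in data.columns:
            raise ValueError(f"occasion table lacks column {c!r}")
    data = data.loc[(data["success"] + data["failure"]) > 0].reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no occasions with positive trials")
    des = design if design is not None else build_design(data, spec)
    succ = data["success"].to_numpy(dtype=float)
    fail = data["failure"].to_numpy(dtype=float)
    const = float(np.sum(gammaln(succ + fail + 1) - gammaln(succ + 1)
                         - gammaln(fail + 1)))
    fingerprint = int(pd.util.hash_pandas_object(
        data[sorted(data.columns)].astype(str)).sum())

    converged = True
    if lambdas is None:
        def laml(rho):
            lam = np.exp(np.clip(rho, -30, 30))
            S_lam = des.penalty(lam)
            try:
                beta, H, ll, _ = _pirls(des.X, S_lam, succ, fail)
            except RuntimeError:
                return 1e10
            A = H + S_lam
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e10
            pen = float(beta @ S_lam @ beta)
            return -ll + 0.5 * pen + 0.5 * logdet_A - 0.5 * des.log_pdet_pen(rho)

        res = minimize(laml, np.zeros(des.n_lambda), method="L-BFGS-B",
                       bounds=[(-18.0, 18.0)] * des.n_lambda,
                       options={"maxiter": 200})
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"REML optimization did not converge: {res.message}")
        lam = np.exp(res.x)
    else:
        lam = np.asarray(lambdas, dtype=float)
        if lam.shape != (des.n_lambda,):
            raise ValueError(f"expected {des.n_lambda} smoothing parameters")

    S_lam = des.penalty(lam)
    if lambdas is not None and np.all(lam == 0):
        # unpenalized: plain IRLS (normal equations may be merely PSD)
        beta, H, ll, pdev = _pirls(des.X, S_lam + 1e-10 * np.eye(des.X.shape[1]),
                                   succ, fail)
        S_lam = np.zeros_like(S_lam)
    else:
        beta, H, ll, pdev = _pirls(des.X, S_lam, succ, fail)
    A = H + S_lam + 1e-12 * np.eye(des.X.shape[1])
    Ainv = np.linalg.inv(A)
    F_diag = np.einsum("ij,ji->i", Ainv, H)

    edf = {}
    n_para = des.blocks[0].sl.start if des.blocks else des.X.shape[1]
    edf["parametric"] = float(np.sum(F_diag[:n_para]))
    lam_map = {}
    for b in des.blocks:
        edf[b.label] = float(np.sum(F_diag[b.sl]))
        lam_map[b.label] = float(lam[b.lam_index])
    edf_total = float(np.sum(F_diag))

    coef = pd.Series(beta, index=des.colnames)
    vcov = pd.DataFrame(Ainv, index=des.colnames, columns=des.colnames)
    loglik = ll + const
    return HGAMFit(
        spec=spec, coef=coef, lambdas=lam_map, edf=edf, edf_total=edf_total,
        loglik=loglik, penalized_loglik=loglik - 0.5 * float(beta @ S_lam @ beta),
        vcov=vcov, converged=converged, n_obs=len(succ),
        fingerprint=fingerprint, design=des,
    )


def _has_global(spec: HGAMSpec) -> bool:
    has_by_site = any(s.by == spec.site_col for s in spec.smooths)
    has_global = any(s.by is None and not s.is_random_effect
                     for s in spec.smooths)
    return has_by_site and has_global


def hgam_aic_compare(fit1: HGAMFit, fit2: HGAMFit) -> float:
    """AIC(fit1) - AIC(fit2): positive favours the second structure.

    Comparisons between structures with and without a global smoother are
    biased towards the structure without it; a warning flags that case.
    """
    if fit1.fingerprint != fit2.fingerprint:
        raise ValueError("fits were not computed on the same data")
    g1, g2 = _has_global(fit1.spec), _has_global(fit2.spec)
    if g1 != g2:
        warnings.warn("comparing structures with and without a global "
                      "smoother: AIC tends to favour the one without it")
    return fit1.aic - fit2.aic


def season_structures(covariate: str = "season", K: int = 12,
                      knots=None) -> tuple[HGAMSpec, HGAMSpec]:
    """The two covariate HGAM structures for seasonal activity contrasts.

    Structure 1 (random-intercept analogue): covariate main effect, a cyclic
    smooth of time per covariate level, and a site ridge smoother. Structure 2
    adds a global cyclic smooth and a (shared-smoothing) by-site cyclic smooth
    so the site curves shrink towards the common shape.
    """
    kn = tuple(knots) if knots is not None else None
    s_by_cov = CyclicSplineSpec(label="s(time)", K=K, knots=kn, by=covariate)
    s_site_re = CyclicSplineSpec(label="s(site)", is_random_effect=True)
    spec1 = HGAMSpec(parametric=(covariate,), smooths=(s_by_cov, s_site_re))
    s_global = CyclicSplineSpec(label="s(time)_global", K=K, knots=kn)
    s_by_site = CyclicSplineSpec(label="s(time)_site", K=K, knots=kn,
                                 by="site", share_lambda=True)
    spec2 = HGAMSpec(parametric=(covariate,),
                     smooths=(s_global, s_by_site, s_by_cov, s_site_re))
    return spec1, spec2
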