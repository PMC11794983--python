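"""End-to-end analysis workflows tying the modules together.

``run_shape_analysis`` fits the cathemeral/unimodal/bimodal trigonometric
model trio and reports the AIC table, the LRT chain and the winning model's
activity curve. ``run_covariate_analysis`` quantifies a categorical
covariate's effect on the activity pattern via a trigonometric GLMM with
covariate-by-harmonic interactions, the two cyclic-spline HGAM structures,
and per-level KDEs. Both write their artifacts with a run manifest (input
checksums, seed, package versions) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, child_seed
from .curves import conditional_mean, curve_ci, find_peaks, marginal_mean
from .hgam import fit_hgam, hgam_aic_compare, season_structures
from .io import export_curves, read_detections, read_effort
from .kde import kde_curve
from .occasions import aggregate_binomial, bin_detections, independent_events
from .trig import TrigModelSpec, aic, compare_aic, fit_trig, lrt, wald_test

__all__ = ["run_shape_analysis", "run_covariate_analysis",
           "shape_analysis", "prepare_occasions"]


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _manifest(cfg: AnalysisConfig, outdir: Path, extra: dict) -> None:
    man = {
        "dielact_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "inputs": {
            "detections": {"path": cfg.detections, "sha256_16": _checksum(cfg.detections)},
            "effort": {"path": cfg.effort, "sha256_16": _checksum(cfg.effort)},
        },
        "config": json.loads(cfg.model_dump_json()),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(man, indent=1))


def prepare_occasions(cfg: AnalysisConfig, group_by=()):
    """Read inputs and build the binomial occasion table per the config."""
    det = read_detections(cfg.detections)
    eff = read_effort(cfg.effort)
    if cfg.event_threshold_minutes > 0:
        det = independent_events(det, cfg.event_threshold_minutes)
    binary = bin_detections(det, eff, cfg.bin_hours, effort_mode=cfg.effort_mode)
    occ = aggregate_binomial(binary, group_by=group_by)
    return det, eff, occ


def shape_analysis(occ: pd.DataFrame, quad_points: int = 11,
                   random_structure: str = "intercept_only",
                   grid_minutes: float = 5.0, ci_seed: int = 0) -> dict:
    """Fit the null/unimodal/bimodal trio on an occasion table.

    Returns the AIC table, the LRT chain, each model's fit and the winning
    model's conditional (typical-site) curve with its peaks.
    """
    fits, failures = {}, {}
    for name, periods in (("null_mod", ()), ("unimodal", (24.0,)),
                          ("bimodal", (24.0, 12.0))):
        spec = TrigModelSpec(periods=periods, random_structure=random_structure,
                             quad_points=quad_points)
        try:
            fits[name] = fit_trig(spec, occ)
        except Exception as e:          # a failed member must not sink the report
            failures[name] = str(e)
    if not fits:
        raise RuntimeError(f"all shape models failed: {failures}")

    tab = compare_aic(fits)
    tests = {}
    if {"null_mod", "unimodal"} <= fits.keys():
        s, d, p = lrt(fits["null_mod"], fits["unimodal"])
        tests["null_vs_unimodal"] = {"stat": s, "df": d, "p": p}
    if {"unimodal", "bimodal"} <= fits.keys():
        s, d, p = lrt(fits["unimodal"], fits["bimodal"])
        tests["unimodal_vs_bimodal"] = {"stat": s, "df": d, "p": p}

    best = tab.index[0]
    times = np.arange(0, 24, grid_minutes / 60.0)
    curve = conditional_mean(fits[best], times)
    curve = curve_ci(fits[best], curve, seed=ci_seed)
    return {"fits": fits, "aic_table": tab, "lrt": tests, "best": best,
            "curve": curve, "peaks": find_peaks(curve), "failures": failures}


def run_shape_analysis(cfg: AnalysisConfig) -> dict:
    """Config-driven shape analysis; writes report artifacts to cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trig_models = [m for m in cfg.models if m.family == "trig"]
    quad = trig_models[0].quad_points if trig_models else 11
    rs = trig_models[0].random_structure if trig_models else "intercept_only"
    _, _, occ = prepare_occasions(cfg)
    res = shape_analysis(occ, quad_points=quad, random_structure=rs,
                         ci_seed=child_seed(cfg.seed, "shape_ci"))
    res["aic_table"].to_csv(outdir / "aic_table.csv")
    export_curves({res["best"]: res["curve"]}, outdir / "best_curve.csv")
    report = {
        "best": res["best"],
        "aic_table": res["aic_table"].to_dict(orient="index"),
        "lrt": res["lrt"],
        "peaks": res["peaks"],
        "failures": res["failures"],
        "converged": {k: f.converged for k, f in res["fits"].items()},
    }
    (outdir / "shape_report.json").write_text(json.dumps(report, indent=1))
    _manifest(cfg, outdir, {"analysis": "shape"})
    return res


def covariate_analysis(occ_by_level: pd.DataFrame, covariate: str,
                       det: pd.DataFrame | None = None,
                       quad_points: int = 11, K: int = 12,
                       grid_minutes: float = 5.0, seed: int = 0,
                       kde_bootstrap: int = 200,
                       fit_hgams: bool = True) -> dict:
    """Covariate-effect analysis on a per-level occasion table.

    Fits a trigonometric GLMM with covariate-by-harmonic interactions (plus
    the no-covariate null for the AIC contrast), optionally the two HGAM
    structures, and a KDE per covariate level from the (event-filtered)
    detections if given. Emits per-level conditional and marginal curves.
    """
    levels = sorted(occ_by_level[covariate].astype(str).unique())
    out: dict = {"levels": levels}
    times = np.arange(0, 24, grid_minutes / 60.0)

    if len(levels) < 2:
        res = shape_analysis(occ_by_level.drop(columns=[covariate])
                             .groupby(["site", "time"], as_index=False)
                             [["success", "failure"]].sum(),
                             quad_points=quad_points, ci_seed=seed)
        out["note"] = "covariate has a single level; reduced to shape analysis"
        out["shape"] = res
        return out

    # drop levels carrying no trials
    trials = occ_by_level.groupby(covariate)[["success", "failure"]].sum().sum(axis=1)
    dead = [str(l) for l in trials.index[trials == 0]]
    if dead:
        warnings.warn(f"covariate level(s) with zero trials dropped: {dead}")
        occ_by_level = occ_by_level[~occ_by_level[covariate].astype(str).isin(dead)]
        levels = sorted(occ_by_level[covariate].astype(str).unique())
        out["levels"] = levels

    spec_cov = TrigModelSpec(periods=(24.0, 12.0), covariates=(covariate,),
                             interactions=True, quad_points=quad_points)
    spec_null = TrigModelSpec(periods=(24.0, 12.0), quad_points=quad_points)
    fit_cov = fit_trig(spec_cov, occ_by_level)
    # the no-covariate model must see the same aggregation to share data rows
    fit_null = fit_trig(spec_null, occ_by_level)
    inter_names = [n for n in fit_cov.alpha.index if ":" in n]
    w_stat, w_df, w_p = wald_test(fit_cov, inter_names)
    out["trig"] = {
        "fit": fit_cov,
        "null_fit": fit_null,
        "delta_aic_null_vs_covariate": aic(fit_null) - aic(fit_cov),
        "interaction_wald": {"stat": w_stat, "df": w_df, "p": w_p},
        "sigma_tau": float(fit_cov.re_sd.iloc[0]),
    }

    curves = {}
    for lev in levels:
        cov = {covariate: lev}
        cc = conditional_mean(fit_cov, times, covariates=cov)
        cc = curve_ci(fit_cov, cc, covariates=cov, seed=seed)
        mc = marginal_mean(fit_cov, times, covariates=cov)
        curves[f"trig_conditional_{lev}"] = cc
        curves[f"trig_marginal_{lev}"] = mc

    if fit_hgams:
        spec1, spec2 = season_structures(covariate, K=K)
        h1 = fit_hgam(occ_by_level, spec1)
        h2 = fit_hgam(occ_by_level, spec2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delta12 = hgam_aic_compare(h1, h2)
        out["hgam"] = {"structure1": h1, "structure2": h2,
                       "delta_aic_structure1_vs_2": delta12}
        for lev in levels:
            cov = {covariate: lev}
            hc = conditional_mean(h1, times, covariates=cov)
            hc = curve_ci(h1, hc, covariates=cov)
            curves[f"hgam_conditional_{lev}"] = hc

    if det is not None and "timestamp" in det:
        lev_col = covariate if covariate in det.columns else None
        if lev_col is not None:
            for lev in levels:
                sub = det[det[lev_col].astype(str) == lev]
                if len(sub) >= 5:
                    curves[f"kde_{lev}"] = kde_curve(
                        sub, ci=kde_bootstrap > 0, B=kde_bootstrap, seed=seed)
    out["curves"] = curves
    return out


def run_covariate_analysis(cfg: AnalysisConfig) -> dict:
    """Config-driven covariate analysis; writes artifacts to cfg.outdir."""
    if not cfg.covariate:
        raise ValueError("config must set 'covariate' for a covariate analysis")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    det, eff, occ = prepare_occasions(cfg, group_by=(cfg.covariate,))
    trig_models = [m for m in cfg.models if m.family == "trig"]
    hgam_models = [m for m in cfg.models if m.family == "hgam"]
    kde_models = [m for m in cfg.models if m.family == "kde"]
    det_for_kde = det if kde_models else None
    if det_for_kde is not None and cfg.covariate not in det_for_kde.columns:
        det_for_kde = None
    res = covariate_analysis(
        occ, cfg.covariate, det=det_for_kde,
        quad_points=trig_models[0].quad_points if trig_models else 11,
        K=hgam_models[0].K if hgam_models else 12,
        seed=child_seed(cfg.seed, "covariate"),
        kde_bootstrap=kde_models[0].bootstrap if kde_models else 0,
        fit_hgams=bool(hgam_models),
    )
    if "curves" in res:
        export_curves(res["curves"], outdir / "curves.csv")
    report = {"levels": res["levels"]}
    if "trig" in res:
        report["trig"] = {k: v for k, v in res["trig"].items()
                          if k not in ("fit", "null_fit")}
    if "hgam" in res:
        report["hgam"] = {"delta_aic_structure1_vs_2":
                          res["hgam"]["delta_aic_structure1_vs_2"],
                          "sigma_tau_implied":
                          res["hgam"]["structure1"].implied_sigma_tau()}
    (outdir / "covariate_report.json").write_text(json.dumps(report, indent=1))
    _manifest(cfg, outdir, {"analysis": "covariate"})
    return res
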