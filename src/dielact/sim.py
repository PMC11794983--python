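"""Generative simulator for diel detection data.

The probability that a species is active at site ``i`` during the time-of-day
interval starting at ``t`` (hours) follows a two-harmonic logistic model

    logit p_it = beta0 + beta1*cos(2*pi*t/omega1 + theta0 + gamma_i)
                       + beta2*cos(2*pi*t/omega2 + theta1 + gamma_i) + tau_i

with site random effects tau_i ~ N(0, sigma_tau) (vertical shifts in the
frequency of site use) and gamma_i ~ N(0, sigma_gamma) (shifts in the timing
of activity, shared by both harmonics). Detections are Bernoulli draws per
site x day x bin, so every other module in the package can be exercised
against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimParams",
    "draw_site_effects",
    "linear_predictor",
    "true_curve",
    "simulate_detections",
    "figure1_scenarios",
]

#: Phase shift that places the peak of the 24-h harmonic at 20:00.
_PEAK20 = -2.0 * math.pi * 20.0 / 24.0


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-harmonic logistic activity model.

    Amplitudes are constrained non-negative: a sign flip is equivalent to a
    half-period phase shift, so the sign is absorbed by ``theta0``/``theta1``.
    """

    beta0: float = -3.0
    beta1: float = 1.0
    beta2: float = 0.7
    theta0: float = _PEAK20
    theta1: float = 0.0
    omega1: float = 24.0
    omega2: float = 12.0
    sigma_tau: float = 1.0
    sigma_gamma: float = 0.3

    def __post_init__(self) -> None:
        vals = [self.beta0, self.beta1, self.beta2, self.theta0, self.theta1,
                self.omega1, self.omega2, self.sigma_tau, self.sigma_gamma]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all simulation parameters must be finite")
        if self.omega1 <= 0 or self.omega2 <= 0:
            raise ValueError("harmonic periods must be positive")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("amplitudes beta1, beta2 must be >= 0 "
                             "(sign is absorbed by the phase)")
        if self.sigma_tau < 0 or self.sigma_gamma < 0:
            raise ValueError("random-effect SDs must be >= 0")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


def draw_site_effects(params: SimParams, n_sites: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-site random effects (intercept ``tau``, phase ``gamma``).

    Site effects are drawn before any observation noise so that the same seed
    yields the same sites regardless of downstream sampling choices.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    tau = rng.normal(0.0, params.sigma_tau, size=n_sites)
    gamma = rng.normal(0.0, params.sigma_gamma, size=n_sites)
    return pd.DataFrame({
        "site": [f"S{i + 1:03d}" for i in range(n_sites)],
        "tau": tau,
        "gamma": gamma,
    })


def linear_predictor(params: SimParams, t, tau: float = 0.0,
                     gamma: float = 0.0):
    """Logit-scale activity at hour-of-day ``t`` for one site.

    ``t`` may be scalar or array, in [0, 24).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= 24):
        raise ValueError("t must lie in [0, 24)")
    if not (np.isfinite(tau) and np.isfinite(gamma)):
        raise ValueError("site effects must be finite")
    eta = (params.beta0
           + params.beta1 * np.cos(2 * np.pi * t / params.omega1 + params.theta0 + gamma)
           + params.beta2 * np.cos(2 * np.pi * t / params.omega2 + params.theta1 + gamma)
           + tau)
    return eta if eta.ndim else float(eta)


def true_curve(params: SimParams, t, tau: float = 0.0, gamma: float = 0.0):
    """Probability-scale activity curve for one site (or the typical site)."""
    return expit(linear_predictor(params, t, tau, gamma))


def simulate_detections(params: SimParams, n_sites: int = 100,
                        n_days: int = 60, bin_hours: float = 1.0,
                        seed: int = 0, start_date: str = "2016-05-15"):
    """Simulate Bernoulli detections per site x day x time bin.

    Activity probabilities are evaluated at bin *start* times
    ``t in {0, bin_hours, 2*bin_hours, ...}``; one detection record (with its
    timestamp at the bin start) is emitted per successful bin. The effort
    table covers every simulated day at every site.

    Returns
    -------
    detections : DataFrame with columns ``site``, ``timestamp``
    effort : DataFrame with columns ``site``, ``start``, ``end``
    effects : DataFrame with columns ``site``, ``tau``, ``gamma``
    """
    if n_sites < 1 or n_days < 1:
        raise ValueError("n_sites and n_days must be >= 1")
    n_bins_f = 24.0 / bin_hours
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError("24 must be divisible by bin_hours")
    n_bins = int(round(n_bins_f))

    rng = np.random.default_rng(seed)
    effects = draw_site_effects(params, n_sites, rng)

    t_grid = np.arange(n_bins) * bin_hours
    # p[i, t]: constant across days
    eta = np.stack([
        linear_predictor(params, t_grid, tau=row.tau, gamma=row.gamma)
        for row in effects.itertuples()
    ])
    p = expit(eta)

    u = rng.random(size=(n_sites, n_days, n_bins))
    hits = u < p[:, None, :]

    t0 = pd.Timestamp(start_date)
    site_idx, day_idx, bin_idx = np.nonzero(hits)
    timestamps = (t0
                  + pd.to_timedelta(day_idx, unit="D")
                  + pd.to_timedelta(bin_idx * bin_hours, unit="h"))
    det = pd.DataFrame({
        "site": effects["site"].to_numpy()[site_idx],
        "timestamp": timestamps,
    }).sort_values(["site", "timestamp"], kind="stable").reset_index(drop=True)

    effort = pd.DataFrame({
        "site": effects["site"],
        "start": t0,
        "end": t0 + pd.Timedelta(days=n_days),
    })
    return det, effort, effects


def figure1_scenarios(which: str):
    """Preset site-effect configurations illustrating the two variance axes.

    ``'a'``: six sites varying only in frequency of use
    (tau in {+-0.5, +-1, +-1.5}, gamma = 0).
    ``'b'``: six sites varying only in timing (tau = 0,
    gamma in {+-0.5, +-1, +-1.5}).
    ``'c'``: random scenario with sigma_tau = 1, sigma_gamma = 0.3.
    """
    base = SimParams()
    if which == "a":
        grid = [0.5, -0.5, 1.0, -1.0, 1.5, -1.5]
        effects = pd.DataFrame({
            "site": [f"S{i + 1:03d}" for i in range(6)],
            "tau": grid,
            "gamma": [0.0] * 6,
        })
        return base.with_(sigma_tau=0.0, sigma_gamma=0.0), effects
    if which == "b":
        grid = [0.5, -0.5, 1.0, -1.0, 1.5, -1.5]
        effects = pd.DataFrame({
            "site": [f"S{i + 1:03d}" for i in range(6)],
            "tau": [0.0] * 6,
            "gamma": grid,
        })
        return base.with_(sigma_tau=0.0, sigma_gamma=0.0), effects
    if which == "c":
        return base.with_(sigma_tau=1.0, sigma_gamma=0.3), None
    raise ValueError(f"unknown scenario panel {which!r}; expected 'a', 'b' or 'c'")
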