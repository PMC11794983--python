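"""Circular (von Mises) kernel density estimation of relative activity.

The baseline that hierarchical models are compared against: detection times
are mapped to angles on the circle, and the density is a mixture of von Mises
kernels centred at the observations,

    f_hat(x) = (1/n) * sum_i exp(kappa * cos(x - a_i)) / (2*pi*I0(kappa)).

The kernel concentration kappa is chosen by the standard von Mises plug-in
rule (fit a von Mises by maximum likelihood, then apply the smoothing rule
for von Mises kernels); an ``adjust`` multiplier scales it, since KDEs are
sensitive to the bandwidth choice. KDEs use only the detections — effort is
ignored — so they estimate *relative* activity (a density integrating to one
over the circle), and because they pool data across sites they estimate a
marginal, population-averaged pattern. Uncertainty comes from a nonparametric
bootstrap over detections, which ignores within-site dependence.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0, i0e, i1e, ive

__all__ = ["time_to_radians", "radians_to_time", "taylor_concentration",
           "vm_kde", "kde_bootstrap_ci", "kde_curve"]

TWO_PI = 2.0 * np.pi


def time_to_radians(t):
    """Hours of day to angle: (2*pi*t/24) mod 2*pi."""
    return np.mod(TWO_PI * np.asarray(t, dtype=float) / 24.0, TWO_PI)


def radians_to_time(a):
    """Angle to hours of day in [0, 24)."""
    return np.mod(np.asarray(a, dtype=float) * 24.0 / TWO_PI, 24.0)


def _vm_mle_kappa(rbar: float) -> float:
    """Solve A1(kappa) = I1/I0 = rbar for the ML concentration."""
    if rbar < 1e-12:
        return 0.0
    if rbar > 1 - 1e-10:
        raise ValueError("mean resultant length ~ 1: concentration undefined "
                         "(all angles identical?)")
    f = lambda k: i1e(k) / i0e(k) - rbar
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("concentration solve failed")
    return brentq(f, 0.0, hi, xtol=1e-12)


def taylor_concentration(angles, weights=None) -> float:
    """Plug-in kernel concentration for von Mises KDE (Taylor's rule).

    kappa_kernel = [ 3 n kappa^2 I2(2 kappa) / (4 sqrt(pi) I0(kappa)^2) ]^{2/5}
    where kappa is the ML concentration of a von Mises fit to the sample.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 angles for automatic bandwidth")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()
    C = np.sum(w * np.cos(a)) / n
    S = np.sum(w * np.sin(a)) / n
    rbar = np.hypot(C, S)
    kap = _vm_mle_kappa(rbar)
    if kap == 0.0:
        # uniform-looking sample: fall back to a mild fixed concentration
        return 1.0
    # ratio I2(2k)/I0(k)^2 via exponentially scaled Bessels for stability
    ratio = ive(2, 2 * kap) / (i0e(kap) ** 2)
    return float((3.0 * a.size * kap ** 2 * ratio / (4.0 * np.sqrt(np.pi))) ** 0.4)


def vm_kde(angles, concentration: float | None = None, adjust: float = 1.0,
           n_grid: int = 512, weights=None):
    """Von Mises kernel density estimate on an equally spaced circular grid.

    Returns ``(grid, density)`` with the density integrating to one over
    [0, 2*pi). ``adjust`` multiplies the concentration (values > 1 smooth
    less). ``weights`` are optional per-observation weights.
    """
    a = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    if a.size < 1:
        raise ValueError("need at least one angle")
    if concentration is None:
        kappa = taylor_concentration(a, weights)
    else:
        kappa = float(concentration)
    kappa *= adjust
    if kappa <= 0:
        raise ValueError("kernel concentration must be positive")
    grid = np.arange(n_grid) * TWO_PI / n_grid
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    dens = np.zeros(n_grid)
    norm = TWO_PI * i0(kappa) if kappa < 700 else np.inf
    # chunk over observations to bound memory at large n
    for lo in range(0, a.size, 8192):
        ai = a[lo:lo + 8192]
        wi = w[lo:lo + 8192]
        # exp(kappa*cos(x - ai)) computed stably as exp(kappa*(cos - 1))*e^kappa
        c = np.cos(grid[:, None] - ai[None, :])
        if np.isinf(norm):
            dens += np.exp(kappa * (c - 1.0)) @ wi
        else:
            dens += np.exp(kappa * c) @ wi
    if np.isinf(norm):
        dens /= TWO_PI * i0e(kappa)
    else:
        dens /= norm
    return grid, dens


def kde_bootstrap_ci(angles, B: int = 1000, seed: int = 0,
                     concentration: float | None = None, adjust: float = 1.0,
                     n_grid: int = 512, level: float = 0.95):
    """Pointwise percentile bootstrap band for the von Mises KDE.

    Resamples detections with replacement; the concentration is re-selected
    on each replicate unless a fixed ``concentration`` is given.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 5:
        raise ValueError("need at least 5 angles to bootstrap")
    rng = np.random.default_rng(seed)
    grid, est = vm_kde(a, concentration, adjust, n_grid)
    sims = np.empty((B, n_grid))
    for b in range(B):
        ab = rng.choice(a, size=a.size, replace=True)
        try:
            _, sims[b] = vm_kde(ab, concentration, adjust, n_grid)
        except ValueError:   # degenerate resample: reuse the point estimate
            sims[b] = est
    alpha = 0.5 * (1 - level)
    lo = np.quantile(sims, alpha, axis=0)
    hi = np.quantile(sims, 1 - alpha, axis=0)
    return grid, est, lo, hi


def kde_curve(det, concentration: float | None = None, adjust: float = 1.0,
              n_grid: int = 512, ci: bool = False, B: int = 1000,
              seed: int = 0):
    """KDE of relative activity from a detection table, on the hour scale.

    Accepts a DataFrame with a ``timestamp`` column or a vector of
    hours-of-day. The returned curve is a density per *hour* (integrates to
    one over 24 h) with scale flag ``kde_relative``.
    """
    from .curves import ActivityCurve

    if hasattr(det, "columns"):
        import pandas as pd
        ts = pd.to_datetime(det["timestamp"])
        hours = (ts - ts.dt.normalize()).dt.total_seconds().to_numpy() / 3600.0
    else:
        hours = np.asarray(det, dtype=float)
    ang = time_to_radians(hours)
    if ci:
        grid, est, lo, hi = kde_bootstrap_ci(ang, B=B, seed=seed,
                                             concentration=concentration,
                                             adjust=adjust, n_grid=n_grid)
        scale_f = TWO_PI / 24.0
        return ActivityCurve(radians_to_time(grid), est * scale_f,
                             lo * scale_f, hi * scale_f,
                             scale="kde_relative", model="vm_kde")
    grid, est = vm_kde(ang, concentration, adjust, n_grid)
    return ActivityCurve(radians_to_time(grid), est * TWO_PI / 24.0,
                         scale="kde_relative", model="vm_kde")
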