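"""Cyclic cubic regression splines.

A cyclic cubic regression spline is parameterized by the function's values at
the knots, with the value and the first and second derivatives matching at the
two ends of the time axis so the fitted curve wraps smoothly around the diel
cycle. With knots t_0 < ... < t_{K-1} (t_{K-1} identified with t_0 plus the
period) the natural-spline interpolation conditions give the second
derivatives as a linear map B^{-1} D of the knot values, the wiggliness
penalty is the integrated squared second derivative S = D' B^{-1} D, and the
basis evaluates the interpolating cyclic spline at arbitrary points. The
penalty null space is the constants (rank K-2 for K knots, i.e. K-1 free
values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CyclicSplineSpec", "cyclic_knots", "cyclic_basis"]


@dataclass(frozen=True)
class CyclicSplineSpec:
    """Specification of one cyclic smooth term.

    ``K`` is the basis dimension (number of knots); the default 12 knots span
    [0, 23] so that hour 23 wraps onto hour 0, matching common usage on
    hourly-binned data (use ``knots=cyclic_knots(K, 0, 24)`` for a full
    24-hour wrap, recommended for sub-hourly bins). ``by`` replicates the
    (centred) smoother per level of a factor; ``is_random_effect`` marks the
    site ridge smoother (one indicator column per site, identity penalty),
    whose smoothing parameter maps to an implied random-intercept variance
    sigma_tau^2 = 1/lambda. ``share_lambda`` gives all levels of a ``by``
    smooth a single smoothing parameter (the factor-smooth convention, used
    for by-site random curves so the outer optimization stays low-dimensional).
    """

    label: str = "s(time)"
    K: int = 12
    knots: tuple | None = None
    by: str | None = None
    is_random_effect: bool = False
    share_lambda: bool = False

    def resolved_knots(self) -> np.ndarray:
        if self.is_random_effect:
            raise ValueError("random-effect smoother has no knots")
        if self.knots is not None:
            kn = np.asarray(self.knots, dtype=float)
        else:
            kn = cyclic_knots(self.K, 0.0, 23.0)
        if kn.ndim != 1 or len(kn) < 4:
            raise ValueError("need at least 4 knots (K >= 4)")
        if np.any(np.diff(kn) <= 0):
            raise ValueError("knots must be strictly increasing")
        return kn


def cyclic_knots(K: int, lo: float = 0.0, hi: float = 23.0) -> np.ndarray:
    """K equally spaced knots spanning [lo, hi]; first/last are wrap points."""
    if K < 4:
        raise ValueError("K must be >= 4")
    return np.linspace(lo, hi, K)


def _bd_matrices(knots: np.ndarray):
    """Cyclic tridiagonal B, D with B @ f'' = D @ f at the free knots."""
    m = len(knots) - 1                       # free knot values (wrap point dropped)
    h = np.diff(knots)                        # m interval widths, cyclic
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for j in range(m):
        jm = (j - 1) % m
        jp = (j + 1) % m
        B[j, jm] += h[jm] / 6.0
        B[j, j] += (h[jm] + h[j]) / 3.0
        B[j, jp] += h[j] / 6.0
        D[j, jm] += 1.0 / h[jm]
        D[j, j] += -(1.0 / h[jm] + 1.0 / h[j])
        D[j, jp] += 1.0 / h[j]
    return B, D


def cyclic_basis(times, spec: CyclicSplineSpec):
    """Evaluate the cyclic cubic regression spline basis and its penalty.

    Returns ``(X, S)``: ``X`` maps the K-1 free knot values to function values
    at ``times`` (reduced modulo the period into the knot range), and ``S`` is
    the integrated-squared-second-derivative penalty, symmetric PSD with the
    constants as null space.
    """
    knots = spec.resolved_knots()
    m = len(knots) - 1
    if spec.K > len(knots):
        raise ValueError("basis dimension exceeds number of knots")
    period = knots[-1] - knots[0]
    x = np.asarray(times, dtype=float)
    x = knots[0] + np.mod(x - knots[0], period)

    B, D = _bd_matrices(knots)
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = 0.5 * (S + S.T)

    # locate interval j with knots[j] <= x < knots[j+1]
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, m - 1)
    hj = knots[j + 1] - knots[j]
    a = (knots[j + 1] - x) / hj            # weight on left knot value
    b = (x - knots[j]) / hj
    ca = ((knots[j + 1] - x) ** 3 / hj - hj * (knots[j + 1] - x)) / 6.0
    cb = ((x - knots[j]) ** 3 / hj - hj * (x - knots[j])) / 6.0

    n = len(x)
    A1 = np.zeros((n, m))                   # value part
    A2 = np.zeros((n, m))                   # second-derivative part
    rows = np.arange(n)
    jl = j
    jr = (j + 1) % m                        # right end of last interval wraps to knot 0
    np.add.at(A1, (rows, jl), a)
    np.add.at(A1, (rows, jr), b)
    np.add.at(A2, (rows, jl), ca)
    np.add.at(A2, (rows, jr), cb)

    X = A1 + A2 @ Binv_D
    return X, S
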