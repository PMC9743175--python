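"""Response curves along the RD gradient; decoupling and coupling statistics.

Fits linear, quadratic and logistic (S-shape) responses of productivity
(AGB) and species richness (SR) to resource diversity (RD), compares
them by R-squared/AIC and the significance of the family's key
coefficient, and derives

* the decoupling index ``DI(x) = SR'(x) / AGB'(x)`` from the fitted
  curves' closed-form derivatives (DI > 1: RD shifts richness faster
  than productivity),
* the tipping point: the RD value where a quadratic smooth of DI crosses
  1 from above,
* the per-site coupling degree ``C = 2*sqrt(SR*P) / (SR + P)``, a
  function of the SR/AGB ratio alone, with its linear trend along RD.

Richness (a count) and biomass (g/m2) are incommensurable, so DI is
computed from fits on min-max-normalized responses by default; ``zscore``
(derivatives rescaled by 1/sd) and ``raw`` modes are available.  The
coupling degree is computed on the raw pairwise values, where imbalance
between the two responses is the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CurveFit",
    "DecouplingSeries",
    "CouplingSeries",
    "minmax_normalize",
    "fit_curve",
    "derivative",
    "decoupling_index",
    "tipping_point",
    "coupling_degree",
]

FAMILIES = ("linear", "quadratic", "logistic")
NORMALIZATION_MODES = ("minmax", "zscore", "raw")


@dataclass
class CurveFit:
    """A fitted response curve and its comparison statistics.

    ``key_coef_p`` is the p-value of the family's decisive coefficient:
    the slope (linear), the quadratic term (quadratic) or the rate ``k``
    (logistic, from its asymptotic standard error).
    """

    family: str
    params: dict
    r_squared: float
    aic: float
    key_coef_p: float
    n: int
    converged: bool = True
    message: str = ""


@dataclass
class DecouplingSeries:
    grid: np.ndarray
    di: np.ndarray
    tipping_point: Optional[float]


@dataclass
class CouplingSeries:
    c: np.ndarray
    trend_slope: Optional[float] = None
    trend_p: Optional[float] = None


def minmax_normalize(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector")
    return (v - lo) / (hi - lo)


def _logistic(x, a, k, m):
    return a / (1.0 + np.exp(-k * (x - m)))


def _gaussian_aic(n: int, rss: float, n_params: int) -> float:
    # error variance counted as a parameter
    return n * np.log(max(rss, 1e-300) / n) + 2 * (n_params + 1)


def _poly_fit(x, y, degree: int) -> CurveFit:
    n = x.size
    X = np.vander(x, degree + 1, increasing=True)  # columns 1, x, x^2...
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - (degree + 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tstat = beta[-1] / se[-1] if se[-1] > 0 else np.inf
    p = 2 * stats.t.sf(abs(tstat), dof)
    tss = float(np.sum((y - y.mean()) ** 2))
    names = ["intercept", "slope"] if degree == 1 else ["intercept", "b1", "b2"]
    return CurveFit(
        family="linear" if degree == 1 else "quadratic",
        params=dict(zip(names, map(float, beta))),
        r_squared=1.0 - rss / tss if tss > 0 else 1.0,
        aic=_gaussian_aic(n, rss, degree + 1),
        key_coef_p=float(p),
        n=n,
    )


def _logistic_fit(x, y, n_restarts: int = 5, seed: int = 0) -> CurveFit:
    n = x.size
    a0 = float(y.max())
    m0 = float(np.median(x))
    slope = float(np.polyfit(x, y, 1)[0])
    k0 = 4.0 * slope / a0 if a0 != 0 else 1.0
    if k0 <= 0:
        k0 = 1.0 / max(np.ptp(x), 1e-6)
    rng = np.random.default_rng(seed)
    starts = [(a0, k0, m0)]
    starts += [
        (a0 * rng.uniform(0.5, 1.5), k0 * rng.uniform(0.3, 3.0), m0 + np.ptp(x) * rng.uniform(-0.3, 0.3))
        for _ in range(n_restarts)
    ]
    best = None
    message = ""
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _logistic, x, y, p0=p0,
                    bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            rss = float(np.sum((y - _logistic(x, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
        except (RuntimeError, ValueError) as exc:  # non-convergence for this start
            message = str(exc)
    if best is None:
        return CurveFit(
            family="logistic", params={}, r_squared=np.nan, aic=np.inf,
            key_coef_p=np.nan, n=n, converged=False,
            message=f"logistic fit failed after {len(starts)} starts: {message}",
        )
    rss, popt, pcov = best
    a, k, m = map(float, popt)
    se_k = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    dof = n - 3
    p = 2 * stats.t.sf(abs(k / se_k), dof) if se_k > 0 and np.isfinite(se_k) else np.nan
    tss = float(np.sum((y - y.mean()) ** 2))
    return CurveFit(
        family="logistic",
        params={"a": a, "k": k, "m": m},
        r_squared=1.0 - rss / tss if tss > 0 else 1.0,
        aic=_gaussian_aic(n, rss, 3),
        key_coef_p=float(p),
        n=n,
    )


def fit_curve(x, y, family: str, seed: int = 0) -> CurveFit:
    """Least-squares fit of one response family.

    Logistic fits use nonlinear least squares initialized at
    ``a0 = max(y)``, ``m0 = median(x)``, ``k0 = 4*slope(y~x)/a0`` with 5
    jittered restarts; non-convergence is returned as a flagged fit, not
    raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    n_params = {"linear": 2, "quadratic": 3, "logistic": 3}[family]
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < n_params + 2:
        raise ValueError(f"{family} fit needs at least {n_params + 2} points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if family == "linear":
        return _poly_fit(x, y, 1)
    if family == "quadratic":
        return _poly_fit(x, y, 2)
    return _logistic_fit(x, y, seed=seed)


def derivative(fit: CurveFit, x) -> np.ndarray:
    """Closed-form derivative of the fitted curve on a grid."""
    x = np.asarray(x, dtype=float)
    if not fit.converged:
        raise ValueError(f"cannot differentiate a non-converged fit: {fit.message}")
    if fit.family == "linear":
        return np.full_like(x, fit.params["slope"])
    if fit.family == "quadratic":
        return fit.params["b1"] + 2.0 * fit.params["b2"] * x
    a, k, m = fit.params["a"], fit.params["k"], fit.params["m"]
    e = np.exp(-k * (x - m))
    return a * k * e / (1.0 + e) ** 2


def decoupling_index(fit_sr: CurveFit, fit_agb: CurveFit, grid) -> DecouplingSeries:
    """DI along the grid, with the tipping point of its quadratic smooth.

    Grid points where the AGB derivative is below 1e-12 in magnitude are
    dropped with a warning (DI undefined there).
    """
    grid = np.asarray(grid, dtype=float)
    d_sr = derivative(fit_sr, grid)
    d_agb = derivative(fit_agb, grid)
    keep = np.abs(d_agb) > 1e-12
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} grid point(s) where the AGB derivative vanishes",
            RuntimeWarning,
            stacklevel=2,
        )
    grid, d_sr, d_agb = grid[keep], d_sr[keep], d_agb[keep]
    di = d_sr / d_agb
    tp = tipping_point(grid, di) if grid.size >= 4 else None
    return DecouplingSeries(grid=grid, di=di, tipping_point=tp)


def tipping_point(rd, di) -> Optional[float]:
    """RD where the quadratic smooth of DI crosses 1 going down.

    Fits ``DI ~ quadratic(RD)`` and returns the real root of
    ``quadratic - 1`` inside the observed RD range at which DI passes
    from above 1 to below 1 as RD increases; ``None`` if no such
    crossing exists.
    """
    rd = np.asarray(rd, dtype=float)
    di = np.asarray(di, dtype=float)
    if rd.size < 4:
        raise ValueError("tipping point needs at least 4 DI points")
    coeffs = np.polynomial.polynomial.polyfit(rd, di - 1.0, 2)  # c0 + c1 x + c2 x^2
    c0, c1, c2 = coeffs
    if abs(c2) < 1e-12 * max(1.0, abs(c0), abs(c1)):
        roots = np.array([-c0 / c1]) if c1 != 0 else np.array([])
    else:
        disc = c1**2 - 4.0 * c2 * c0
        if disc < 0:
            roots = np.array([])
        else:
            sq = np.sqrt(disc)
            roots = np.array([(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)])
    lo, hi = rd.min(), rd.max()
    in_range = [r for r in roots if lo <= r <= hi]
    # downward crossing: derivative of the quadratic negative at the root
    down = [r for r in in_range if (c1 + 2.0 * c2 * r) < 0]
    if down:
        return float(down[0])
    return None


def coupling_degree(sr, agb, rd=None) -> CouplingSeries:
    """Per-site coupling degree between richness and biomass.

    Computed on the raw pairwise values by default usage (C depends only
    on the SR/AGB ratio); callers may pass normalized vectors instead.

    ``C_i = sqrt(SR_i*P_i / ((SR_i+P_i)/2)**2) = 2*sqrt(SR_i*P_i)/(SR_i+P_i)``,
    1 when the two normalized values coincide, 0 when either is 0.
    Pairs with ``SR_i + P_i == 0`` are excluded (C undefined).  When
    ``rd`` is supplied, the linear trend of C along RD is fitted for the
    retained pairs.
    """
    sr = np.asarray(sr, dtype=float)
    agb = np.asarray(agb, dtype=float)
    if np.any(sr < 0) or np.any(agb < 0):
        raise ValueError("coupling degree requires nonnegative inputs")
    keep = (sr + agb) > 0
    c = np.full(sr.shape, np.nan)
    c[keep] = 2.0 * np.sqrt(sr[keep] * agb[keep]) / (sr[keep] + agb[keep])
    slope = p = None
    if rd is not None and int(keep.sum()) >= 3:
        rd = np.asarray(rd, dtype=float)
        res = stats.linregress(rd[keep], c[keep])
        slope, p = float(res.slope), float(res.pvalue)
    return CouplingSeries(c=c, trend_slope=slope, trend_p=p)
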