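"""Productivity-biodiversity relationship (PBR) along the RD gradient.

Resolves how the AGB-SR association changes with resource diversity:

* *at* RD levels — quantile groups of RD-sorted sites with per-group
  ordinary-least-squares slopes of SR on AGB;
* *across* RD levels — nested cumulative groups (lowest 20%, 30%, ...,
  or the mirror from the top) with standardized partial effects from
  multiple regression (AGB ~ RD + SR and SR ~ RD + AGB on z-scored
  variables);
* *along* RD — moving-window partial correlations r(AGB, SR | RD)
  plotted against each window's mean RD, in sliding or disjoint-block
  mode.

Simpson's dominance (sum of squared relative abundances) is included as
the per-site community-structure statistic used alongside the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupingScheme",
    "GroupFit",
    "PartialEffect",
    "rd_quantile_groups",
    "cumulative_groups",
    "observed_relationship",
    "partial_effects",
    "partial_correlation",
    "moving_windows",
    "window_partial_series",
    "simpsons_dominance",
]

DEFAULT_FRACTIONS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class GroupingScheme:
    mode: str  # quantile | cumulative_low | cumulative_high
    labels: list
    # label -> positional indices into the original (unsorted) site order
    assignment: dict = field(default_factory=dict)


@dataclass
class GroupFit:
    group: str
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass
class PartialEffect:
    target: str  # e.g. "RD->AGB | SR"
    coef: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def _sorted_order(rd) -> np.ndarray:
    rd = np.asarray(rd, dtype=float)
    return np.argsort(rd, kind="stable")  # stable: ties keep input order


def rd_quantile_groups(rd, g: int = 5) -> GroupingScheme:
    """Partition RD-sorted sites into ``g`` roughly equal groups.

    The first ``g - 1`` groups take ``floor(n/g)`` sites each; the last
    group absorbs the remainder (97 sites, 5 groups -> 19/19/19/19/21).
    """
    rd = np.asarray(rd, dtype=float)
    n = rd.size
    if n < g:
        raise ValueError(f"cannot split {n} sites into {g} groups")
    order = _sorted_order(rd)
    base = n // g
    assignment, labels = {}, []
    start = 0
    for i in range(g):
        size = base if i < g - 1 else n - base * (g - 1)
        label = f"Q{i + 1}"
        labels.append(label)
        assignment[label] = order[start : start + size]
        start += size
    return GroupingScheme(mode="quantile", labels=labels, assignment=assignment)


def cumulative_groups(rd, fractions: Sequence[float] = DEFAULT_FRACTIONS, from_: str = "low") -> GroupingScheme:
    """Nested groups of the lowest (or highest) ``ceil(f*n)`` RD-sorted sites."""
    rd = np.asarray(rd, dtype=float)
    fr = list(fractions)
    if any(not (0.0 < f <= 1.0) for f in fr) or any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("fractions must be strictly increasing within (0, 1]")
    if from_ not in ("low", "high"):
        raise ValueError("from_ must be 'low' or 'high'")
    order = _sorted_order(rd)
    if from_ == "high":
        order = order[::-1]
    n = rd.size
    assignment, labels = {}, []
    for f in fr:
        size = math.ceil(f * n)
        label = f"{from_}_{int(round(100 * f))}"
        labels.append(label)
        assignment[label] = order[:size]
    return GroupingScheme(mode=f"cumulative_{from_}", labels=labels, assignment=assignment)


def observed_relationship(x, y, group: str = "all", conf: float = 0.95) -> GroupFit:
    """OLS slope of the observed y ~ x relationship with a t-based CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("observed relationship needs at least 5 sites")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(x, y)
    dof = x.size - 2
    tcrit = stats.t.ppf(0.5 + conf / 2, dof)
    half = tcrit * res.stderr
    return GroupFit(
        group=group,
        slope=float(res.slope),
        ci_low=float(res.slope - half),
        ci_high=float(res.slope + half),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def _zscore(v):
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def _ols_partial(y, X, names, n, conf=0.95):
    """Standardized OLS with intercept; one PartialEffect per column of X."""
    design = sm.add_constant(X)
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=1 - conf)
    return [
        PartialEffect(
            target=name,
            coef=float(res.params[j]),
            ci_low=float(ci[j, 0]),
            ci_high=float(ci[j, 1]),
            p_value=float(res.pvalues[j]),
            n=n,
        )
        for j, name in enumerate(names, start=1)
    ]


def partial_effects(agb, sr, rd, conf: float = 0.95) -> list[PartialEffect]:
    """Standardized partial effects from the two multiple regressions.

    Returns three records: the RD coefficient from ``AGB ~ RD + SR``
    (resource effect on productivity excluding richness), and the RD and
    AGB coefficients from ``SR ~ RD + AGB`` (resource effect on richness
    excluding productivity; partial AGB-SR relationship excluding
    resources).  All variables are z-scored first.
    """
    agb = np.asarray(agb, dtype=float)
    sr = np.asarray(sr, dtype=float)
    rd = np.asarray(rd, dtype=float)
    n = agb.size
    if n < 6:
        raise ValueError("partial effects need at least 6 sites")
    z_agb, z_sr, z_rd = _zscore(agb), _zscore(sr), _zscore(rd)
    if abs(np.corrcoef(z_rd, z_agb)[0, 1]) >= 1.0 - 1e-12:
        raise ValueError("RD and AGB are perfectly collinear")
    eff_agb = _ols_partial(z_agb, np.column_stack([z_rd, z_sr]), ["RD->AGB | SR", "SR->AGB | RD"], n, conf)
    eff_sr = _ols_partial(z_sr, np.column_stack([z_rd, z_agb]), ["RD->SR | AGB", "AGB->SR | RD"], n, conf)
    return [eff_agb[0], eff_sr[0], eff_sr[1]]


def partial_correlation(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r(x, y | z) and its p-value.

    ``r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``;
    the p-value is from ``t = r*sqrt((n-3)/(1-r^2))`` on n-3 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("partial correlation needs at least 5 observations")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("a control correlation of |1| leaves no residual variation")
    r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 3) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), n - 3))
    return r, p


def moving_windows(n: int, w: int, mode: str = "block") -> list[np.ndarray]:
    """Index windows along RD-sorted sites.

    ``sliding``: every run of ``w`` consecutive sites (step 1).
    ``block``: disjoint consecutive blocks of ``w`` sites; if ``n`` is
    not divisible by ``w`` the final window is the last ``w`` sites and
    overlaps the previous block (97 sites, w=10 -> windows 1-10, 11-20,
    ..., 81-90, 88-97).
    """
    if not 5 <= w <= n:
        raise ValueError(f"window size must satisfy 5 <= w <= n, got w={w}, n={n}")
    if mode == "sliding":
        return [np.arange(s, s + w) for s in range(n - w + 1)]
    if mode == "block":
        starts = list(range(0, n - w + 1, w))
        windows = [np.arange(s, s + w) for s in starts]
        if starts[-1] + w < n:
            windows.append(np.arange(n - w, n))
        return windows
    raise ValueError("mode must be 'sliding' or 'block'")


def window_partial_series(
    rd, agb, sr, w: int = 10, mode: str = "block"
) -> pd.DataFrame:
    """Moving-window partial correlations r(AGB, SR | RD) along RD.

    Sites are sorted ascending by RD; each window contributes its mean
    RD and the within-window partial correlation.  Degenerate windows
    (zero variance or perfect control correlation) are flagged via the
    ``valid`` column rather than dropped.
    """
    rd = np.asarray(rd, dtype=float)
    agb = np.asarray(agb, dtype=float)
    sr = np.asarray(sr, dtype=float)
    order = _sorted_order(rd)
    rd_s, agb_s, sr_s = rd[order], agb[order], sr[order]
    rows = []
    for i, idx in enumerate(moving_windows(rd.size, w, mode)):
        try:
            r, p = partial_correlation(agb_s[idx], sr_s[idx], rd_s[idx])
            valid = np.isfinite(r)
        except ValueError:
            r, p, valid = np.nan, np.nan, False
        rows.append(
            {
                "window_id": i,
                "start": int(idx[0]),
                "end": int(idx[-1]),
                "mean_rd": float(rd_s[idx].mean()),
                "partial_r": r,
                "p_value": p,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)


def simpsons_dominance(p: Sequence[float]) -> float:
    """Simpson's dominance ``D = sum(p_i^2)`` of a relative-abundance vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("relative abundances must be nonnegative")
    total = float(p.sum())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"relative abundances must sum to 1 (observed sum {total:.12g})")
    return float(np.sum(p**2))
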