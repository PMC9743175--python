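"""Radar-chart resource-diversity indices (RR, RE, RD).

A site's resource profile (e.g. mean annual precipitation plus soil
TOC/TN/TP) is standardized across sites, shifted to positive radii, and
drawn as a radar chart of equal-angle sectors, one sector per resource.
From the chart's total sector area ``S`` and perimeter ``L`` the module
derives

* resource richness  ``RR = S / max(S)``   (area, max-normalized to 1),
* resource evenness  ``RE = 4*pi*S / L**2`` (isoperimetric ratio, 1 when
  all radii are equal),
* resource diversity ``RD = sqrt(RR * RE)`` (geometric mean).

Radii are sorted ascending before chart construction, so the exposed
radial segments of the boundary total exactly ``2*(r_max - r_min)``.

Two geometry conventions are available.  The default ``"sector"`` mode
assigns each resource an equal sector of angle ``2*pi/n``:
``S = (pi/n) * sum(r_j**2)`` and ``L = 2*(r_max - r_min) +
(2*pi/n) * sum(r_j)``, under which RE attains 1 exactly at perfect
evenness.  The ``"as_printed"`` mode instead sums one full circle per
resource (``pi*r**2`` and ``2*pi*r``); it is retained for comparison but
caps RE at ``1/n`` for even profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedRadii",
    "ChartGeometry",
    "standardize",
    "chart_geometry",
    "resource_richness",
    "resource_evenness",
    "resource_diversity_index",
    "compute_indices",
]

GEOMETRY_MODES = ("sector", "as_printed")
SD_MODES = ("sample", "population")


@dataclass
class StandardizedRadii:
    """Z-scored, positivity-shifted resource radii for a set of sites."""

    radii: np.ndarray  # (n_sites, n_resources), strictly positive
    shift: float
    sites: list = field(default_factory=list)
    resources: list = field(default_factory=list)


@dataclass
class ChartGeometry:
    """Area and perimeter of one site's radar chart."""

    S: float
    L: float
    sorted_radii: np.ndarray
    mode: str = "sector"


def _as_matrix(matrix) -> tuple[np.ndarray, list, list]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("resource matrix must be 2-dimensional (sites x resources)")
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def standardize(
    matrix,
    shift: Union[float, str] = 2.0,
    sd_mode: str = "sample",
) -> StandardizedRadii:
    """Z-score each resource column and shift to strictly positive radii.

    Parameters
    ----------
    matrix
        Site-by-resource table (DataFrame or 2-D array), natural units.
    shift
        Positive constant added to every z-score.  The string ``"auto"``
        selects the smallest integer >= 2 that makes every radius
        strictly positive (the "smallest integer" rule applied to the
        data at hand).
    sd_mode
        ``"sample"`` (ddof=1, default) or ``"population"`` (ddof=0).

    Raises
    ------
    ValueError
        On a zero-variance column (named), non-finite input, fewer than
        2 sites, or a numeric shift too small to keep all radii positive
        (the message reports the minimum z-score and the required shift).
    """
    values, sites, resources = _as_matrix(matrix)
    if values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 sites")
    if not np.all(np.isfinite(values)):
        raise ValueError("resource matrix contains non-finite values")
    if sd_mode not in SD_MODES:
        raise ValueError(f"sd_mode must be one of {SD_MODES}, got {sd_mode!r}")

    ddof = 1 if sd_mode == "sample" else 0
    sd = values.std(axis=0, ddof=ddof)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"zero variance in resource column {resources[j]!r}")
    z = (values - values.mean(axis=0)) / sd

    min_z = float(z.min())
    if shift == "auto":
        shift_val = float(max(2, math.floor(-min_z) + 1))
    else:
        shift_val = float(shift)
        if shift_val <= 0:
            raise ValueError("shift must be positive")
        if min_z + shift_val <= 0:
            raise ValueError(
                f"minimum z-score {min_z:.4f} gives non-positive radius with "
                f"shift {shift_val:g}; a shift > {-min_z:.4f} is required"
            )
    return StandardizedRadii(radii=z + shift_val, shift=shift_val, sites=sites, resources=resources)


def chart_geometry(radii: Sequence[float], mode: str = "sector") -> ChartGeometry:
    """Area ``S`` and perimeter ``L`` of one site's radar chart.

    Radii are sorted ascending; each of the ``n`` resources occupies an
    equal sector.  With a single resource the chart is a full circle in
    either mode.
    """
    if mode not in GEOMETRY_MODES:
        raise ValueError(f"geometry mode must be one of {GEOMETRY_MODES}, got {mode!r}")
    r = np.sort(np.asarray(radii, dtype=float))
    if r.size == 0:
        raise ValueError("at least one radius required")
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("all radii must be positive and finite")
    n = r.size
    radial = 2.0 * (r[-1] - r[0])
    if mode == "sector":
        S = (math.pi / n) * float(np.sum(r**2))
        L = radial + (2.0 * math.pi / n) * float(np.sum(r))
    else:  # as_printed: one full circle per resource
        S = math.pi * float(np.sum(r**2))
        L = radial + 2.0 * math.pi * float(np.sum(r))
    return ChartGeometry(S=S, L=L, sorted_radii=r, mode=mode)


def resource_richness(areas: Sequence[float]) -> np.ndarray:
    """Max-normalized chart areas: ``RR_i = S_i / max_i S_i``."""
    S = np.asarray(areas, dtype=float)
    if S.size == 0:
        raise ValueError("resource_richness needs at least one site")
    if np.any(S <= 0):
        raise ValueError("all areas must be positive")
    return S / S.max()


def resource_evenness(geometry: ChartGeometry) -> float:
    """Isoperimetric evenness ``RE = 4*pi*S / L**2``."""
    return 4.0 * math.pi * geometry.S / geometry.L**2


def resource_diversity_index(rr, re) -> np.ndarray:
    """Geometric mean ``RD = sqrt(RR * RE)``."""
    rr = np.asarray(rr, dtype=float)
    re = np.asarray(re, dtype=float)
    if np.any(rr <= 0) or np.any(re <= 0):
        raise ValueError("RR and RE must be strictly positive")
    return np.sqrt(rr * re)


def compute_indices(
    matrix,
    shift: Union[float, str] = 2.0,
    sd_mode: str = "sample",
    geometry: str = "sector",
) -> pd.DataFrame:
    """Full per-site index table: columns ``S, L, RR, RE, RD``.

    Composes :func:`standardize`, :func:`chart_geometry` per site,
    :func:`resource_richness`, :func:`resource_evenness` and
    :func:`resource_diversity_index`.
    """
    std = standardize(matrix, shift=shift, sd_mode=sd_mode)
    geoms = [chart_geometry(row, mode=geometry) for row in std.radii]
    S = np.array([g.S for g in geoms])
    L = np.array([g.L for g in geoms])
    rr = resource_richness(S)
    re = np.array([resource_evenness(g) for g in geoms])
    rd = resource_diversity_index(rr, re)
    return pd.DataFrame(
        {"S": S, "L": L, "RR": rr, "RE": re, "RD": rd},
        index=pd.Index(std.sites, name="site_id"),
    )
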