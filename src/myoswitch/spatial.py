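"""Spatial statistics: nearest-neighbour distance as a density proxy.

The microscopy analysis exports one row per segmented cell (planar
coordinates plus one or more fluorescence intensity channels).  The
distance from each cell to its closest neighbour estimates the local
cell density (small distance = dense neighbourhood); intensity is then
related to that proxy by a LOWESS curve and Spearman's rank correlation.
A *negative* rho therefore means intensity *rises* with local density,
the direction reported for both the CD56 and the superoxide channels.

Tables are plain pandas DataFrames with columns ``id, x, y`` plus one
column per channel; coordinates are used in their stated units (microns
for microscopy exports, world units for simulation snapshots) and never
rescaled.  The metric is plain Euclidean with no periodic wrap.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import (
    DomainError,
    ParameterError,
    UndefinedCorrelationError,
    UndefinedResultError,
)

__all__ = [
    "CorrelationResult",
    "LowessFit",
    "DensityIntensityReport",
    "nn_distances",
    "lowess_curve",
    "spearman",
    "positive_fraction",
    "density_intensity_report",
]

EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "approximate"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ParameterError(f"|rho| must be <= 1, got {self.rho}")


@dataclass(frozen=True)
class LowessFit:
    x_sorted: np.ndarray
    fitted: np.ndarray
    frac: float
    iterations: int


@dataclass(frozen=True)
class DensityIntensityReport:
    """Composite spatial report for one intensity channel.

    ``rho < 0`` means intensity increases with local density (shorter
    nearest-neighbour distances carry brighter cells).
    """

    channel: str
    nn_dist: np.ndarray
    lowess: LowessFit
    correlation: CorrelationResult
    positive_fraction: float
    background: float

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "n": self.correlation.n,
            "rho": self.correlation.rho,
            "p_value": self.correlation.p_value,
            "p_value_method": self.correlation.method,
            "positive_fraction": self.positive_fraction,
            "background": self.background,
            "sign_convention": (
                "negative rho indicates intensity rising with local cell density"
            ),
        }


def _coords(table: pd.DataFrame) -> np.ndarray:
    for col in ("x", "y"):
        if col not in table.columns:
            raise DomainError(f"cell table lacks required column {col!r}")
    xy = table[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise DomainError("coordinates must be finite")
    return xy


def nn_distances(table: pd.DataFrame) -> np.ndarray:
    """Per-cell distance to the closest other cell (Euclidean, no wrap)."""
    xy = _coords(table)
    n = len(xy)
    if n < 2:
        raise UndefinedResultError("nearest-neighbour distances require at least 2 cells")
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=2)
    out = dist[:, 1]
    if np.any(out == 0):
        warnings.warn("duplicate coordinates give nearest-neighbour distance 0", stacklevel=2)
    return out


def lowess_curve(x, y, frac: float = 2.0 / 3.0, iterations: int = 3) -> LowessFit:
    """Tricube-weighted robust local linear regression of y on x.

    Classical LOWESS: a local linear fit in a window containing a
    fraction ``frac`` of the data, with ``iterations`` bisquare
    robustifying passes, evaluated at the sorted x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if len(x) < 5:
        raise UndefinedResultError("lowess requires at least 5 points")
    if not 0 < frac <= 1:
        raise ParameterError(f"frac must be in (0, 1], got {frac}")
    if iterations < 0:
        raise ParameterError(f"iterations must be >= 0, got {iterations}")
    if np.ptp(x) == 0:
        raise UndefinedResultError("lowess requires non-zero spread in x")
    fitted = _sm_lowess(y, x, frac=frac, it=iterations, return_sorted=True)
    return LowessFit(
        x_sorted=fitted[:, 0], fitted=fitted[:, 1], frac=frac, iterations=iterations
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value by full enumeration of rank orders."""
    n = len(rx)
    denom_x = np.sum((rx - rx.mean()) ** 2)
    denom_y = np.sum((ry - ry.mean()) ** 2)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    count = 0
    total = 0
    scale = math.sqrt(denom_x * denom_y)
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(cx[list(perm)], cy)) / scale
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    The two-sided p-value is computed by exhaustive permutation
    enumeration for n <= 8 and by the large-sample approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise UndefinedResultError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined: an input has zero variance")
    rx = stats.rankdata(x)  # mid-ranks
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        res = stats.spearmanr(x, y)
        p = float(res.pvalue)
        method = "approximate"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return CorrelationResult(rho=rho, p_value=p, n=n, method=method)


def positive_fraction(intensities, background: float) -> float:
    """Fraction of cells with intensity strictly above the background level."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 1 or len(intensities) < 1:
        raise DomainError("intensities must be a non-empty 1-D vector")
    if background < 0:
        raise ParameterError(f"background must be >= 0, got {background}")
    return float(np.mean(intensities > background))


def density_intensity_report(
    table: pd.DataFrame,
    channel: str = "I",
    frac: float = 2.0 / 3.0,
    iterations: int = 3,
    background: float = 0.0,
) -> DensityIntensityReport:
    """Full density-vs-intensity analysis of one channel.

    Computes nearest-neighbour distances, the LOWESS curve of intensity
    against that density proxy, the Spearman correlation between the two,
    and the fraction of cells above the intensity background.
    """
    if channel not in table.columns:
        raise DomainError(f"channel {channel!r} not present in the cell table")
    if len(table) < 5:
        raise UndefinedResultError("density-intensity report requires at least 5 cells")
    d = nn_distances(table)
    intensity = table[channel].to_numpy(dtype=float)
    fit = lowess_curve(d, intensity, frac=frac, iterations=iterations)
    corr = spearman(d, intensity)
    return DensityIntensityReport(
        channel=channel,
        nn_dist=d,
        lowess=fit,
        correlation=corr,
        positive_fraction=positive_fraction(intensity, background),
        background=background,
    )
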