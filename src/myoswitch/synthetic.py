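"""Synthetic inputs with the statistical structure the analysis assumes.

The microscopy stage of the pipeline needs planar point patterns with
heterogeneous local density and per-cell intensities whose dependence on
local density is known.  A Thomas cluster process (Poisson parents, each
with a Poisson number of Gaussian-scattered offspring, plus optional
Poisson background points) provides controllable, analytically
characterised clustering; planting an intensity that decreases linearly
in the nearest-neighbour distance (slope ``beta1 > 0``) reproduces the
observed direction of the density effect, i.e. a negative Spearman rho
between intensity and nearest-neighbour distance.

A velocity fixture with exponentially distributed magnitudes mirrors the
empirical speed distribution used to calibrate the migration model
(16000 observed values by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, UndefinedResultError
from .spatial import nn_distances

__all__ = [
    "ClusterPatternParams",
    "IntensityModel",
    "gen_cluster_pattern",
    "plant_intensity",
    "gen_velocity_fixture",
]


@dataclass(frozen=True)
class ClusterPatternParams:
    """Thomas cluster process parameters.

    window    -- (width, height) of the observation window, length units
    kappa     -- parent intensity per unit area
    mu        -- mean offspring per parent
    sigma     -- isotropic Gaussian dispersion of offspring around parents
    lambda_bg -- intensity of additional homogeneous background points
    seed      -- generator seed (all output is deterministic given it)
    """

    window: tuple[float, float] = (1000.0, 1000.0)
    kappa: float = 5e-5
    mu: float = 40.0
    sigma: float = 30.0
    lambda_bg: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ConfigurationError(f"window must have positive area, got {self.window}")
        if self.kappa < 0 or self.mu < 0 or self.lambda_bg < 0:
            raise ParameterError("kappa, mu and lambda_bg must be >= 0")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class IntensityModel:
    """Linear planted dependence of intensity on nearest-neighbour distance.

    ``I = max(0, beta0 - beta1 * nn_dist + Normal(0, noise_sd))``; with
    beta1 > 0 the planted Spearman rho(I, nn_dist) is negative — the
    observed direction (bright cells in dense regions).
    """

    beta0: float = 100.0
    beta1: float = 1.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


def gen_cluster_pattern(params: ClusterPatternParams) -> pd.DataFrame:
    """Sample a Thomas-type clustered point pattern.

    Parents ~ Poisson(kappa * area) uniform in the window; each parent
    gets Poisson(mu) offspring displaced by Gaussian(sigma) and clipped
    to the window; background points ~ Poisson(lambda_bg * area).  The
    expected total count is ``area * (kappa * mu + lambda_bg)``.
    Returns a cell table with columns id, x, y.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.window
    area = w * h
    n_parents = rng.poisson(params.kappa * area)
    px = rng.uniform(0, w, size=n_parents)
    py = rng.uniform(0, h, size=n_parents)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for k in range(n_parents):
        m = rng.poisson(params.mu)
        if m == 0:
            continue
        ox = px[k] + rng.normal(0.0, params.sigma, size=m)
        oy = py[k] + rng.normal(0.0, params.sigma, size=m)
        keep = (ox >= 0) & (ox < w) & (oy >= 0) & (oy < h)
        xs.append(ox[keep])
        ys.append(oy[keep])
    n_bg = rng.poisson(params.lambda_bg * area)
    if n_bg:
        xs.append(rng.uniform(0, w, size=n_bg))
        ys.append(rng.uniform(0, h, size=n_bg))
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    return pd.DataFrame({"id": np.arange(len(x), dtype=np.int64), "x": x, "y": y})


def plant_intensity(table: pd.DataFrame, model: IntensityModel) -> pd.DataFrame:
    """Add an intensity channel "I" with a planted density dependence."""
    if len(table) < 2:
        raise UndefinedResultError(
            "planting an intensity requires at least 2 cells (nn distance undefined)"
        )
    rng = np.random.default_rng(model.seed)
    d = nn_distances(table)
    eps = rng.normal(0.0, model.noise_sd, size=len(d)) if model.noise_sd > 0 else 0.0
    out = table.copy()
    out["I"] = np.maximum(0.0, model.beta0 - model.beta1 * d + eps)
    return out


def gen_velocity_fixture(
    n: int = 16000, mean_speed: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Exponential velocity-magnitude fixture (empirical sample size 16000)."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if mean_speed <= 0:
        raise ParameterError(f"mean_speed must be > 0, got {mean_speed}")
    rng = np.random.default_rng(seed)
    return rng.exponential(mean_speed, size=n)
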