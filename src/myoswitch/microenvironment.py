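"""Gridded diffusible resource R: the cells' density sensor.

The virtual dish is divided into square patches.  Each patch carries a
concentration of a diffusible substance R (no chemical identity is
assumed), initially ``R0 = 100`` everywhere.  Each step, every cell
removes ``u`` units from its patch; the patch then relaxes toward the
medium concentration at rate ``D_med`` and mixes with its 8 neighbours at
rate ``D_lat``.  Where uptake outpaces replenishment R drops, so local
depletion reads out local cell density:  ``d_hat = 1 - R / R0``.

With ``D_lat = 0`` and a constant per-step drain ``u * n`` the per-patch
equilibrium is ``R* = R0 - u * n / D_med`` (clamped at 0), the
"equilibrium between consumption and diffusion from the medium".

Positions map to patches by half-open intervals
``[k * patch_size, (k+1) * patch_size)``.  The field does not wrap: the
outermost ring exchanges laterally only with its existing neighbours, and
with the medium through ``D_med``, even though cell *motion* is periodic
(the medium, not the opposite edge, is the reservoir).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate

from .errors import DomainError, ParameterError

__all__ = [
    "FieldParams",
    "ResourceField",
    "apply_uptake",
    "apply_replenishment",
    "local_R",
    "local_R_many",
    "density_hat",
    "write_field",
    "read_field",
]

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class FieldParams:
    """Resource-field coefficients.

    R0         -- medium concentration (resource units), default 100
    D_med      -- per-step relaxation rate toward R0, in (0, 1]
    D_lat      -- per-step lateral 8-neighbour mixing weight, in [0, 1)
    u          -- resource units removed per cell per step
    patch_size -- world length units per patch edge
    """

    R0: float = 100.0
    D_med: float = 0.1
    D_lat: float = 0.2
    u: float = 4.89
    patch_size: float = 1.0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ParameterError(f"R0 must be > 0, got {self.R0}")
        if not 0 < self.D_med <= 1:
            raise ParameterError(f"D_med must be in (0, 1], got {self.D_med}")
        if not 0 <= self.D_lat < 1:
            raise ParameterError(f"D_lat must be in [0, 1), got {self.D_lat}")
        if self.D_med + self.D_lat > 1:
            raise ParameterError(
                f"D_med + D_lat must be <= 1, got {self.D_med + self.D_lat}"
            )
        if self.u <= 0:
            raise ParameterError(f"u must be > 0, got {self.u}")
        if self.patch_size <= 0:
            raise ParameterError(f"patch_size must be > 0, got {self.patch_size}")


@dataclass
class ResourceField:
    """Patch grid of resource concentrations.

    ``grid[i, j]`` holds the concentration of the patch whose lower-left
    corner is at ``(i * patch_size, j * patch_size)``.
    """

    grid: np.ndarray
    params: FieldParams

    @classmethod
    def uniform(cls, nx: int, ny: int, params: FieldParams | None = None) -> "ResourceField":
        params = params or FieldParams()
        if nx < 1 or ny < 1:
            raise ParameterError(f"grid dimensions must be >= 1, got {nx}x{ny}")
        return cls(grid=np.full((nx, ny), params.R0, dtype=float), params=params)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def world_size(self) -> tuple[float, float]:
        nx, ny = self.grid.shape
        ps = self.params.patch_size
        return nx * ps, ny * ps

    def patch_indices(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map positions to patch indices (half-open patch convention)."""
        ps = self.params.patch_size
        wx, wy = self.world_size
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if np.any(~np.isfinite(xs)) or np.any(~np.isfinite(ys)):
            raise DomainError("positions must be finite")
        if np.any(xs < 0) or np.any(xs >= wx) or np.any(ys < 0) or np.any(ys >= wy):
            raise DomainError(f"position outside the {wx}x{wy} world")
        return (xs // ps).astype(np.intp), (ys // ps).astype(np.intp)


def apply_uptake(field: ResourceField, positions: np.ndarray) -> ResourceField:
    """Each cell removes ``u`` from its patch; concentrations clamp at 0."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    grid = field.grid.copy()
    if len(positions):
        ix, iy = field.patch_indices(positions[:, 0], positions[:, 1])
        drain = np.zeros_like(grid)
        np.add.at(drain, (ix, iy), field.params.u)
        grid = np.maximum(0.0, grid - drain)
    return dataclasses.replace(field, grid=grid)


def apply_replenishment(field: ResourceField) -> ResourceField:
    """Relax toward the medium and mix laterally.

    ``R' = R + D_med (R0 - R) + D_lat (mean of existing 8-neighbours - R)``
    clamped to [0, R0].  Edge patches average over the neighbours they
    actually have (5 on an edge, 3 in a corner); there is no wrap.
    """
    p = field.params
    grid = field.grid
    nbr_sum = correlate(grid, _NEIGHBOUR_KERNEL, mode="constant", cval=0.0)
    nbr_count = correlate(np.ones_like(grid), _NEIGHBOUR_KERNEL, mode="constant", cval=0.0)
    # a 1x1 grid has no lateral neighbours; treat its "mean" as itself
    nbr_mean = np.divide(nbr_sum, nbr_count, out=grid.astype(float).copy(), where=nbr_count > 0)
    new = grid + p.D_med * (p.R0 - grid) + p.D_lat * (nbr_mean - grid)
    return dataclasses.replace(field, grid=np.clip(new, 0.0, p.R0))


def local_R(field: ResourceField, position: tuple[float, float]) -> float:
    """Concentration of the patch containing ``position`` (no interpolation)."""
    ix, iy = field.patch_indices(np.array([position[0]]), np.array([position[1]]))
    return float(field.grid[ix[0], iy[0]])


def local_R_many(field: ResourceField, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    ix, iy = field.patch_indices(xs, ys)
    return field.grid[ix, iy]


def density_hat(R, R0):
    """Local density proxy ``clamp(1 - R/R0, 0, 1)``: 0 at R0, 1 at full depletion."""
    if np.any(np.asarray(R0) <= 0):
        raise ParameterError(f"R0 must be > 0, got {R0}")
    if np.any(np.asarray(R) < 0):
        raise DomainError(f"R must be >= 0, got {R}")
    return np.clip(1.0 - np.asarray(R, dtype=float) / R0, 0.0, 1.0)


def write_field(field: ResourceField, path: str | Path, step: int = 0) -> None:
    """Export the grid as a delimited-text matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, field.grid, delimiter="\t")
    sidecar = {
        "patch_size": field.params.patch_size,
        "R0": field.params.R0,
        "step": step,
        "shape": list(field.grid.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_field(path: str | Path, params: FieldParams | None = None) -> ResourceField:
    path = Path(path)
    grid = np.loadtxt(path, delimiter="\t")
    if grid.ndim == 1:
        grid = grid[None, :]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if params is None:
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            params = FieldParams(R0=meta["R0"], patch_size=meta["patch_size"])
        else:
            params = FieldParams()
    return ResourceField(grid=grid, params=params)
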