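"""Cell migration, nematic alignment, cell cycle and division.

Migration follows the phenomenology of time-lapse recordings of myoblast
cultures: solitary cells perform an unbiased random walk with
exponentially distributed step lengths, while cells with at least one
neighbour within ``r_align`` align the *axis* of their motion with those
neighbours and pick the forward or backward direction along it at random
("random in a single dimension").  The axis is the half-angle of the
resultant of doubled headings, the standard nematic construction, so
headings theta and theta+pi reinforce rather than cancel.  Speed is
always drawn independently of the neighbourhood.

Cells divide after a cycle of 20-24 steps (1 step ~ 1 hour) provided the
local neighbourhood is below a crowding cap; crowded mothers hold their
clock and retry.  Daughters stay within one patch width of the mother and
inherit her phenotype level exactly.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError, UndefinedResultError
from .model_core import PhenotypeState

__all__ = [
    "Cell",
    "MotilityParams",
    "PopulationParams",
    "periodic_delta",
    "periodic_distance",
    "neighbor_set",
    "update_heading",
    "mean_axis",
    "step_speed",
    "advance_position",
    "advance_cycle",
    "nematic_order",
    "nematic_order_arrays",
]


@dataclass
class Cell:
    """One agent: position, heading, cycle state and phenotype."""

    id: int
    position: tuple[float, float]
    heading: float
    cycle_clock: int
    cycle_length: int
    state: PhenotypeState
    founder_class: str = "mixed"


@dataclass(frozen=True)
class MotilityParams:
    """Migration and alignment coefficients.

    r_align           -- alignment neighbourhood radius (world units)
    eta               -- angular noise sd added to the aligned axis (rad)
    mean_speed        -- mean of the exponential step-length distribution
                         (world units per step)
    alignment_enabled -- disable for the random-migration ablation
    polar             -- Vicsek-style polar alignment instead of nematic
                         (comparison variant, off by default)
    """

    r_align: float = 1.5
    eta: float = 0.2
    mean_speed: float = 0.5
    alignment_enabled: bool = True
    polar: bool = False

    def __post_init__(self) -> None:
        if self.r_align <= 0:
            raise ParameterError(f"r_align must be > 0, got {self.r_align}")
        if self.eta < 0:
            raise ParameterError(f"eta must be >= 0, got {self.eta}")
        if self.mean_speed <= 0:
            raise ParameterError(f"mean_speed must be > 0, got {self.mean_speed}")


@dataclass(frozen=True)
class PopulationParams:
    """Cell-cycle and crowding parameters.

    cycle_min, cycle_max -- inclusive bounds of the uniform integer cell
                            cycle length (steps; 20-24 ~ 20-24 h)
    crowding_cap         -- division proceeds only while the number of
                            cells in the (2*crowd_radius+1)^2-patch
                            neighbourhood is below this cap
    crowd_radius         -- neighbourhood half-width in patches
    R_div                -- minimal local resource concentration for
                            division: proliferation consumes the same
                            limiting substance the cells sense, so a
                            depleted patch defers division exactly like a
                            crowded one.  This pins the saturated
                            population density to the resource level
                            rather than to count fluctuations.
    death_rate           -- per-step removal probability; a small
                            constant turnover balances the division flux
                            at saturation
    """

    cycle_min: int = 20
    cycle_max: int = 24
    crowding_cap: int = 26
    crowd_radius: int = 2
    R_div: float = 27.0
    death_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.cycle_min > self.cycle_max:
            raise ParameterError(
                f"cycle_min must be <= cycle_max, got {self.cycle_min} > {self.cycle_max}"
            )
        if self.cycle_min < 1:
            raise ParameterError(f"cycle_min must be >= 1, got {self.cycle_min}")
        if self.crowding_cap < 1:
            raise ParameterError(f"crowding_cap must be >= 1, got {self.crowding_cap}")
        if self.crowd_radius < 0:
            raise ParameterError(f"crowd_radius must be >= 0, got {self.crowd_radius}")
        if self.R_div < 0:
            raise ParameterError(f"R_div must be >= 0, got {self.R_div}")
        if not 0 <= self.death_rate < 1:
            raise ParameterError(f"death_rate must be in [0, 1), got {self.death_rate}")


def periodic_delta(a: np.ndarray, b: np.ndarray, length: float) -> np.ndarray:
    """Signed minimal displacement b - a on a circle of circumference ``length``."""
    d = (np.asarray(b) - np.asarray(a)) % length
    return np.where(d > length / 2.0, d - length, d)


def periodic_distance(p: Sequence[float], q: Sequence[float], world: tuple[float, float]) -> float:
    dx = periodic_delta(p[0], q[0], world[0])
    dy = periodic_delta(p[1], q[1], world[1])
    return float(np.hypot(dx, dy))


def neighbor_set(
    cells: Sequence[Cell], focal: Cell, radius: float, world: tuple[float, float]
) -> list[Cell]:
    """Cells other than ``focal`` within periodic distance <= radius (closed ball)."""
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    return [
        c
        for c in cells
        if c is not focal and periodic_distance(focal.position, c.position, world) <= radius
    ]


def mean_axis(headings: np.ndarray) -> float | None:
    """Nematic mean axis: half the argument of sum(exp(2i*theta)).

    Returns None when the doubled-angle resultant vanishes (perfectly
    balanced axes), which callers treat as "keep the previous heading".
    """
    z = np.exp(2j * np.asarray(headings, dtype=float)).sum()
    if abs(z) < 1e-12:
        return None
    return cmath.phase(z) / 2.0


def update_heading(
    focal: Cell,
    neighbours: Sequence[Cell],
    mp: MotilityParams,
    rng: np.random.Generator,
) -> float:
    """New heading for one cell.

    Without neighbours (or with alignment disabled) the heading is drawn
    uniformly on [0, 2*pi).  Otherwise the cell adopts the nematic mean
    axis of its neighbours' headings, perturbed by Normal(0, eta) angular
    noise, and moves forward or backward along it with probability 1/2
    each.  In the polar variant the circular mean direction is used and
    no direction flip is applied.
    """
    if not neighbours or not mp.alignment_enabled:
        return float(rng.uniform(0.0, 2.0 * math.pi))
    headings = np.array([c.heading for c in neighbours], dtype=float)
    if mp.polar:
        z = np.exp(1j * headings).sum()
        if abs(z) < 1e-12:
            return focal.heading
        angle = cmath.phase(z) + rng.normal(0.0, mp.eta)
        return float(angle % (2.0 * math.pi))
    axis = mean_axis(headings)
    if axis is None:
        return focal.heading
    angle = axis + rng.normal(0.0, mp.eta)
    if rng.random() < 0.5:
        angle += math.pi
    return float(angle % (2.0 * math.pi))


def step_speed(mp: MotilityParams, rng: np.random.Generator) -> float:
    """Exponential step length with mean ``mean_speed`` (matches the
    exponential distribution of observed velocity magnitudes)."""
    return float(rng.exponential(mp.mean_speed))


def advance_position(
    position: Sequence[float], heading: float, speed: float, world: tuple[float, float]
) -> tuple[float, float]:
    """Move along the heading and wrap periodically into the world."""
    x = (position[0] + speed * math.cos(heading)) % world[0]
    y = (position[1] + speed * math.sin(heading)) % world[1]
    return (x, y)


def advance_cycle(
    cell: Cell,
    local_count: int,
    pp: PopulationParams,
    rng: np.random.Generator,
    world: tuple[float, float],
    patch_size: float = 1.0,
    id_start: int | None = None,
    local_R: float | None = None,
) -> list[Cell]:
    """Advance one cell's cycle clock; divide or die as appropriate.

    Death (if enabled) is resolved first.  A cell whose clock has reached
    its cycle length divides when ``local_count < crowding_cap`` and the
    local resource (if supplied) is at least ``R_div``: it is replaced by
    two daughters at the mother's position jittered within one patch
    width, each inheriting P and founder class, with clock 0 and a fresh
    cycle length uniform on [cycle_min, cycle_max].  A crowded or
    resource-starved mother keeps her clock at the cycle length and
    retries next step.
    """
    if pp.death_rate > 0 and rng.random() < pp.death_rate:
        return []
    clock = min(cell.cycle_clock + 1, cell.cycle_length)
    if clock >= cell.cycle_length:
        if local_count < pp.crowding_cap and (local_R is None or local_R >= pp.R_div):
            base = cell.id if id_start is None else id_start
            daughters = []
            for k in range(2):
                jitter = rng.uniform(-patch_size / 2.0, patch_size / 2.0, size=2)
                pos = (
                    (cell.position[0] + jitter[0]) % world[0],
                    (cell.position[1] + jitter[1]) % world[1],
                )
                daughters.append(
                    Cell(
                        id=base + k,
                        position=pos,
                        heading=cell.heading,
                        cycle_clock=0,
                        cycle_length=int(rng.integers(pp.cycle_min, pp.cycle_max + 1)),
                        state=PhenotypeState(
                            P=cell.state.P, phenotype_class=cell.state.phenotype_class
                        ),
                        founder_class=cell.founder_class,
                    )
                )
            return daughters
        return [replace(cell, cycle_clock=cell.cycle_length)]
    return [replace(cell, cycle_clock=clock)]


def nematic_order_arrays(
    xs: np.ndarray,
    ys: np.ndarray,
    headings: np.ndarray,
    radius: float,
    world: tuple[float, float],
) -> float:
    """Nematic order parameter of a population snapshot.

    Mean over cells (with at least one neighbour within ``radius``) of
    the modulus of the neighbour average of exp(2i*theta): 1 for a single
    shared axis, near 0 for uniform random headings in large
    neighbourhoods.
    """
    from scipy.spatial import cKDTree

    n = len(xs)
    if n < 2:
        raise UndefinedResultError("nematic order requires at least 2 cells")
    pts = np.column_stack([np.mod(xs, world[0]), np.mod(ys, world[1])])
    tree = cKDTree(pts, boxsize=world)
    z = np.exp(2j * np.asarray(headings, dtype=float))
    acc = np.zeros(n, dtype=complex)
    counts = np.zeros(n, dtype=float)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(acc, i, z[j])
        np.add.at(acc, j, z[i])
        np.add.at(counts, i, 1.0)
        np.add.at(counts, j, 1.0)
    has = counts > 0
    if not np.any(has):
        raise UndefinedResultError("no cell has a neighbour within the radius")
    return float(np.mean(np.abs(acc[has] / counts[has])))


def nematic_order(cells: Sequence[Cell], radius: float, world: tuple[float, float]) -> float:
    if len(cells) < 2:
        raise UndefinedResultError("nematic order requires at least 2 cells")
    xs = np.array([c.position[0] for c in cells])
    ys = np.array([c.position[1] for c in cells])
    headings = np.array([c.heading for c in cells])
    return nematic_order_arrays(xs, ys, headings, radius, world)
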