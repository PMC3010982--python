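"""Population simulator and in-silico sorting experiments.

One simulation step applies, in a fixed order:

1. resource uptake by every cell at its current patch,
2. field replenishment (relaxation to the medium + lateral mixing),
3. heading, speed and position updates (periodic world),
4. phenotype updates of every cell against the freshly updated field at
   its new position,
5. cycle advance, division under the crowding cap, and optional death.

Snapshots and per-step summary series are recorded after step 5.

The in-silico sorting experiment mirrors the flow-sorting protocol: two
simulations differ only in the founder phenotype (all-low vs all-high,
each founder started at the corresponding stable fixed point of the
baseline dynamics).  ``S_low(t)`` is the fraction of the low-founder
lineage currently classified high, ``S_high(t)`` the fraction of the
high-founder lineage classified low, and ``delta_S = S_high - S_low``
(positive when sorted high-P founders convert more).

Parameter sweeps tile a plane of two of {C_B, N_int, N_ext} with paired
sorting runs and classify each grid cell into three regimes: *grey* (no
conversion), *blue* (delta_S > 0) or *red* (delta_S < 0).  When the two
noise amplitudes are swept the kinetic parameters are held constant
(C_B = 0) with the Hill constant frozen at a representative mid-culture
value ``B_frozen``, so that only the noise terms vary across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import correlate
from scipy.spatial import cKDTree

from . import model_core as mc
from . import microenvironment as env
from .errors import ConfigurationError, ParameterError
from .motility import MotilityParams, PopulationParams

__all__ = [
    "SimulationConfig",
    "SweepSettings",
    "Snapshot",
    "SimulationResult",
    "SortingResult",
    "SweepResult",
    "AblationResult",
    "run_simulation",
    "run_sorting_pair",
    "delta_S",
    "classify_regime",
    "sweep",
    "tsa_in_silico",
    "alignment_ablation",
    "saturation_step",
]

_SWEEPABLE = {"C_B", "N_int", "N_ext"}


@dataclass(frozen=True)
class SweepSettings:
    """Thresholds and conventions for sweep regime calls.

    B_frozen  -- Hill constant used when sweeping (N_ext, N_int) with the
                 density coupling switched off (C_B = 0); chosen to match
                 the effective threshold at a representative mid-culture
                 depletion of the default coupled model.
    eps_conv  -- below this conversion fraction a grid cell is "grey".
    delta_tol -- |delta_S| within this band is a tie, defaulting to grey.
    """

    B_frozen: float = 525.0
    eps_conv: float = 0.01
    delta_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.B_frozen <= 0:
            raise ParameterError(f"B_frozen must be > 0, got {self.B_frozen}")
        if self.eps_conv <= 0 or self.delta_tol <= 0:
            raise ParameterError("eps_conv and delta_tol must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, validated description of one simulation run."""

    phenotype: mc.PhenotypeParams = mc.PhenotypeParams()
    noise: mc.NoiseParams = mc.NoiseParams()
    motility: MotilityParams = MotilityParams()
    population: PopulationParams = PopulationParams()
    field: env.FieldParams = env.FieldParams()
    nx: int = 60
    ny: int = 60
    n_founders: int = 24
    founder_init: str = "mixed"
    n_steps: int = 220
    record_steps: tuple[int, ...] = (40, 100)
    seed: int = 0

    sweep: SweepSettings = SweepSettings()

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ConfigurationError(f"world must be at least 3x3 patches, got {self.nx}x{self.ny}")
        if self.n_founders < 1:
            raise ConfigurationError(f"n_founders must be >= 1, got {self.n_founders}")
        if self.founder_init not in ("low", "high", "mixed"):
            raise ConfigurationError(
                f"founder_init must be one of low/high/mixed, got {self.founder_init!r}"
            )
        if self.n_steps < 0:
            raise ConfigurationError(f"n_steps must be >= 0, got {self.n_steps}")
        bad = [s for s in self.record_steps if not 0 <= s <= self.n_steps]
        if bad:
            raise ConfigurationError(
                f"record_steps {bad} fall outside [0, n_steps={self.n_steps}]"
            )

    @property
    def world(self) -> tuple[float, float]:
        ps = self.field.patch_size
        return (self.nx * ps, self.ny * ps)


@dataclass
class Snapshot:
    step: int
    cells: pd.DataFrame
    field_grid: np.ndarray


@dataclass
class SimulationResult:
    config: SimulationConfig
    steps: np.ndarray            # 0 .. n_steps
    population: np.ndarray       # live cell count per step
    n_high: np.ndarray           # cells currently classified high
    n_low: np.ndarray
    S_low: np.ndarray            # low-founder lineage fraction now high (NaN if none)
    S_high: np.ndarray           # high-founder lineage fraction now low (NaN if none)
    snapshots: dict[int, Snapshot]

    @property
    def final_population(self) -> int:
        return int(self.population[-1])


@dataclass
class SortingResult:
    """Conversion time courses of the paired sorted-founder simulations."""

    steps: np.ndarray
    S_low: np.ndarray
    S_high: np.ndarray
    delta_S_at: dict[int, float]
    seed: int

    def __post_init__(self) -> None:
        for arr, name in ((self.S_low, "S_low"), (self.S_high, "S_high")):
            vals = np.asarray(arr)
            if np.any((vals < -1e-12) | (vals > 1 + 1e-12)):
                raise ParameterError(f"{name} must lie in [0, 1]")


@dataclass
class SweepResult:
    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    record_steps: tuple[int, ...]
    delta_S_grid: dict[int, np.ndarray]     # step -> (n1, n2) mean over replicates
    S_high_grid: dict[int, np.ndarray]
    S_low_grid: dict[int, np.ndarray]
    regime_grid: dict[int, np.ndarray]      # step -> (n1, n2) of {"grey","blue","red"}
    n_replicates: int
    seeds: list[int]


@dataclass
class AblationResult:
    aligned: SweepResult
    random_migration: SweepResult
    agreement: dict[int, float]             # step -> fraction of grid cells agreeing


class _Engine:
    """Array-based state of one running simulation."""

    def __init__(self, config: SimulationConfig):
        config = _validated(config)
        self.cfg = config
        ss = np.random.SeedSequence(config.seed)
        init_ss, motility_ss, phen_ss, pop_ss = ss.spawn(4)
        self.rng_init = np.random.default_rng(init_ss)
        self.rng_motility = np.random.default_rng(motility_ss)
        self.rng_phen = np.random.default_rng(phen_ss)
        self.rng_pop = np.random.default_rng(pop_ss)

        self.field = env.ResourceField.uniform(config.nx, config.ny, config.field)
        self.world = config.world

        pp = config.phenotype
        self.p_plus_baseline = mc.high_fixed_point(pp.A, pp.B, pp.k_deg)
        if self.p_plus_baseline is None:
            raise ConfigurationError(
                "phenotype parameters are monostable at baseline (B_eff = B); "
                "the model requires a baseline high state"
            )

        n = config.n_founders
        wx, wy = self.world
        self.x = self.rng_init.uniform(0.0, wx, size=n)
        self.y = self.rng_init.uniform(0.0, wy, size=n)
        self.heading = self.rng_init.uniform(0.0, 2.0 * np.pi, size=n)
        popp = config.population
        self.cycle_length = self.rng_init.integers(popp.cycle_min, popp.cycle_max + 1, size=n)
        # desynchronised clocks: founders are a random-phase population
        self.cycle_clock = (self.rng_init.random(n) * self.cycle_length).astype(np.int64)
        if config.founder_init == "low":
            high_mask = np.zeros(n, dtype=bool)
        elif config.founder_init == "high":
            high_mask = np.ones(n, dtype=bool)
        else:
            high_mask = self.rng_init.random(n) < 0.5
        self.P = np.where(high_mask, self.p_plus_baseline, 0.0).astype(float)
        self.founder_class = np.where(high_mask, "high", "low").astype(object)
        self.next_id = n
        self.id = np.arange(n, dtype=np.int64)

    # -- step phases -----------------------------------------------------

    def _uptake_and_replenish(self) -> None:
        positions = np.column_stack([self.x, self.y])
        self.field = env.apply_uptake(self.field, positions)
        self.field = env.apply_replenishment(self.field)

    def _move(self) -> None:
        mp = self.cfg.motility
        n = len(self.x)
        new_heading = self.rng_motility.uniform(0.0, 2.0 * np.pi, size=n)
        if mp.alignment_enabled and n >= 2:
            pts = np.column_stack([self.x, self.y])
            tree = cKDTree(pts, boxsize=self.world)
            pairs = tree.query_pairs(mp.r_align, output_type="ndarray")
            if len(pairs):
                i, j = pairs[:, 0], pairs[:, 1]
                if mp.polar:
                    z = np.exp(1j * self.heading)
                else:
                    z = np.exp(2j * self.heading)
                acc = np.zeros(n, dtype=complex)
                np.add.at(acc, i, z[j])
                np.add.at(acc, j, z[i])
                has = np.abs(acc) > 1e-12
                noise = self.rng_motility.normal(0.0, mp.eta, size=n)
                flips = self.rng_motility.random(n) < 0.5
                if mp.polar:
                    aligned = np.angle(acc) + noise
                else:
                    aligned = np.angle(acc) / 2.0 + noise
                    aligned = np.where(flips, aligned + np.pi, aligned)
                new_heading = np.where(has, aligned, new_heading)
            else:
                # keep the stream layout comparable across sparse steps
                self.rng_motility.normal(0.0, mp.eta, size=n)
                self.rng_motility.random(n)
        self.heading = np.mod(new_heading, 2.0 * np.pi)
        speed = self.rng_motility.exponential(mp.mean_speed, size=n)
        self.x = np.mod(self.x + speed * np.cos(self.heading), self.world[0])
        self.y = np.mod(self.y + speed * np.sin(self.heading), self.world[1])

    def _local_B_eff_and_density(self) -> tuple[np.ndarray, np.ndarray]:
        R = env.local_R_many(self.field, self.x, self.y)
        pp = self.cfg.phenotype
        B_eff = mc.effective_B(pp.B, pp.C_B, R)
        d_hat = env.density_hat(R, self.cfg.field.R0)
        return B_eff, d_hat

    def _update_phenotypes(self) -> None:
        pp, noise = self.cfg.phenotype, self.cfg.noise
        B_eff, d_hat = self._local_B_eff_and_density()
        n = len(self.P)
        p_hat = np.clip(self.P / self.p_plus_baseline, 0.0, 1.0)
        sd_ext = mc.context_noise_sd(p_hat, d_hat, noise.N_ext)
        eps = self.rng_phen.standard_normal(n) * noise.N_int
        eps = eps + self.rng_phen.standard_normal(n) * sd_ext
        self.P = np.maximum(
            0.0, self.P + mc.production_rate(self.P, pp.A, B_eff) - pp.k_deg * self.P + eps
        )

    def _neighbourhood_counts(self) -> np.ndarray:
        """Cells per (2r+1)x(2r+1)-patch neighbourhood at each cell's patch."""
        popp = self.cfg.population
        ix, iy = self.field.patch_indices(self.x, self.y)
        occ = np.zeros(self.field.shape, dtype=float)
        np.add.at(occ, (ix, iy), 1.0)
        k = 2 * popp.crowd_radius + 1
        counts = correlate(occ, np.ones((k, k)), mode="wrap")
        return counts[ix, iy]

    def _divide_and_die(self) -> None:
        popp = self.cfg.population
        n = len(self.x)
        keep = np.ones(n, dtype=bool)
        if popp.death_rate > 0:
            keep = self.rng_pop.random(n) >= popp.death_rate
            self._apply_mask(keep)
            n = len(self.x)
            if n == 0:
                return
        self.cycle_clock = np.minimum(self.cycle_clock + 1, self.cycle_length)
        ready = self.cycle_clock >= self.cycle_length
        if not np.any(ready):
            return
        counts = self._neighbourhood_counts()
        R_here = env.local_R_many(self.field, self.x, self.y)
        dividing = ready & (counts < popp.crowding_cap) & (R_here >= popp.R_div)
        # crowded mothers hold their clock (already capped) and retry next step
        if not np.any(dividing):
            return
        m = int(dividing.sum())
        mothers = np.where(dividing)[0]
        jitter = self.rng_pop.uniform(
            -self.cfg.field.patch_size / 2.0, self.cfg.field.patch_size / 2.0, size=(2 * m, 2)
        )
        new_lengths = self.rng_pop.integers(popp.cycle_min, popp.cycle_max + 1, size=2 * m)
        dx = np.repeat(self.x[mothers], 2) + jitter[:, 0]
        dy = np.repeat(self.y[mothers], 2) + jitter[:, 1]
        dx = np.mod(dx, self.world[0])
        dy = np.mod(dy, self.world[1])

        survivors = ~dividing
        self.x = np.concatenate([self.x[survivors], dx])
        self.y = np.concatenate([self.y[survivors], dy])
        self.heading = np.concatenate([self.heading[survivors], np.repeat(self.heading[mothers], 2)])
        self.P = np.concatenate([self.P[survivors], np.repeat(self.P[mothers], 2)])
        self.founder_class = np.concatenate(
            [self.founder_class[survivors], np.repeat(self.founder_class[mothers], 2)]
        )
        self.cycle_length = np.concatenate([self.cycle_length[survivors], new_lengths])
        self.cycle_clock = np.concatenate(
            [self.cycle_clock[survivors], np.zeros(2 * m, dtype=np.int64)]
        )
        new_ids = np.arange(self.next_id, self.next_id + 2 * m, dtype=np.int64)
        self.next_id += 2 * m
        self.id = np.concatenate([self.id[survivors], new_ids])

    def _apply_mask(self, keep: np.ndarray) -> None:
        for name in ("x", "y", "heading", "P", "founder_class", "cycle_length", "cycle_clock", "id"):
            setattr(self, name, getattr(self, name)[keep])

    # -- observation -----------------------------------------------------

    def classes(self) -> np.ndarray:
        B_eff, _ = self._local_B_eff_and_density()
        return mc.is_high(self.P, B_eff)

    def summary(self) -> tuple[int, int, int, float, float]:
        high = self.classes()
        n = len(self.P)
        n_high = int(high.sum())
        low_founders = self.founder_class == "low"
        high_founders = self.founder_class == "high"
        s_low = float(high[low_founders].mean()) if np.any(low_founders) else np.nan
        s_high = float((~high[high_founders]).mean()) if np.any(high_founders) else np.nan
        return n, n_high, n - n_high, s_low, s_high

    def snapshot(self, step: int) -> Snapshot:
        high = self.classes()
        cells = pd.DataFrame(
            {
                "id": self.id,
                "x": self.x,
                "y": self.y,
                "heading": self.heading,
                "P": self.P,
                "phenotype": np.where(high, "high", "low"),
                "founder_class": self.founder_class.astype(str),
                "step": step,
            }
        )
        return Snapshot(step=step, cells=cells, field_grid=self.field.grid.copy())

    def step(self) -> None:
        if len(self.x) == 0:
            return
        self._uptake_and_replenish()
        self._move()
        self._update_phenotypes()
        self._divide_and_die()


def _validated(config: SimulationConfig) -> SimulationConfig:
    if not isinstance(config, SimulationConfig):
        raise ConfigurationError(f"expected SimulationConfig, got {type(config).__name__}")
    return config


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run one full simulation; deterministic given (config, seed)."""
    engine = _Engine(config)
    record = set(config.record_steps)
    steps = np.arange(config.n_steps + 1)
    population = np.zeros(config.n_steps + 1, dtype=np.int64)
    n_high = np.zeros(config.n_steps + 1, dtype=np.int64)
    n_low = np.zeros(config.n_steps + 1, dtype=np.int64)
    S_low = np.zeros(config.n_steps + 1)
    S_high = np.zeros(config.n_steps + 1)
    snapshots: dict[int, Snapshot] = {}

    def observe(t: int) -> None:
        n, nh, nl, sl, sh = engine.summary()
        population[t], n_high[t], n_low[t] = n, nh, nl
        S_low[t], S_high[t] = sl, sh
        if t in record or t == config.n_steps:
            snapshots[t] = engine.snapshot(t)

    observe(0)
    for t in range(1, config.n_steps + 1):
        engine.step()
        observe(t)
    return SimulationResult(
        config=config,
        steps=steps,
        population=population,
        n_high=n_high,
        n_low=n_low,
        S_low=S_low,
        S_high=S_high,
        snapshots=snapshots,
    )


def delta_S(S_high_t: float, S_low_t: float) -> float:
    """Difference in switch rate, ``S_high - S_low``.

    Positive when sorted high-P founders convert more than sorted low-P
    founders (the blue regime); negative in the red regime.
    """
    for name, v in (("S_high_t", S_high_t), ("S_low_t", S_low_t)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    return S_high_t - S_low_t


def run_sorting_pair(config: SimulationConfig, seed: int | None = None) -> SortingResult:
    """Paired sorted-founder simulations (pure low vs pure high founders)."""
    if config.founder_init == "mixed":
        raise ConfigurationError("sorting runs require founder_init 'low' or 'high', not 'mixed'")
    seed = config.seed if seed is None else int(seed)
    low = run_simulation(replace(config, founder_init="low", seed=seed))
    high = run_simulation(replace(config, founder_init="high", seed=seed))
    d = {
        int(s): delta_S(float(high.S_high[s]), float(low.S_low[s]))
        for s in config.record_steps
    }
    return SortingResult(
        steps=low.steps, S_low=low.S_low, S_high=high.S_high, delta_S_at=d, seed=seed
    )


def classify_regime(
    S_high: float, S_low: float, eps_conv: float = 0.01, delta_tol: float = 0.02
) -> str:
    """Map conversion fractions to one of the three sweep regimes."""
    for name, v in (("S_high", S_high), ("S_low", S_low)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    if max(S_high, S_low) < eps_conv:
        return "grey"
    d = S_high - S_low
    if d > delta_tol:
        return "blue"
    if d < -delta_tol:
        return "red"
    return "grey"


def _apply_axis(config: SimulationConfig, name: str, value: float) -> SimulationConfig:
    if name == "C_B":
        return replace(config, phenotype=replace(config.phenotype, C_B=float(value)))
    if name == "N_int":
        return replace(config, noise=replace(config.noise, N_int=float(value)))
    if name == "N_ext":
        return replace(config, noise=replace(config.noise, N_ext=float(value)))
    raise ConfigurationError(f"unknown sweep axis {name!r}")


def _replicate_seeds(base_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def sweep(
    config: SimulationConfig,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    n_replicates: int = 3,
    base_seed: int | None = None,
) -> SweepResult:
    """Tile a parameter plane with paired sorting runs.

    Each grid cell runs ``n_replicates`` sorting pairs (seeds shared
    across the grid so cells are paired by replicate); delta_S is the
    mean over replicates and the regime is called on the mean conversion
    fractions.  Sweeping the (N_ext, N_int) plane switches the density
    coupling off (C_B = 0) and freezes the Hill constant at
    ``config.sweep.B_frozen`` so only the noise terms differ across the
    plane.
    """
    (name1, values1), (name2, values2) = axis1, axis2
    if name1 not in _SWEEPABLE or name2 not in _SWEEPABLE:
        raise ConfigurationError(f"sweep axes must be in {sorted(_SWEEPABLE)}")
    if name1 == name2:
        raise ConfigurationError(f"sweep axes must differ, both are {name1!r}")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    values1 = np.asarray(list(values1), dtype=float)
    values2 = np.asarray(list(values2), dtype=float)
    base = config
    if {name1, name2} == {"N_ext", "N_int"}:
        base = replace(
            config,
            phenotype=replace(config.phenotype, C_B=0.0, B=config.sweep.B_frozen),
        )
    base_seed = config.seed if base_seed is None else int(base_seed)
    seeds = _replicate_seeds(base_seed, n_replicates)
    record = tuple(int(s) for s in config.record_steps)
    shape = (len(values1), len(values2))
    sh_acc = {s: np.zeros(shape) for s in record}
    sl_acc = {s: np.zeros(shape) for s in record}
    for i, v1 in enumerate(values1):
        for j, v2 in enumerate(values2):
            cfg = _apply_axis(_apply_axis(base, name1, v1), name2, v2)
            cfg = replace(cfg, founder_init="low")
            for seed in seeds:
                res = run_sorting_pair(cfg, seed)
                for s in record:
                    sh_acc[s][i, j] += float(res.S_high[s])
                    sl_acc[s][i, j] += float(res.S_low[s])
    regimes: dict[int, np.ndarray] = {}
    deltas: dict[int, np.ndarray] = {}
    for s in record:
        sh_acc[s] /= n_replicates
        sl_acc[s] /= n_replicates
        deltas[s] = sh_acc[s] - sl_acc[s]
        grid = np.empty(shape, dtype=object)
        for i in range(shape[0]):
            for j in range(shape[1]):
                grid[i, j] = classify_regime(
                    sh_acc[s][i, j], sl_acc[s][i, j],
                    config.sweep.eps_conv, config.sweep.delta_tol,
                )
        regimes[s] = grid
    return SweepResult(
        axis_names=(name1, name2),
        axis_values=(values1, values2),
        record_steps=record,
        delta_S_grid=deltas,
        S_high_grid=sh_acc,
        S_low_grid=sl_acc,
        regime_grid=regimes,
        n_replicates=n_replicates,
        seeds=seeds,
    )


def tsa_in_silico(
    config: SimulationConfig, N_int_elevated: float
) -> tuple[SortingResult, SortingResult]:
    """Sorting pair at baseline vs elevated intrinsic noise, same seeds.

    The treated condition models a histone-deacetylase-inhibitor exposure
    as a pure increase of the intrinsic noise amplitude; everything else,
    including the seed, is identical to the control.
    """
    if N_int_elevated <= config.noise.N_int:
        raise ParameterError(
            f"N_int_elevated ({N_int_elevated}) must exceed the baseline N_int "
            f"({config.noise.N_int})"
        )
    control = run_sorting_pair(replace(config, founder_init="low"))
    treated = run_sorting_pair(
        replace(
            config,
            founder_init="low",
            noise=replace(config.noise, N_int=float(N_int_elevated)),
        )
    )
    return control, treated


def alignment_ablation(
    config: SimulationConfig,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    n_replicates: int = 3,
    base_seed: int | None = None,
) -> AblationResult:
    """Identical sweeps with and without nematic alignment.

    Reports, per recorded step, the fraction of grid cells whose regime
    call agrees between the aligned and random-migration models.
    """
    aligned = sweep(
        replace(config, motility=replace(config.motility, alignment_enabled=True)),
        axis1, axis2, n_replicates, base_seed,
    )
    random_mig = sweep(
        replace(config, motility=replace(config.motility, alignment_enabled=False)),
        axis1, axis2, n_replicates, base_seed,
    )
    agreement = {
        s: float(np.mean(aligned.regime_grid[s] == random_mig.regime_grid[s]))
        for s in aligned.record_steps
    }
    return AblationResult(aligned=aligned, random_migration=random_mig, agreement=agreement)


def saturation_step(population: np.ndarray, frac: float = 0.95) -> int:
    """First step at which the population reaches ``frac`` of its final size."""
    population = np.asarray(population)
    target = frac * population[-1]
    return int(np.argmax(population >= target))
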