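# myoswitch

An agent-based model of **noise-driven bistable phenotype switching in
proliferating myoblast cultures**, together with the in-silico sorting
experiment used to probe it and the spatial statistics used to relate a
cell's phenotype to its local density.

Primary human myoblast cultures contain two interconvertible phenotypes
(classically read out as CD56-high and CD56-low cells). Sorted pure
subpopulations regenerate the mixture, the mixed population sits near a
stable ~3:1 high:low composition, and high-expressing cells concentrate
in locally dense regions. This package reimplements the computational
model that accounts for those observations: each cell carries a bistable
internal variable, senses local cell density through the depletion of a
diffusible resource, and switches state under the combined action of
intrinsic and context-dependent noise, while migrating with
density-triggered nematic alignment and proliferating under resource and
crowding limits.

It is aimed at researchers studying stochastic cell-fate dynamics who
want a tested, reproducible re-implementation to run sorting
experiments, parameter-space sweeps and spatial analyses in silico.

## The model

Each cell updates a phenotype level `P` once per step (1 step ~ 1 h):

```
P(t+1) = P(t) + A·P²/(B_eff + P²) − k_deg·P + ε_int + ε_ext
B_eff  = B + C_B·R
```

* Hill production (exponent 2) plus linear degradation makes the
  noise-free map bistable: stable states at `P = 0` and
  `P₊ = (A + √(A² − 4k²B_eff))/(2k)`, separated by an unstable
  threshold `P₋`. A cell is classified **high** when its production rate
  exceeds the rate at the Hill inflection point (`A/4`), i.e. when
  `P > √(B_eff/3)`.
* `R` is a diffusible resource (initially 100 everywhere) consumed by
  cells and replenished from the medium; its local depletion is the
  cells' density sensor. Through `B_eff = B + C_B·R`, abundant resource
  (low density) raises the production threshold and favours the low
  state.
* `ε_int ~ N(0, N_int)` is intrinsic noise; `ε_ext` has a standard
  deviation following a hyperbolic-paraboloid surface of (phenotype,
  density) — maximal when the cell's state mismatches its
  microenvironment, zero when they match.
* Cells migrate with exponential step lengths; with a neighbour within
  `r_align` they adopt the local nematic axis (forward or backward at
  random), producing the wave-like patterns of confluent myoblasts.
* Cells divide after a 20–24-step cycle when local resource and
  crowding permit, and die at a small constant rate.

The **in-silico sorting experiment** starts separate simulations from
pure low-P and pure high-P founders and tracks `S_low(t)` (fraction of
the low-founder lineage now high) and `S_high(t)` (fraction of the
high-founder lineage now low). Their difference `δS = S_high − S_low`
classifies the parameter space into three regimes: *grey* (no
conversion), *blue* (`δS > 0`) and *red* (`δS < 0`).

The **spatial analysis** takes any cell table (x, y, intensity), uses
the nearest-neighbour distance as a local-density proxy, and reports a
LOWESS curve of intensity against that proxy, Spearman's rank
correlation (negative ρ = intensity rises with density) and the
fraction of cells above an intensity background. A Thomas-cluster
synthetic generator provides tables with planted effects for testing.

## Worked example

```python
import numpy as np
from myoswitch import default_config, run_sorting_pair
import dataclasses

cfg = default_config(founder_init="low", n_steps=100)   # C_B = 15 default
res = run_sorting_pair(cfg)
print({k: round(v, 3) for k, v in res.delta_S_at.items()})
```

prints

```
{40: 1.0, 100: 1.0}
```

With the default strong density coupling (`C_B = 15`) the experiment
starts at low density, where depleted-free medium keeps every cell's
production threshold high: the sorted high-P founders all convert to
low while low-P founders stay put, so `δS = +1` at steps 40 and 100
(blue regime). Re-running with weak coupling and dominant intrinsic
noise flips the sign — the low well is much shallower than the high
well, so noise preferentially converts low-P founders:

```python
cfg2 = dataclasses.replace(
    cfg,
    phenotype=dataclasses.replace(cfg.phenotype, C_B=5.0),
    noise=dataclasses.replace(cfg.noise, N_int=3.0),
)
print({k: round(v, 3) for k, v in run_sorting_pair(cfg2).delta_S_at.items()})
```

```
{40: -0.218, 100: -0.344}
```

The command line exposes the same operations (`myoswitch simulate`,
`sort`, `sweep`, `spatial`, `synth`); every run writes a manifest with
the resolved configuration, seed and output hashes, and identical
(config, seed) pairs reproduce outputs bit for bit.

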