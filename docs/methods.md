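# Methods

This note documents the model implemented by `myoswitch`, the reasoning
behind every constant in the default configuration, what the synthetic
generators do and do not emulate, and the numerical conventions. The
scheme reconstructs a previously described agent-based model whose code
and numeric constants were never published; every value below is this
package's own calibration, frozen in `src/myoswitch/default_config.yaml`.

## 1. Single-cell phenotype dynamics

The phenotype of a cell is a non-negative level `P` updated once per
simulation step by the forward-Euler map

    P' = max(0,  P + A·P²/(B_eff + P²) − k_deg·P + ε_int + ε_ext),
    B_eff = B + C_B·R_local.

One step represents roughly one hour, so the 20–24-step cell cycle
matches a 20–24 h cycle and ~8 population doublings fit in 150–200
steps. Production and degradation are evaluated at the pre-step `P`,
the two noise draws are added, and the result is clamped at zero; there
is no sub-stepping. The low stable state therefore sits exactly at
`P = 0` with a reflecting boundary — whether the original scheme used a
strictly positive basal production is unknown, and we make no further
assumption.

Fixed points of the noise-free map are `P = 0` (stable) and, when
`A² > 4·k_deg²·B_eff`, the roots `P∓ = (A ∓ √disc)/(2·k_deg)` of
`k_deg·P² − A·P + k_deg·B_eff` (unstable threshold and stable high
state). A cell is classified *high* when its current production rate
exceeds the rate at the Hill inflection point, which is `A/4`
independently of `B_eff`; equivalently `P > √(B_eff/3)`, with the
boundary classified low (strict inequality). Classification is
context-dependent: the same `P` can be high in a depleted patch and low
in a resource-rich one.

**Noise.** `ε_int ~ Normal(0, N_int)` is identical for every cell.
`ε_ext ~ Normal(0, σ(p̂, d̂))` with the bilinear (hyperbolic-paraboloid)
amplitude surface

    σ(p̂, d̂) = N_ext · (1 + (2d̂ − 1)(1 − 2p̂)) / 2,

where `d̂ = 1 − R/R0` is the local density proxy and
`p̂ = clamp(P / P₊(baseline), 0, 1)` is the normalised phenotype
coordinate, with `P₊(baseline)` the high fixed point at `B_eff = B`.
A continuous `p̂` (rather than the binary class) preserves the saddle
structure of the surface. σ equals `N_ext` at the mismatched corners
(low-P cell at high density, high-P cell at low density), zero at the
matched corners, and `N_ext/2` along the saddle lines. The noise is
mean-zero and symmetric; only its amplitude is context-dependent.

**Default kinetics** `A = 10`, `B = 50`, `k_deg = 0.2`. These were
chosen so that (i) the baseline dynamics are bistable
(`P₋ ≈ 1.02`, `P₊ ≈ 48.98`, threshold `≈ 4.08`); (ii) with the strong
coupling `C_B = 15` the dynamics are monostable-low wherever
`R > 38.3` — any sparsely populated region actively erases the high
phenotype; and (iii) with the weak coupling `C_B = 5` the dynamics stay
bistable at every `R ≤ 100`, so conversions under weak coupling are
purely noise-driven. This separation is what makes the two worked
sorting examples mechanistically distinct. Default noise amplitudes
are `N_int = 0.1` (quiet: no spontaneous conversions on its own) and
`N_ext = 3.0` (drives low→high conversion in depleted regions within
tens of steps).

## 2. The resource field

The dish is a 60×60 grid of unit patches carrying a concentration `R`
of an anonymous diffusible resource, initially `R0 = 100` everywhere.
Each step, in order: every cell removes `u` from its patch (clamped at
0); every patch then relaxes toward the medium and mixes with its
existing 8 neighbours,

    R' = clamp( R + D_med·(R0 − R) + D_lat·(mean₈ − R), 0, R0 ).

With `D_lat = 0` and a steady per-patch drain `u·n` the equilibrium is
`R* = R0 − u·n/D_med`. Positions map to patches by half-open intervals;
a cell reads the concentration of its containing patch without
interpolation. The field does not wrap even though cell motion does:
the medium, not the opposite edge, is the reservoir, and a periodic
field would couple depletion across the seam. Defaults: `D_med = 0.1`,
`D_lat = 0.2`, `u = 4.89`.

`u` and `D_med` were calibrated jointly (see §5): they set both how
strongly a single founder depletes its patch during the sparse phase
(`R ≈ 80`, so `d̂ ≈ 0.2` — low density must *read* as low density for
the context-noise asymmetry) and where the saturated culture's
operating point lands on the bistable/monostable boundary.

## 3. Migration, proliferation, turnover

Headings are re-drawn every step. A cell with no neighbour within
`r_align = 1.5` picks a uniform random heading (isolated cells perform
an unbiased random walk). Otherwise it aligns *nematically*: the local
mean axis is half the argument of `Σ exp(2iθ)` over neighbour headings;
the cell adds `Normal(0, eta = 0.2)` angular noise and moves forward or
backward along the axis with probability ½ each, reproducing motion
that is "random in one dimension" in dense regions. A polar
(Vicsek-style) variant is available as a config flag for comparison but
is not the default. Step lengths are exponential with mean 0.5 patch
widths, independent of the neighbourhood, matching the empirically
exponential distribution of velocity magnitudes.

Cells divide when their cycle clock (length uniform on [20, 24] steps,
clocks initialised at random phases) expires, provided (i) fewer than
`crowding_cap = 26` cells occupy the surrounding 5×5-patch
neighbourhood and (ii) the local resource is at least `R_div = 27`.
Deferred mothers hold their clock and retry. Daughters are placed
within half a patch width of the mother and inherit her `P` and founder
class exactly. Cells die with probability `death_rate = 0.002` per
step.

Two of these rules are this package's own additions, made because the
plain count-cap proved insufficient:

* **Resource-gated division.** Motility re-randomises neighbourhood
  counts every step, so a pure count cap always finds open slots and
  the population creeps upward indefinitely (measured +37 % between
  steps 220 and 600), dragging the resource level — and with it the
  phenotype composition — downward without bound. Requiring `R ≥ R_div`
  ties proliferation to the same limiting substance the cells sense,
  which is also the natural biological reading.
* **Turnover.** With `death_rate = 0`, the composition has no
  stationary state: conversion into the deep high well is effectively
  irreversible in a uniformly depleted dish. A small constant death
  rate, balanced by division concentrated in resource-rich (sparser,
  lower-P) regions, closes the loop and produces a genuine dynamic
  equilibrium in which both conversion directions keep occurring.

## 4. Simulation step order and bookkeeping

Per step: (1) uptake, (2) replenishment, (3) heading/speed/position,
(4) phenotype updates reading the freshly updated field at the new
positions, (5) death, cycle advance, division. Observations are taken
after (5). All randomness flows from one seed through four named
child streams (init, motility, phenotype, population), so identical
(config, seed) give bit-identical outputs.

Sorting runs start 24 founders (positions uniform, `P` at the baseline
stable fixed point of their class) and track, per step, the fraction of
each founder lineage currently classified opposite to its origin;
`δS(t) = S_high(t) − S_low(t)` is reported at steps 40 and 100 (the
exponential growth phase). Regime calls use `eps_conv = 0.01` (below
which a grid cell is *grey*) and `delta_tol = 0.02` (the |δS| tie band,
defaulting to grey); both were fixed once so that the grey/blue/red
structure is stable under reseeding at the 5×5-grid, 3-replicate desk
scale, and both are exposed in the config.

**Noise-plane sweeps.** When the two noise amplitudes are swept the
density coupling is off (`C_B = 0`) and the Hill constant is frozen at
`B_frozen = 525`, i.e. near the bistable boundary (625), where both
wells are shallow enough for either noise term to act on the 100-step
horizon. At the default baseline `B = 50` the high well is ~45 units
deep against a restoring drift of up to ~4.7 per step, and no noise
amplitude produces the high→low conversions that define the blue
regime. `B_frozen = 525` corresponds to the effective threshold of the
coupled model at a representative mid-culture depletion and makes the
sweep a statement about noise alone, holding kinetics fixed.

## 5. Calibration of the default configuration

The frozen defaults were obtained by grid exploration against three
reference behaviours, in this order, then never revisited:

1. **Growth.** From 24 founders the 60×60 world saturates near 5000
   cells (measured ≈ 4800 ± 150 over seeds) with the plateau reached
   around step 210; `crowding_cap = 26` over 5×5 patches sets the
   ceiling (a per-patch cap cannot: per-patch occupancy at 5000 cells
   is only ~1.4).
2. **Composition.** With `C_B = 15`, the saturated culture must hold a
   ~3:1 high:low ratio as a *stationary* value. The ratio is set by the
   spatial mix of depleted (bistable, conversion-prone) and
   resource-rich (monostable-low) zones and by the turnover flux;
   `u = 4.89` centres the plateau at ≈ 3.0 (seed range ≈ 2.6–3.6). The
   plateau is reached at ~700–800 steps; the acceptance protocol
   therefore measures at step 800 (the requirement is only ≥ 300).
3. **Sorting signs.** `C_B = 15` with default noise gives `δS = +1` at
   steps 40 and 100 (every high founder converts during the sparse
   phase; low founders do not); `C_B = 5` with `N_int = 3` gives
   `δS ≈ −0.2…−0.35` (the shallow low well empties under intrinsic
   noise; the deep high well does not).

## 6. Spatial statistics

Nearest-neighbour distances (plain Euclidean, no wrap — microscopy
fields of view are not periodic) come from a k-d tree and are checked
against an exhaustive O(n²) oracle in the tests. LOWESS uses the
classical tricube local-linear smoother (statsmodels) with defaults
`frac = 2/3` and 3 robustifying iterations, both exposed. Spearman's ρ
uses mid-ranks for ties; the two-sided p-value is exact (full
permutation enumeration) for n ≤ 8 and the large-sample approximation
otherwise. Coordinates are taken in their stated units and never
rescaled. A negative ρ between intensity and nearest-neighbour distance
means intensity rises with local density; the same machinery applies to
any intensity channel.

## 7. Synthetic data

`gen_cluster_pattern` draws a Thomas cluster process (Poisson parents,
Poisson(μ) Gaussian-scattered offspring, Poisson background) — a
controllable, analytically characterised stand-in for the density
heterogeneity of real cultures. It does **not** reproduce the
anisotropic wave-like patterns of confluent myoblasts (those are
produced by the simulator itself), microscope optics, segmentation
errors or fluorescence bleed-through. `plant_intensity` makes intensity
linear in the nearest-neighbour distance (clamped at zero) so the
planted effect is exactly the statistic the analysis computes; passing
the planted-recovery and type-I calibration tests therefore validates
the statistical pipeline, not the realism of any particular microscope.
`gen_velocity_fixture` draws 16 000 exponential speeds, mirroring the
empirical sample size used to calibrate migration.

## 8. Numerical conventions and degenerate inputs

* Boundary classification ties break low (strict inequality).
* A zero doubled-angle resultant (perfectly balanced axes) keeps the
  previous heading.
* Patch assignment is half-open; positions exactly on the world edge
  are rejected as out-of-world.
* Duplicate coordinates yield nearest-neighbour distance 0 with a
  warning; constant vectors raise an undefined-correlation error rather
  than returning NaN.
* Empty synthetic tables and zero-step simulations are valid and
  round-trip through the CSV layer, which preserves floats bit-exactly
  (shortest round-trip repr on write, round-trip parser on read).

## 9. Known limitations

* The alignment rule, field update scheme and all rate constants are
  reconstructions; only the functional forms (Hill production, linear
  degradation, paraboloid noise surface, resource-mediated coupling)
  and the qualitative target behaviours constrain them.
* The composition plateau (~3:1) emerges from spatial zone mixing plus
  turnover; its value is sensitive to `u` at the ±0.5-per-0.05 level,
  which is why `u` is frozen in the shipped config.
* `δS = +1` under strong coupling is a saturated version of the
  qualitative claim (high founders convert faster); the model at this
  calibration converts *all* high founders during the sparse phase.
* Cell fusion into myotubes, contact mechanics, chemotaxis and any
  molecular identity for `P` or `R` are out of scope.
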