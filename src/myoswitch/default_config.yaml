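# Default configuration of the myoswitch model.
#
# Every constant below is this package's own calibration: the scheme it
# reconstructs was described only qualitatively, so kinetic rates, field
# rates, world size and crowding were chosen (and then frozen) to
# reproduce the reference behaviours documented in docs/methods.md:
# saturation near 5000 cells within steps 150-200, a high:low phenotype
# ratio of about 3:1 at long-run equilibrium, and the sorted-founder
# conversion asymmetries.

phenotype:
  A: 10.0        # maximal Hill production rate, phenotype units/step
  B: 50.0        # baseline Hill shape constant, phenotype units^2
  n: 2           # Hill exponent (fixed)
  k_deg: 0.2     # linear degradation rate, per step
  C_B: 15.0      # density coupling: B_eff = B + C_B * R ("strong" example)

noise:
  N_int: 0.1     # intrinsic noise sd, phenotype units
  N_ext: 3.0     # maximal context-dependent noise sd, phenotype units

motility:
  r_align: 1.5          # alignment radius, world units (patch widths)
  eta: 0.2              # angular noise on the aligned axis, rad
  mean_speed: 0.5       # mean exponential step length, world units/step
  alignment_enabled: true
  polar: false          # polar (Vicsek) variant instead of nematic

population:
  cycle_min: 20         # cell cycle bounds, steps (1 step ~ 1 h)
  cycle_max: 24
  crowding_cap: 26      # max cells in the crowding neighbourhood for division
  crowd_radius: 2       # neighbourhood half-width, patches (2 -> 5x5 patches)
  R_div: 27.0           # minimal local resource for division (resource-limited growth)
  death_rate: 0.002     # per-step turnover; balances residual division flux

field:
  R0: 100.0      # medium resource concentration
  D_med: 0.1     # per-step relaxation toward the medium
  D_lat: 0.2     # per-step lateral 8-neighbour mixing
  u: 4.89        # resource uptake per cell per step
  patch_size: 1.0

world:
  nx: 60         # patches
  ny: 60

run:
  n_founders: 24
  founder_init: mixed   # low | high | mixed
  n_steps: 220
  record_steps: [40, 100]
  seed: 0

sweep:
  B_frozen: 525.0  # Hill constant used for (N_ext, N_int) sweeps at C_B = 0
  eps_conv: 0.01   # conversion fraction below which a grid cell is "grey"
  delta_tol: 0.02  # |delta_S| tie band, defaults to grey
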