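"""Single-cell bistable phenotype dynamics.

The phenotype of a cell is summarised by the level ``P`` of an abstract
substance (one or several proteins; in the wet-lab system it maps loosely
to CD56).  Per simulation step the level is updated by

    P' = P + A * P**2 / (B_eff + P**2)  -  k_deg * P  +  eps_int + eps_ext

i.e. sigmoidal (Hill, exponent 2) autocatalytic production, linear
degradation, and two additive mean-zero Gaussian noise terms.  The Hill
shape constant couples to the local density through the diffusible
resource R:  ``B_eff = B + C_B * R``.  Because R is high where cells are
sparse, a positive ``C_B`` raises the production threshold at low density
and favours the low-P state there.

``eps_int`` has fixed standard deviation ``N_int`` (cell-intrinsic noise).
``eps_ext`` has a standard deviation that follows a hyperbolic-paraboloid
surface of (phenotype, local density): it is maximal when the cell state
mismatches its microenvironment (low-P cell at high density, or high-P
cell at low density) and vanishes when they match.

The deterministic part of the map has up to three fixed points: P = 0
(stable), and when ``A**2 > 4 * k_deg**2 * B_eff`` an unstable threshold
P- and a stable high state P+, the roots of
``k_deg * P**2 - A * P + k_deg * B_eff = 0``.

A cell is *classified* "high" when its instantaneous production rate
exceeds the rate at the inflection point of the Hill curve, which is
``A / 4`` independently of ``B_eff``; equivalently when
``P > sqrt(B_eff / 3)`` (strict: the boundary classifies as low).

All rate functions accept scalars or numpy arrays; the simulator reuses
them on whole populations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import DomainError, ParameterError

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "PhenotypeParams",
    "NoiseParams",
    "PhenotypeClass",
    "PhenotypeState",
    "FixedPoint",
    "effective_B",
    "production_rate",
    "classification_threshold",
    "classify_phenotype",
    "is_high",
    "context_noise_sd",
    "net_drift",
    "fixed_points",
    "high_fixed_point",
    "phenotype_hat",
    "step_phenotype",
]


def _check_finite(name: str, value: ArrayLike) -> None:
    if not np.all(np.isfinite(value)):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class PhenotypeParams:
    """Kinetic coefficients of the phenotype update map.

    A      -- maximal production rate (phenotype units / step), > 0
    B      -- Hill shape constant (phenotype units squared), > 0
    n      -- Hill exponent, fixed at 2
    k_deg  -- linear degradation rate constant per step, in (0, 1]
    C_B    -- density-coupling coefficient (phenotype units squared per
              resource unit), >= 0; ``B_eff = B + C_B * R``
    """

    A: float = 10.0
    B: float = 50.0
    n: int = 2
    k_deg: float = 0.2
    C_B: float = 15.0

    def __post_init__(self) -> None:
        for name in ("A", "B", "k_deg", "C_B"):
            _check_finite(name, getattr(self, name))
        if self.A <= 0:
            raise ParameterError(f"A must be > 0, got {self.A}")
        if self.B <= 0:
            raise ParameterError(f"B must be > 0, got {self.B}")
        if self.n != 2:
            raise ParameterError(f"Hill exponent n is fixed at 2, got {self.n}")
        if not 0 < self.k_deg <= 1:
            raise ParameterError(f"k_deg must be in (0, 1], got {self.k_deg}")
        if self.C_B < 0:
            raise ParameterError(f"C_B must be >= 0, got {self.C_B}")


@dataclass(frozen=True)
class NoiseParams:
    """Standard deviations of the two noise terms (phenotype units).

    N_int -- intrinsic noise, identical for every cell.
    N_ext -- maximal context-dependent noise, realised only where the
             phenotype mismatches the local density (see
             :func:`context_noise_sd`).
    """

    N_int: float = 0.1
    N_ext: float = 3.0

    def __post_init__(self) -> None:
        _check_finite("N_int", self.N_int)
        _check_finite("N_ext", self.N_ext)
        if self.N_int < 0:
            raise ParameterError(f"N_int must be >= 0, got {self.N_int}")
        if self.N_ext < 0:
            raise ParameterError(f"N_ext must be >= 0, got {self.N_ext}")


class PhenotypeClass(str, enum.Enum):
    LOW = "low"
    HIGH = "high"

    def __str__(self) -> str:  # plain value in tables
        return self.value


@dataclass
class PhenotypeState:
    """Current phenotype level and its classification."""

    P: float
    phenotype_class: PhenotypeClass = PhenotypeClass.LOW

    def __post_init__(self) -> None:
        _check_finite("P", self.P)
        if self.P < 0:
            raise ParameterError(f"P must be >= 0, got {self.P}")


@dataclass(frozen=True)
class FixedPoint:
    P: float
    stable: bool


def effective_B(B: ArrayLike, C_B: ArrayLike, R: ArrayLike) -> ArrayLike:
    """Density-modulated Hill constant ``B + C_B * R``.

    Strictly increasing in R whenever C_B > 0: abundant resource
    (low density) enlarges the production threshold.
    """
    for name, v in (("B", B), ("C_B", C_B), ("R", R)):
        _check_finite(name, v)
    if np.any(np.asarray(B) <= 0):
        raise ParameterError(f"B must be > 0, got {B}")
    if np.any(np.asarray(C_B) < 0):
        raise ParameterError(f"C_B must be >= 0, got {C_B}")
    if np.any(np.asarray(R) < 0):
        raise ParameterError(f"R must be >= 0, got {R}")
    return B + C_B * R


def production_rate(P: ArrayLike, A: ArrayLike, B_eff: ArrayLike) -> ArrayLike:
    """Hill production rate ``A * P**2 / (B_eff + P**2)``, bounded in [0, A)."""
    _check_finite("P", P)
    if np.any(np.asarray(P) < 0):
        raise DomainError(f"P must be >= 0, got {P}")
    P = np.asarray(P, dtype=float) if isinstance(P, np.ndarray) else float(P)
    return A * P * P / (B_eff + P * P)


def classification_threshold(B_eff: ArrayLike) -> ArrayLike:
    """Phenotype level at the inflection point of the Hill curve.

    The production rate there is A/4 for every B_eff; a cell is "high"
    strictly above this level.
    """
    return np.sqrt(np.asarray(B_eff) / 3.0) if isinstance(B_eff, np.ndarray) else math.sqrt(B_eff / 3.0)


def is_high(P: ArrayLike, B_eff: ArrayLike) -> ArrayLike:
    """Vectorised classification: True where production exceeds A/4.

    ``production > A/4  <=>  3 P**2 > B_eff`` (strict inequality; the
    boundary counts as low).
    """
    return 3.0 * np.asarray(P) ** 2 > np.asarray(B_eff)


def classify_phenotype(P: float, A: float, B_eff: float) -> PhenotypeClass:
    """Classify one cell by comparing its production rate with A/4."""
    _check_finite("P", P)
    if P < 0:
        raise DomainError(f"P must be >= 0, got {P}")
    if B_eff <= 0:
        raise ParameterError(f"B_eff must be > 0, got {B_eff}")
    return PhenotypeClass.HIGH if 3.0 * P * P > B_eff else PhenotypeClass.LOW


def context_noise_sd(p_hat: ArrayLike, d_hat: ArrayLike, N_ext: float) -> ArrayLike:
    """Standard deviation of the context-dependent noise.

    Bilinear (hyperbolic-paraboloid) surface of the normalised phenotype
    coordinate ``p_hat`` and the local density ``d_hat``, both in [0, 1]:

        sd = N_ext * (1 + (2 d_hat - 1)(1 - 2 p_hat)) / 2

    which equals N_ext at the mismatched corners (p_hat=0, d_hat=1) and
    (p_hat=1, d_hat=0), 0 at the matched corners, and N_ext/2 along the
    saddle lines p_hat = 1/2 and d_hat = 1/2.
    """
    for name, v in (("p_hat", p_hat), ("d_hat", d_hat)):
        _check_finite(name, v)
        arr = np.asarray(v)
        if np.any(arr < 0) or np.any(arr > 1):
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    if N_ext < 0:
        raise ParameterError(f"N_ext must be >= 0, got {N_ext}")
    return N_ext * (1.0 + (2.0 * np.asarray(d_hat) - 1.0) * (1.0 - 2.0 * np.asarray(p_hat))) / 2.0


def net_drift(P: ArrayLike, pp: PhenotypeParams, B_eff: ArrayLike) -> ArrayLike:
    """Deterministic per-step change: production minus degradation."""
    return production_rate(P, pp.A, B_eff) - pp.k_deg * np.asarray(P)


def fixed_points(A: float, B_eff: float, k_deg: float) -> list[FixedPoint]:
    """Fixed points of the noise-free map, ordered by P.

    P = 0 is always a stable state.  When the discriminant
    ``A**2 - 4 k_deg**2 B_eff`` is positive the quadratic
    ``k_deg P**2 - A P + k_deg B_eff`` contributes an unstable threshold
    P- and a stable high state P+.  A zero discriminant gives a single
    semi-stable double root at ``A / (2 k_deg)``, flagged unstable.
    """
    if A <= 0 or B_eff <= 0 or not 0 < k_deg <= 1:
        raise ParameterError(
            f"require A > 0, B_eff > 0, 0 < k_deg <= 1; got A={A}, B_eff={B_eff}, k_deg={k_deg}"
        )
    pts = [FixedPoint(0.0, True)]
    disc = A * A - 4.0 * k_deg * k_deg * B_eff
    if disc > 0:
        root = math.sqrt(disc)
        pts.append(FixedPoint((A - root) / (2.0 * k_deg), stable=False))
        pts.append(FixedPoint((A + root) / (2.0 * k_deg), stable=True))
    elif disc == 0:
        pts.append(FixedPoint(A / (2.0 * k_deg), stable=False))
    return pts


def high_fixed_point(A: float, B_eff: float, k_deg: float) -> float | None:
    """The stable high state P+, or None when the dynamics are monostable."""
    pts = fixed_points(A, B_eff, k_deg)
    if len(pts) == 3:
        return pts[2].P
    return None


def phenotype_hat(P: ArrayLike, pp: PhenotypeParams) -> ArrayLike:
    """Normalised phenotype coordinate for the noise surface.

    ``clamp(P / P_plus_baseline, 0, 1)`` where P_plus_baseline is the high
    fixed point of the *baseline* dynamics (B_eff = B, no density term),
    so that the saddle structure of the noise surface is a continuous
    function of P rather than of the binary class.
    """
    p_plus = high_fixed_point(pp.A, pp.B, pp.k_deg)
    if p_plus is None:
        raise ParameterError(
            "baseline dynamics are monostable (A**2 <= 4 k_deg**2 B); "
            "p_hat normalisation requires a baseline high state"
        )
    return np.clip(np.asarray(P, dtype=float) / p_plus, 0.0, 1.0)


def step_phenotype(
    state: PhenotypeState,
    B_eff: float,
    pp: PhenotypeParams,
    noise: NoiseParams,
    d_hat: float,
    rng: np.random.Generator,
) -> PhenotypeState:
    """One forward-Euler update of a single cell's phenotype level.

    Production and degradation are evaluated at the pre-step P, both
    noise draws are added, and the result is clamped at zero.  The class
    is recomputed against the supplied B_eff.  Two standard-normal
    variates are always consumed from ``rng`` (even when a noise
    amplitude is zero) so the stream layout is independent of the
    parameter values.
    """
    if not 0.0 <= d_hat <= 1.0:
        raise DomainError(f"d_hat must lie in [0, 1], got {d_hat}")
    if B_eff <= 0:
        raise ParameterError(f"B_eff must be > 0, got {B_eff}")
    p_hat = float(phenotype_hat(state.P, pp))
    sd_ext = float(context_noise_sd(p_hat, d_hat, noise.N_ext))
    eps_int = rng.standard_normal() * noise.N_int
    eps_ext = rng.standard_normal() * sd_ext
    new_P = state.P + float(production_rate(state.P, pp.A, B_eff)) - pp.k_deg * state.P
    new_P = max(0.0, new_P + eps_int + eps_ext)
    return PhenotypeState(P=new_P, phenotype_class=classify_phenotype(new_P, pp.A, B_eff))
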