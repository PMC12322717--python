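"""Allometric scaling laws for metabolic, demographic, and interaction parameters.

Metabolic scaling theory posits that individual metabolic rate grows with
body mass as a 3/4 power law, and that demographic rates and densities
inherit related quarter-power exponents.  This module collects those laws
as pure functions of body mass (or population mean body mass), sharing a
single :class:`ScalingConstants` bundle of normalization constants:

====================================  ====================  =========
quantity                              law                   exponent
====================================  ====================  =========
metabolic rate                        b = b0 fT M^(3/4)       +3/4
mass-specific metabolic rate          b/M = b0 fT M^(-1/4)    -1/4
maximum intrinsic growth rate         r = r0 M^(-1/4)         -1/4
generation time                       G = g0 M^(1/4)          +1/4
biomass-density carrying capacity     K = K0 M^(1/4)          +1/4
abundance-density carrying capacity   K/M = K0 M^(-3/4)       -3/4
per-capita consumption rate           C = C0 M^(-1/4)         -1/4
competitive effect of j on i          a_ij = a0 (Mj/Mi)^α     α=-1/4
====================================  ====================  =========

The temperature response fT is treated as a fixed positive scalar: every
law here describes one thermal domain with one response, so temperature is
absorbed into the effective normalization constants.  All exponents carry
the canonical quarter-power defaults but are configurable, since empirical
estimates vary across taxa.

All functions accept scalars or numpy arrays of body mass and raise
``ValueError`` on nonpositive mass.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ScalingConstants",
    "metabolic_rate",
    "mass_specific_rate",
    "max_growth_rate",
    "generation_time",
    "carrying_capacity",
    "abundance_carrying_capacity",
    "consumption_rate",
    "consumption_from_demographics",
    "interaction_coefficient",
]


@dataclass(frozen=True)
class ScalingConstants:
    """Effective parameters shared by all allometric laws.

    Parameters
    ----------
    b0
        Metabolic normalization, units mass^(1/4) time^(-1).
    fT
        Dimensionless thermal response multiplier for the fixed thermal
        domain under study; must be positive.
    r0
        Growth-rate normalization, mass^(1/4) time^(-1).
    K0
        Carrying-capacity normalization, mass^(3/4) area^(-1).
    C0
        Consumption normalization, mass^(-3/4) area.
    a0_prime
        Dimensionless conversion factor relating competitive effects to
        consumption-rate ratios.
    a0
        Interaction normalization of the mass-ratio law for a_ij.
    g0
        Generation-time proportionality constant, time mass^(-1/4).
    alpha
        Interaction scaling exponent (default -1/4).
    consumption_exponent
        Exponent of the consumption-rate law (default -1/4; some taxa
        support -3/4 instead).
    """

    b0: float = 1.0
    fT: float = 1.0
    r0: float = 1.0
    K0: float = 1.0
    C0: float = 1.0
    a0_prime: float = 1.0
    a0: float = 1.0
    g0: float = 1.0
    alpha: float = -0.25
    consumption_exponent: float = -0.25

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("alpha", "consumption_exponent"):
                continue
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")


def _as_positive_mass(m: ArrayLike, name: str = "mass") -> NDArray[np.float64]:
    arr = np.asarray(m, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be finite and strictly positive")
    return arr


def _scalar_ok(m: ArrayLike, value: NDArray[np.float64]):
    # return a python float when the input was scalar-like
    return value.item() if np.ndim(m) == 0 else value


def metabolic_rate(m: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Individual metabolic rate b = b0 * fT * m^(3/4) (mass/time)."""
    mm = _as_positive_mass(m)
    return _scalar_ok(m, c.b0 * c.fT * mm ** 0.75)


def mass_specific_rate(m: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Mass-specific metabolism b/m = b0 * fT * m^(-1/4) (1/time)."""
    mm = _as_positive_mass(m)
    return _scalar_ok(m, c.b0 * c.fT * mm ** -0.25)


def max_growth_rate(M: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Maximum intrinsic growth rate r = r0 * M^(-1/4) (1/time).

    ``M`` is the population mean body mass; the growth rate inherits the
    exponent of mass-specific metabolism.
    """
    mm = _as_positive_mass(M)
    return _scalar_ok(M, c.r0 * mm ** -0.25)


def generation_time(M: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Generation time G = g0 * M^(1/4) (time).

    Only the proportionality G ∝ M^(1/4) is theoretically fixed; g0 is a
    free user parameter (default 1).  G * r = g0 * r0 for every mass.
    """
    mm = _as_positive_mass(M)
    return _scalar_ok(M, c.g0 * mm ** 0.25)


def carrying_capacity(M: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Biomass-density carrying capacity K = K0 * M^(1/4) (mass/area).

    The abundance-density capacity K0 * M^(-3/4) times mean individual
    mass M gives a net +1/4 exponent for biomass density.
    """
    mm = _as_positive_mass(M)
    return _scalar_ok(M, c.K0 * mm ** 0.25)


def abundance_carrying_capacity(M: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Abundance-density carrying capacity K/M = K0 * M^(-3/4) (individuals/area)."""
    mm = _as_positive_mass(M)
    return _scalar_ok(M, c.K0 * mm ** -0.75)


def consumption_rate(M: ArrayLike, c: ScalingConstants = ScalingConstants()):
    """Per-capita consumption rate C = C0 * M^e with e = ``consumption_exponent``.

    The default exponent is -1/4 (whole-organism consumption ∝ M^(3/4)
    divided by mass); the exponent is configurable because empirical
    studies report alternative dependencies.  Units mass^(-1) area.
    """
    mm = _as_positive_mass(M)
    return _scalar_ok(M, c.C0 * mm ** c.consumption_exponent)


def consumption_from_demographics(K: ArrayLike, r: ArrayLike, d: ArrayLike = 0.0):
    """Consumption rate from demographics: C = 1 / (K * (1 + d/r)).

    Expresses the time-averaged per-capita consumption rate of a
    population through its carrying capacity ``K``, maximum growth rate
    ``r`` and mortality rate ``d``.  With K ∝ M^(1/4) and a fixed d/r
    ratio this reproduces C ∝ M^(-1/4).
    """
    KK = np.asarray(K, dtype=float)
    rr = np.asarray(r, dtype=float)
    dd = np.asarray(d, dtype=float)
    if np.any(KK <= 0) or np.any(rr <= 0):
        raise ValueError("K and r must be strictly positive")
    if np.any(dd < 0):
        raise ValueError("mortality rate d must be nonnegative")
    out = 1.0 / (KK * (1.0 + dd / rr))
    if np.ndim(K) == 0 and np.ndim(r) == 0 and np.ndim(d) == 0:
        return float(out)
    return out


def interaction_coefficient(Mi: ArrayLike, Mj: ArrayLike,
                            c: ScalingConstants = ScalingConstants()):
    """Dimensionless competitive effect of population j on i.

    a_ij = a0 * (Mj / Mi)^alpha with alpha = -1/4 by default: the larger
    the mean body size of the competitor j relative to i, the weaker its
    per-unit-biomass competitive effect on i.  Equivalently (when
    a0 = a0'), a_ij = a0' * C(Mj) / C(Mi), the ratio of per-capita
    consumption rates.  Reciprocity: a_ij * a_ji = a0**2 for any masses.
    """
    mi = _as_positive_mass(Mi, "Mi")
    mj = _as_positive_mass(Mj, "Mj")
    out = c.a0 * (mj / mi) ** c.alpha
    if np.ndim(Mi) == 0 and np.ndim(Mj) == 0:
        return float(out)
    return out
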