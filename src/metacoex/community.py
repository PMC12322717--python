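"""Sampling body-mass vectors and assembling metabolically generated
competition matrices.

A community is summarized by a vector of |S| population mean body masses
M and the interaction matrix A they induce through the mass-ratio law
a_ij = a0 * (Mj/Mi)^alpha (off-diagonal) with a_ii = 1.  Masses are drawn
i.i.d. from a lognormal distribution; the default off-diagonal
normalization a0 = |S|^(-1/2) keeps interspecific competition weak
relative to self-regulation, widening the feasibility domain as real
communities appear to do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .scaling import _as_positive_mass

__all__ = [
    "Community",
    "EnsembleConfig",
    "resolve_a0",
    "sample_masses",
    "build_interaction_matrix",
    "metabolic_K_vector",
    "load_masses",
    "save_matrix",
]

A0Rule = "str | float"  # "inverse_sqrt_S" or a positive scalar


@dataclass(frozen=True)
class Community:
    """A body-mass vector together with its derived interaction matrix.

    Attributes
    ----------
    masses
        Vector of |S| positive population mean body masses.
    A
        |S| x |S| matrix of dimensionless competitive effects; unit
        diagonal, positive off-diagonals, reciprocity
        A[i, j] * A[j, i] = a0**2.
    a0
        Off-diagonal normalization used to build ``A``.
    alpha
        Interaction scaling exponent used to build ``A``.
    """

    masses: NDArray[np.float64]
    A: NDArray[np.float64]
    a0: float
    alpha: float

    @property
    def S(self) -> int:
        return self.masses.size

    def __post_init__(self) -> None:
        if self.A.shape != (self.S, self.S):
            raise ValueError("A must be |S| x |S|")


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of a Monte-Carlo community ensemble.

    ``log_mu`` and ``log_sigma`` are the mean and standard deviation of
    log body mass (LN(0, 2) default: log-mean 0, log-SD 2).  ``a0_rule``
    is either the string ``"inverse_sqrt_S"`` (a0 = S^(-1/2), the
    weak-interaction convention) or a positive scalar.
    """

    S: int = 50
    n_communities: int = 10_000
    log_mu: float = 0.0
    log_sigma: float = 2.0
    a0_rule: "str | float" = "inverse_sqrt_S"
    alpha: float = -0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("community size S must be at least 2")
        if self.n_communities < 1:
            raise ValueError("n_communities must be at least 1")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be nonnegative")
        resolve_a0(self.a0_rule, self.S)  # validate eagerly


def resolve_a0(rule: "str | float", S: int) -> float:
    """Resolve an a0 rule to a positive scalar for a community of size S."""
    if isinstance(rule, str):
        if rule == "inverse_sqrt_S":
            return float(S) ** -0.5
        raise ValueError(f"unknown a0 rule {rule!r}")
    a0 = float(rule)
    if not a0 > 0:
        raise ValueError("a0 must be strictly positive")
    return a0


def sample_masses(cfg: EnsembleConfig, rng: np.random.Generator) -> NDArray[np.float64]:
    """Draw |S| i.i.d. lognormal body masses.

    log M ~ Normal(cfg.log_mu, cfg.log_sigma); with log_sigma = 0 the
    distribution degenerates to the point mass exp(log_mu).
    """
    return np.exp(rng.normal(cfg.log_mu, cfg.log_sigma, size=cfg.S))


def build_interaction_matrix(masses: ArrayLike, alpha: float = -0.25,
                             a0_rule: "str | float" = "inverse_sqrt_S") -> Community:
    """Assemble the competition matrix A from a body-mass vector.

    A[i, j] = a0 * (M_j / M_i)^alpha for i != j and A[i, i] = 1, where a0
    follows ``a0_rule`` (default |S|^(-1/2)).  The off-diagonal part is
    the rank-structure m^(-alpha) outer m^(alpha): species of similar
    size compete near-symmetrically, while a small species exerts a
    stronger per-unit-biomass effect on a large one than vice versa
    (for alpha < 0).
    """
    m = _as_positive_mass(masses)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("masses must be a 1-D vector of length >= 2")
    S = m.size
    a0 = resolve_a0(a0_rule, S)
    ratio = m[np.newaxis, :] / m[:, np.newaxis]  # ratio[i, j] = Mj / Mi
    A = a0 * ratio ** alpha
    np.fill_diagonal(A, 1.0)
    return Community(masses=m, A=A, a0=a0, alpha=alpha)


def metabolic_K_vector(masses: ArrayLike, beta: float) -> NDArray[np.float64]:
    """Carrying-capacity direction K ∝ M^beta, component-wise.

    The normalization constant K0 is omitted: the angular distance to the
    centroid, like feasibility itself, depends only on direction.
    """
    m = _as_positive_mass(masses)
    return m ** beta


def load_masses(path) -> NDArray[np.float64]:
    """Read a one-column plain-text/CSV body-mass vector."""
    m = np.loadtxt(path, delimiter=",", ndmin=1)
    return _as_positive_mass(m)


def save_matrix(path, community: Community) -> None:
    """Export the interaction matrix as a headerless CSV."""
    np.savetxt(path, community.A, delimiter=",")
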