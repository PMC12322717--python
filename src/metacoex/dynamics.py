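"""Generalized Lotka-Volterra competition dynamics.

dN_i/dt = N_i (r_i / K_i) (K_i - sum_j a_ij N_j)

The algebraic equilibrium A N = K from :mod:`metacoex.geometry` is the
interior fixed point of these dynamics; this module makes that claim
executable by integrating the ODE and checking local stability through
the analytic Jacobian.  Convergence to the interior equilibrium is
asserted only when the Jacobian there is verified stable — feasibility
alone does not guarantee attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

__all__ = ["LVParameters", "Trajectory", "lv_rhs", "jacobian_at", "simulate"]

#: densities below this are clipped to exact zero (extinction is absorbing)
EXTINCTION_THRESHOLD = 1e-12


@dataclass(frozen=True)
class LVParameters:
    """Growth rates r, carrying capacities K (both positive, per
    population) and the dimensionless interaction matrix A."""

    r: NDArray[np.float64]
    K: NDArray[np.float64]
    A: NDArray[np.float64]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        K = np.asarray(self.K, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "A", A)
        S = r.size
        if K.shape != (S,) or A.shape != (S, S):
            raise ValueError("r, K, A shapes are inconsistent")
        if np.any(r <= 0) or np.any(K <= 0):
            raise ValueError("r and K must be strictly positive")

    @property
    def S(self) -> int:
        return self.r.size


def lv_rhs(N: ArrayLike, p: LVParameters) -> NDArray[np.float64]:
    """Time derivative of the biomass densities; exact zeros stay zero."""
    N = np.asarray(N, dtype=float)
    if N.shape != (p.S,):
        raise ValueError("state N does not match parameter dimension")
    return N * (p.r / p.K) * (p.K - p.A @ N)


def jacobian_at(N: ArrayLike, p: LVParameters) -> NDArray[np.float64]:
    """Analytic Jacobian of the dynamics at state N.

    J_ij = -(r_i/K_i) N_i a_ij + delta_ij (r_i/K_i)(K_i - sum_k a_ik N_k);
    at an interior equilibrium the diagonal residual term vanishes and
    J = -diag(r N*/K) A.
    """
    N = np.asarray(N, dtype=float)
    if N.shape != (p.S,):
        raise ValueError("state N does not match parameter dimension")
    g = p.r / p.K
    J = -(g * N)[:, None] * p.A
    J[np.diag_indices(p.S)] += g * (p.K - p.A @ N)
    return J


@dataclass(frozen=True)
class Trajectory:
    """ODE solution sampled at the solver's internal time points."""

    t: NDArray[np.float64]
    N: NDArray[np.float64]  # shape (len(t), S)

    @property
    def final(self) -> NDArray[np.float64]:
        return self.N[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, population, biomass_density)."""
        n_t, S = self.N.shape
        return pd.DataFrame({
            "time": np.repeat(self.t, S),
            "population": np.tile(np.arange(S), n_t),
            "biomass_density": self.N.ravel(),
        })


def simulate(N0: ArrayLike, p: LVParameters, t_end: float,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the competition dynamics from N0 over [0, t_end].

    Uses the stiff-capable LSODA scheme with the analytic Jacobian: wide
    body-mass ranges produce widely spread r_i/K_i and hence stiff
    systems.  Densities that dip below 1e-12 are clipped to exact zero
    in the reported trajectory (extinction is absorbing in the model and
    kept absorbing numerically).
    """
    N0 = np.asarray(N0, dtype=float)
    if N0.shape != (p.S,):
        raise ValueError("initial state does not match parameter dimension")
    if np.any(N0 < 0):
        raise ValueError("initial densities must be nonnegative")

    sol = solve_ivp(
        lambda t, N: lv_rhs(np.maximum(N, 0.0), p),
        (0.0, float(t_end)),
        N0,
        method="LSODA",
        jac=lambda t, N: jacobian_at(np.maximum(N, 0.0), p),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    N = sol.y.T.copy()
    N[N < EXTINCTION_THRESHOLD] = 0.0
    return Trajectory(t=sol.t, N=N)
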