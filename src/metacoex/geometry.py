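"""Feasibility-domain geometry: equilibrium, feasibility, centroid, and
the angular distance of a carrying-capacity direction to the centroid.

Under Lotka-Volterra competition the equilibrium is N* = A^(-1) K, and a
community is *feasible* when every component of N* is strictly positive.
Geometrically the set of carrying-capacity vectors compatible with
feasibility is the convex cone spanned by the columns of A; its centroid
Kc(A) — the arithmetic mean of the (raw) spanning columns — represents
the average carrying-capacity distribution across feasible environments
and, by construction, yields equal equilibrium biomass densities h = 1/S
for all populations.  The angular distance d(A, K) = arccos of the
cosine similarity between K and Kc(A), in degrees in [0, 90], measures
how far a given environmental condition sits from that average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "FeasibilityAssessment",
    "equilibrium",
    "is_feasible",
    "feasibility_status",
    "centroid",
    "equal_biomass_constant",
    "angular_distance",
    "assess",
    "sample_feasible_directions",
]

#: condition-number guard for the linear solve
COND_THRESHOLD = 1e12

#: equilibrium components in (0, BOUNDARY_BAND] are reported as "boundary"
BOUNDARY_BAND = 1e-12


@dataclass(frozen=True)
class FeasibilityAssessment:
    """Equilibrium, feasibility flag, and angular distance for one (A, K)."""

    N_star: NDArray[np.float64]
    feasible: bool
    distance_deg: float


def _check_system(A: ArrayLike, K: ArrayLike):
    A = np.asarray(A, dtype=float)
    K = np.asarray(K, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    if K.shape != (A.shape[0],):
        raise ValueError("K must be a vector matching A")
    return A, K


def equilibrium(A: ArrayLike, K: ArrayLike) -> NDArray[np.float64]:
    """Solve A N = K for the equilibrium biomass-density vector.

    Uses a linear solve (not explicit inversion).  Raises
    ``np.linalg.LinAlgError`` when A is singular or its condition number
    exceeds :data:`COND_THRESHOLD`.
    """
    A, K = _check_system(A, K)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        raise np.linalg.LinAlgError(
            f"interaction matrix is singular or ill-conditioned (cond={cond:.3e} "
            f"> {COND_THRESHOLD:.0e}); equilibrium is numerically unreliable"
        )
    return scipy.linalg.solve(A, K)


def is_feasible(A: ArrayLike, K: ArrayLike, tol: float = 0.0) -> bool:
    """True iff the equilibrium N* = A^(-1) K is strictly positive (min > tol)."""
    return bool(np.min(equilibrium(A, K)) > tol)


def feasibility_status(A: ArrayLike, K: ArrayLike) -> str:
    """Classify (A, K) as ``"feasible"``, ``"boundary"``, or ``"infeasible"``.

    Equilibria with a smallest component in (0, 1e-12] sit numerically on
    the cone boundary and are flagged rather than silently accepted:
    near-zero densities are one demographic fluctuation from extinction.
    """
    n_min = float(np.min(equilibrium(A, K)))
    if n_min > BOUNDARY_BAND:
        return "feasible"
    if n_min > 0.0:
        return "boundary"
    return "infeasible"


def centroid(A: ArrayLike, normalize: bool = False) -> NDArray[np.float64]:
    """Centroid of the feasibility domain: the mean of the columns of A.

    With ``normalize=False`` (default) the raw columns are averaged, and
    the equilibrium at the centroid is exactly uniform, (1/S, ..., 1/S).
    ``normalize=True`` averages unit-norm columns instead — a variant
    used elsewhere in the structuralist literature — for which the exact
    equal-density identity no longer holds.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    if normalize:
        A = A / np.linalg.norm(A, axis=0, keepdims=True)
    return A.mean(axis=1)


def equal_biomass_constant(A: ArrayLike) -> float:
    """The common equilibrium density h at the centroid.

    Solving A N = Kc(A) gives N = (h, ..., h); under the raw-column
    centroid h = 1/S exactly (A^(-1) A 1/S = 1/S).  Computed from the
    solve, not assumed.
    """
    N = equilibrium(A, centroid(A))
    h = float(N.mean())
    spread = float(N.max() - N.min())
    if spread > 1e-8 * max(1.0, abs(h)):
        raise np.linalg.LinAlgError(
            f"equilibrium at centroid not uniform (spread {spread:.3e}); "
            "matrix is numerically troublesome"
        )
    return h


def angular_distance(K: ArrayLike, Kc: ArrayLike) -> float:
    """Angle in degrees between directions K and Kc, in [0, 90] for
    nonnegative vectors.

    arccos of the cosine similarity; the argument is clamped to [-1, 1]
    to absorb rounding at collinearity, and cosines within one part in
    10^15 of 1 are snapped to 1 so that positively collinear vectors
    report exactly zero.  Scale-invariant: d(λK, Kc) = d(K, Kc) for any
    λ > 0.
    """
    K = np.asarray(K, dtype=float)
    Kc = np.asarray(Kc, dtype=float)
    nK = np.linalg.norm(K)
    nKc = np.linalg.norm(Kc)
    if nK == 0.0 or nKc == 0.0:
        raise ValueError("angular distance undefined for zero vectors")
    cosine = np.clip(np.dot(K, Kc) / (nK * nKc), -1.0, 1.0)
    if cosine > 1.0 - 1e-15:  # collinear up to float rounding
        return 0.0
    return float(np.degrees(np.arccos(cosine)))


def assess(A: ArrayLike, K: ArrayLike) -> FeasibilityAssessment:
    """Equilibrium solve, feasibility test, and distance to the centroid."""
    N = equilibrium(A, K)
    return FeasibilityAssessment(
        N_star=N,
        feasible=bool(np.min(N) > 0.0),
        distance_deg=angular_distance(K, centroid(A)),
    )


def sample_feasible_directions(A: ArrayLike, n: int, rng: np.random.Generator):
    """Draw n random positive K directions and label each by feasibility.

    Serves as a Monte-Carlo probe of the feasibility cone: every
    direction labeled feasible is, by the solve itself, a positive
    combination of the columns of A.  Returns ``(directions, labels)``
    with directions of unit norm, one per row.
    """
    A = np.asarray(A, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    raw = np.abs(rng.standard_normal((n, A.shape[0])))
    directions = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    labels = np.array([is_feasible(A, d) for d in directions], dtype=bool)
    return directions, labels
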