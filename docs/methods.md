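# Methods

## Model

`metacoex` studies generalized Lotka-Volterra competition,
dN_i/dt = N_i (r_i/K_i)(K_i − Σ_j a_ij N_j), in which every parameter is
generated from population mean body mass through quarter-power
allometric laws (see the README table).  The interaction coefficients
follow the mass-ratio law a_ij = a₀ (M_j/M_i)^α with α = −1/4 and
a_ii = 1: per unit biomass, larger competitors exert weaker effects.
This law arises from interpreting competition coefficients as ratios of
per-capita consumption rates, each scaling as M^(−1/4), so the M^(−1)
abundance corollary below does not depend on the particular consumption
exponent (α = −3/4 gives the same corollary, and both are exposed).

All temperature dependence is collapsed into a fixed positive scalar
multiplier f_T: the package describes one thermal domain and one thermal
response at a time, and makes no attempt to model temperature-response
curves.

Feasibility — existence of a strictly positive equilibrium
N\* = A⁻¹K — depends only on the direction of K.  The feasibility
domain is the convex cone spanned by the columns of A; its centroid is
the arithmetic mean of the *raw* columns.  Two competing conventions
exist in the structuralist literature (raw vs unit-normalized columns
before averaging).  The raw convention is the default here because it
alone makes the equal-density identity exact: A⁻¹K_c = (1/S, …, 1/S) is
an algebraic identity, verified in the tests to a max−min residual
below 10⁻¹⁰.  `centroid(A, normalize=True)` provides the other
convention for comparison.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| S | community size | 50 | large enough for the asymptotic regime, cheap to solve |
| n_communities | ensemble size | 10⁴ | Monte-Carlo SE of the mean distance well below the β-grid resolution |
| log_mu, log_sigma | mean, SD of log body mass | 0, 2 | lognormal LN(0, 2) spans ~7 orders of magnitude of mass |
| a0_rule | off-diagonal normalization | S^(−1/2) | weak-interaction convention; keeps total interspecific pressure on a population bounded as S grows |
| α | interaction exponent | −1/4 | consumption-ratio scaling |
| β grid | exponents tested for K ∝ M^β | [−2, 2], step 0.05 (0.25 in fast runs) | brackets every empirically proposed capacity exponent |
| g₀ | generation-time constant | 1 | only the M^(1/4) proportionality is theory-fixed |
| d/r | mortality-to-growth ratio | 1 | only the ratio enters the demographic consumption identity |
| f_T | thermal multiplier | 1 | fixed thermal domain |

All allometric exponents are configurable; the quarter-power values are
defaults, not assumptions baked into the code, since empirical exponents
vary across taxa.

The "LN(0, 2)" mass distribution is read as log-mean 0, log-**SD** 2.
The variance reading (log-SD √2) is obtainable by passing
`log_sigma=2**0.5`; the location of the distance minimum is insensitive
to this choice because the argmin is driven by the interaction-exponent
algebra, not by the mass spread.

## The ensemble experiment

For each community: sample S masses, build A, take its centroid; for
each β on the grid evaluate the angular distance between M^β and the
centroid; aggregate mean and SD across communities.  Distances are
recorded whether or not M^β is feasible for the particular community —
the angular distance is defined for any positive direction, and no
feasibility filter is applied.  With the default conventions the mean
distance is U-shaped in β with its grid minimum at β = 1/4, and the
minimum distance decreases toward an asymptote as S grows (compared at
S = 5 vs S = 100 in the tests).  Desk-scale runs use n = 200 communities
with a 0.25 grid step — the minimum at β = 1/4 is already unambiguous at
that ensemble size, with per-β standard errors an order of magnitude
smaller than the distance gap to the neighbouring grid points.

Randomness follows one master seed: per-community generators are spawned
from a `SeedSequence`, so results are reproducible regardless of
evaluation order or chunking.  Communities whose interaction matrix
fails the conditioning guard are skipped and counted (none arise under
the default conventions; the guard exists for user-supplied masses and
extreme a₀).

## What the generator emulates — and does not

The mass sampler emulates a size-structured competitive guild with
masses spanning several orders of magnitude and interactions set purely
by metabolism.  It does not emulate: empirical body-size distributions
(which are typically right-skewed beyond lognormal within guilds),
trophic structure, temperature-driven variation in interaction
strengths, or sampling error in measured interaction matrices.  Passing
tests therefore demonstrate the internal consistency of the
scaling-to-geometry argument, not that real communities sit at their
feasibility centroids.

## Numerical choices

- **Equilibria** are computed by LU solve (`scipy.linalg.solve`), never
  explicit inversion, behind a condition-number guard of 10¹²; beyond it
  a `LinAlgError` with the condition estimate is raised.
- **Feasibility** is strict positivity of N\*.  Equilibria whose
  smallest component lies in (0, 10⁻¹²] are classified "boundary" by
  `feasibility_status`, since such densities are one perturbation from
  extinction; `is_feasible` itself uses a user-settable tolerance
  (default 0).
- **Angular distance**: the cosine is clamped to [−1, 1], and cosines
  within one part in 10¹⁵ of 1 are snapped to 1 so positively collinear
  vectors report exactly 0°.  Distances are reported in degrees,
  range [0, 90] for nonnegative vectors.
- **ODE integration** uses LSODA with the analytic Jacobian,
  rtol 10⁻⁸ / atol 10⁻¹⁰: mass ranges of several orders of magnitude
  spread r_i/K_i widely and make the system stiff.  Densities below
  10⁻¹² are clipped to exact zero (extinction stays absorbing).
  Convergence to the interior equilibrium is asserted in tests only
  after the equilibrium Jacobian is verified stable — feasibility alone
  does not imply local attraction.
- **Slope fits** (exponent checks, abundance-density slope) are ordinary
  least squares on log-log axes via `numpy.polyfit`.

## Known limitations

- Only competitive interactions with the mass-ratio structure; no
  trophic or mutualistic links.
- Feasibility is the necessary coexistence condition analysed;
  dynamical stability is only spot-checked (Jacobian eigenvalues at
  specific equilibria), not systematically characterized.
- The exact a₀ value for which the two-species quarter-power direction
  coincides with the centroid is not derived; S = 2 is covered only by
  the generic worked example and the qualitative size-asymptotics check.
- No normalized feasibility volume (solid angle Ω) is computed; the
  angular distance to the centroid is the only geometric summary.
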