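# Methods

## Model and assumptions

A well-mixed population of fixed size N plays a symmetric game.  Payoffs
are computed as if everyone interacted with everyone else, excluding
self-interaction: with i mutants of strategy A among residents B,

    π_A(i) = [a_AA(i−1) + a_AB(N−i)] / (N−1),
    π_B(i) = [a_BA·i + a_BB(N−i−1)] / (N−1),

and for d-player games the focal's d−1 co-players are drawn without
replacement from the other N−1 individuals, giving hypergeometric
mixtures of the payoff table (computed via `scipy.stats.hypergeom`,
stable to N ~ 10⁴).  Self-exclusion is the convention that makes N = 2
well defined; adding a constant to all payoffs never changes anything
downstream because only payoff differences enter the dynamics.

Strategy updating is the pairwise comparison process: focal f imitates
model m with probability g(β(π_m − π_f)), g strictly increasing,
g(−∞) = 0, g(+∞) = 1.  Shipped rules: Fermi g(x) = 1/(1+e^{−x}) and the
rescaled error function g(x) = (1+erf(x))/2.  Any monotone rescaling of
the erf argument is equivalent to rescaling β, so the constant is fixed
at 1 and tests only assert scaling-invariant claims.  The
frequency-dependent Moran process is available with exponential
(f = e^{βπ}) and linear (f = 1+βπ, validity-checked for positivity)
payoff-to-fitness maps; the exponential map yields the same γ ratios as
the Fermi rule, hence identical fixation probabilities at every β — a
property test and an acceptance measurement pin this down to 1e−12.

Mutations are rare: each elementary step is a mutation with probability
μ (the focal adopts a uniformly chosen strategy, possibly its own —
this only rescales the effective mutation rate) and an imitation step
otherwise.  In the small-μ limit the population is almost always
monomorphic and the dynamics is the embedded n-state chain
Λ_ij = ρ_{j→i}/(n−1), where ρ_{j→i} is the fixation probability of a
single j-mutant among i-residents.  Self-mutations in the mutant kernel
are no-ops in this approximation and only rescale time, so the uniform
choice among the other n−1 strategies used in Λ is equivalent to the
uniform choice over all n; this is documented, not configurable.

## Numerics

**Fixation.**  ρ = 1/(1 + Σ exp S_k) with S_k the cumulative log ratios
Σ log γ_j.  All γ products are carried in log space; the denominator is
summed directly when max S_k < 700 (exact at neutrality: ρ(0) = 1/N to
the last bit) and by log-sum-exp otherwise.  `log_rho` is returned
alongside `rho` and stays informative when ρ underflows doubles.  Rules
whose g underflows to an exact zero at finite arguments (user-supplied
g without a stable log) raise an overflow signal instead of returning
garbage.

**Stationary distributions.**  The embedded chain's stationary vector
solves xΛ = x, Σx = 1.  Fixation probabilities at strong selection span
hundreds of orders of magnitude, and the textbook solve (replace one
balance equation by the normalization) destroys small components
through the rounded diagonal 1 − Σ(tiny) = 1; we observed it produce
abundance orderings that flipped randomly between grid points.  The
solver is therefore Grassmann–Taksar–Heyman state reduction — Gaussian
elimination rearranged to be subtraction-free — carried entirely in log
space, which returns every component with full relative accuracy.  For
two strategies x_A = expit(log ρ_A − log ρ_B) directly.  An
eigenvector-based solve is kept as an independent second method; the two
agree to 1e−10 on irreducible chains.  If some ρ underflows to exactly
zero (possible only in the per-point path at extreme β), the chain may
become reducible; mass is then placed on the closed communicating
classes and the result flagged.

**Weak selection.**  Strategies are ranked by dx/dβ at β = 0, estimated
from one-sided differences at steps h, h/2, h/4 with one Richardson
level (x(0) is exactly uniform, so one-sided differencing keeps β ≥ 0).
h is auto-tuned so that max|x(h) − 1/n| lies in [1e−3, 1e−2] — above
solver noise, inside the linear regime; if the two extrapolants disagree
by more than 1e−4 the step is reduced 8× once and the result flagged if
still non-convergent.  Ties below the achieved precision are reported as
tie groups, not broken arbitrarily.

**Strong selection.**  For log-linear rules (Fermi, exponential Moran)
S_k = −β P_k with P_k the partial sums of payoff differences, so the
β → ∞ limit is exact: ρ_∞ = 1 iff all P_k > 0, ρ_∞ = 0 if some P_k < 0,
and exact zeros leave a degenerate intermediate limit flagged as such.
Only the sign structure matters, which is why the strong-selection flow
between two strategies runs toward the risk-dominant one.  For other
rules the limit is bracketed on a geometric β ladder (2⁰..2¹⁵, relative
convergence 1e−9).

## Study protocol

Abundance curves are swept on a 200-point log-spaced β grid from 1e−3
to a per-game β_max, and a rank change is a sign change of
x_i − x_j between consecutive grid points with |x_i − x_j| > 1e−10 on
both sides.  Tangencies and sub-tolerance differences are flagged
degenerate and never counted; the exact tie at β = 0 is not a crossing.
Crossing locations are refined by bisection on β to 1e−6 relative
precision, each probe recomputing a full stationary distribution (no
interpolation).  The count converges with the grid: lowering β_min to
1e−4 or refining the grid 10× moves P(≥1 change) by well under one
Monte Carlo standard error, and a 30-game regression keeps the 200- vs
2000-point counts in agreement.

Two β_max notions coexist deliberately.  `adaptive_beta_max` answers
"where does *this implementation* stop producing finite log-domain
values" — for Fermi/erf in pure log space that is the cap (default
10³) for any game, and the probe only bites for bounded-validity rules
such as linear Moran fitness.  `study_beta_max` answers "where would
the classic linear-domain evaluation of ρ overflow doubles", i.e. the
largest β with max_k S_k ≤ log(DBL_MAX) ≈ 709.8 (closed form
709.8/max_k(−P_k) for log-linear rules; probed otherwise).  The
*studies* use `study_beta_max`: crossing counts depend on the β range
surveyed, and the reference statistics for random games were collected
inside the overflow-limited range (for uniform 3×3 games at N = 100 the
median bound is β ≈ 20; surveying to 10³ instead raises P(≥1) from
≈0.30 to ≈0.34 by counting crossings between astronomically rare
strategies).

Monte Carlo studies (`random_study`) sample payoff matrices with
i.i.d. Uniform(0,1) or standard Gaussian entries — these two
distributions *are* the study conditions, and results are reported for
both since the distribution has little influence.  Defaults: N = 100,
2000 samples, Fermi rule, seed-indexed sub-streams (seed, sample-index)
so results are independent of execution order.  Per-sample overflow
truncates that sample's grid at its own β_max (rejection would bias the
sample toward tame games).  Tail probabilities P(≥k) carry Wilson 95%
intervals (`statsmodels`); the expected count carries its standard
error.

The randomized searches demonstrate the two qualitative phenomena: a
2-strategy 3-player table (standard normal entries, N = 50) with zero
Fermi crossings but ≥ 1 erf crossing; and a 3×3 uniform game (N = 100)
whose weak-selection ranking equals the ranking at the top of its β
grid while ≥ 2 intermediate crossings occur.  The "strong-selection
ranking" used by the latter is the abundance ordering at β_max: the
exact β → ∞ classifier yields 0/1 fixation limits whose limiting chain
is typically reducible and orders only a subset of strategies, whereas
the top-of-grid ordering is total and is what the crossing count is
measured against.  Found instances self-verify on a 10× denser grid.
For d = 2 the first search provably cannot succeed and the test suite
confirms 10⁴ attempts find nothing.

## The stochastic simulator and what passing tests show

`sim_oracle` provides the two independent routes used to validate the
fast implementations: a direct tridiagonal solve of the absorbing
birth–death chain (no product formula), and a step-by-step simulation
of the full mutation–selection process (numba-compiled; ~2 s per 10⁷
steps).  The simulator supports two-player matrix games — the setting
all validation comparisons use; d-player groups would need group payoff
sampling that nothing downstream exercises.

The simulation reports two frequency estimates.  The raw time average
carries an O(μ)-order bias from polymorphic excursions: a doomed mutant
lineage still occupies the population for a while, which puts a floor
of order 10⁻³ (at μ = 10⁻³) under every strategy's apparent abundance —
far above embedded-chain components that can be 10⁻⁹.  The
monomorphic-conditioned average — time shares among monomorphic states
only — is the construct the embedded chain approximates and is the
estimator compared against x(β).  Standard errors come from a bootstrap
over 100 contiguous blocks (successive states are strongly
autocorrelated), with a Poisson floor p·√(2/#excursions) because a
state visited in a handful of excursions carries sampling noise that
contiguous blocks cannot resolve; components whose predicted share of
the run's ~10² excursions is below ~3 are below the run's resolution
and are only checked for consistency at that resolution.  Validation
runs use N = 20, μ = 10⁻³, 10⁷ steps, β = 1, where the population is
monomorphic > 90% of the time.

Passing these tests shows that the embedded-chain machinery, the
log-space fixation formula, and the simulator agree *with each other*
under the stated conditions (small μ, well-mixed population, the two
payoff distributions).  They say nothing about structured populations,
non-small mutation rates, or payoff distributions with heavy tails —
all outside the model.

## Problem sizes and defaults

| quantity | default | why |
|---|---|---|
| population size N | 100 (studies), 20 (simulation checks) | N = 100 matches the public-goods example's scale; crossing probabilities are nearly N-independent over 30–200.  N = 20 keeps 10⁷-step runs in the well-mixed small-μ regime |
| β grid | 200 log points, 1e−3 → study β_max (cap 10³) | crossings span orders of magnitude in β; counts are converged in grid density and lower bound |
| study samples | 2000 (headline), 500 (per-n scans) | Wilson CI halfwidth ≈ 0.02 at 2000 samples |
| mutation rate μ | 10⁻³ | N·μ·log N ≪ 1 with > 90% monomorphic time |
| crossing tolerance | 1e−10 absolute on abundance differences | separates real crossings from solver noise; degenerate near-ties are flagged, not counted |

## Known limitations

- Small-mutation limit only: no full 𝒪(Nⁿ)-state chains or μ sweeps.
- Crossing detection is grid-based; the dense-grid check bounds but does
  not prove that no crossing hides between grid points.
- The simulator handles matrix games and the fermi/erf rules only.
- Weak-selection derivatives are numerical (finite differences with
  Richardson extrapolation), not an analytic perturbation formula; the
  small-β evaluation oracle guards their correctness.
- Structured populations, bimatrix games, and optional-participation
  strategies are out of scope.
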