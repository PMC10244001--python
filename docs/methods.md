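# Methods

## Model and conventions

Two memory-one players repeat a prisoner's dilemma with stage payoffs
`T > R > P > S`. A strategy is a vector `p = [p1, p2, p3, p4]` of
cooperation probabilities conditioned on the previous round's outcome
(CC, CD, DC, DD), written from the owner's perspective (first letter =
own last move). The pair `(p, q)` induces a Markov chain on the four
outcomes; all long-run payoffs in this package are stationary averages
of that chain — there is no discounting and no within-round simulation.

Conventions fixed once and used everywhere:

* State order is (CC, CD, DC, DD) **from the focal player X's
  perspective**. The coplayer observes the letter-swapped outcome, so
  its cooperation probability in X-state `s` is `q[swap(s)]` with CD and
  DC exchanged. Baking the swap into `transition_matrix` is the single
  place perspective is handled.
* Payoff vectors over the outcome order are `(R, S, T, P)` for X and
  `(R, T, S, P)` for Y.
* Payoffs supplied as ints or `Fraction`s are kept exact so the regime
  sign `T + S − 2P` is computed without tolerance; float inputs use a
  `1e−12` sign tolerance. The degenerate boundary `T + S = 2P` is
  admitted and labelled `EQUAL`; no operation silently normalizes it
  away.

## Long-run distributions of reducible chains

Many interesting pairs give reducible chains (e.g. any two strategies
with `p1 = q1 = 1` make mutual cooperation absorbing). Recurrent classes
are found by strong-components analysis of the support graph (edge
present iff transition probability exceeds `1e−15`); each class's
internal stationary distribution comes from a dense left-null-space
solve with the normalization row substituted, plus one step of iterative
refinement. With several recurrent classes the result depends on the
start: the default initial condition is **mutual cooperation in round
one** (both players open nicely, as TFT-like strategies do), and the
limiting distribution mixes class distributions with the absorption
probabilities from that start. The initial distribution is an explicit
argument, so alternatives (e.g. TFT vs TFT started from unilateral
defection, which cycles CD/DC) are well defined and testable.

The Press–Dyson determinant-ratio payoff is provided as a second route;
it raises rather than returning garbage when its denominator determinant
is numerically zero (reducible pairs). Chain and determinant methods
agree to better than `1e−9` on ergodic instances, which the test suite
checks on random pairs.

## ZD algebra

`phi_upper(O, χ)` is derived from the four box constraints of the
parameterization — each entry is linear in `φ` with nonnegative slope,
so the bound is the smallest reciprocal slope. For `O = P` this
reproduces the two-branch closed form whose active branch switches with
the sign of `T + S − 2P`; for general `O` no closed form is assumed.
`χ = 1` is admitted as a closed boundary (the fair/TFT-like limit; at
`O = P`, `φ = 1/(T−S)` it is exactly TFT) because the learning dynamics
terminate there and the limit must be representable. The equalizer
family is the `χ → ∞` limit with `φ′ = φχ` held fixed. GTFT uses the
classical generosity level `g = min(1 − (T−R)/(R−S), (R−P)/(T−P))`.

## Unbending classification

A fixed strategy `q` is unbending to extortion when the probing ZD
family (baseline `O`, default `P`) has (i) `∂sX/∂φ = 0` and (ii)
`∂sX/∂χ < 0`. Membership is decided **numerically**, by grid tests that
are part of the public contract, rather than by transcribing closed-form
region boundaries:

* φ-independence: for each `χ ∈ {1.5, 2, 4, 8}`, `sX` is evaluated on a
  9-point φ-grid spanning `(0, φ_upper]`; the spread must stay below
  `1e−8`. Failure short-circuits the monotonicity scan.
* strict decrease: `sX` on a 64-point χ-grid over `(1+10⁻³, 10]`, with
  the probe's φ at half its upper bound (immaterial once independence
  holds); every consecutive difference must be below `−10⁻¹⁰` per unit
  step. Flat profiles — TFT, which always ties the probe at `P` — are
  therefore classified *not* unbending; they are boundary cases.

Region scans evaluate this test over the free coordinates of the two
structural families `[1, q2, 0, q4]` (class A) and `q4 = hD(q1, q2, q3)`
(class D, the same hyperplane every ZD strategy satisfies). In the
adversarial regime (`T + S < 2P`) the class-A scan also records where
the fixed player strictly outperforms the extortioner at every probed
`χ`. One caution learned from the scans: the `q4 = 0` edge of class A is
degenerate — against an exact `O = P` probe the chain locks into mutual
defection there and the payoff profile is flat — so probe-shift
robustness (`O = P + ε`) holds on the region's interior, not on that
edge.

## Learning dynamics

All three flows are deterministic gradient dynamics built on exact
stationary payoffs (the gameplay chain is assumed to equilibrate faster
than learning):

* integrator: explicit Euler with projection onto the box, defaults
  `dt = 0.01`, `2×10⁵` step cap, stop when the per-step state change
  falls below `1e−10`. Gradients are central differences (`h = 10⁻⁶`),
  one-sided at box faces; outward components are absorbed by the
  projection. Attractors, not paths, are the claims, so a first-order
  integrator suffices; the tests run with `dt = 0.05` and a few thousand
  steps, which reaches every attractor studied.
* terminal classification uses a `1e−3` coordinate tolerance; the TFT
  point `(1, 0)` takes precedence over the cooperative edge `p1 = 1`.
  A trajectory that neither converged nor reached a recognizable
  attractor is labelled `max_steps`.
* χ-learning holds the probe's φ at `φ_upper(χ)/2`, recomputed each
  step — legitimate only against φ-independent coplayers, which the
  contract enforces (`PhiDependenceError` otherwise) — and clips at the
  fair boundary `χ = 1`.
* the coadaptive system evolves `(p1, p2)` of a reactive focal player
  and `(q2, q4)` of a class-A coplayer with relative timescale `ω`;
  `ω = 0` reproduces the fixed-coplayer flow exactly (identical
  arithmetic, not merely close), `ω = 1` freezes the focal player.

The two class-A coplayers used to exhibit the two qualitative basin
structures in the donation game `b = 4, c = 1` were chosen by mapping
basins numerically: `[1, 0.2, 0, 0.1]` has an attracting
mutual-defection corner alongside the cooperative edge (bistability),
while the PSO Gambler `[1, 0.5217, 0, 0.1205]` sends every interior
start to full cooperation `p1 = 1`. The benefit-to-cost ratio 4 exceeds
the golden-ratio threshold `(√5+1)/2`, above which the payoff maximum
against a class-A unbending coplayer lies on the cooperative edge; the
threshold is read as the golden ratio `(√5+1)/2`.

## Moran dynamics

Fitness is exponential in payoff, `f = exp(βπ)` (a linear map
`1 + βπ` is available), with self-excluded payoff averaging in mixed
states — the convention under which the size-`N` favorability condition
`(N−2)a11 + N a12 > N a21 + (N−2)a22` emerges. Fixation probabilities
use the standard birth–death product formula accumulated in log domain
(plain summation when the exponents are small, `logsumexp` otherwise),
so strong selection at large `N` cannot overflow; neutral cases (β = 0,
or identical strategies) return exactly `1/N`. The independent oracle in
the tests solves the full `(N+1)`-state absorption system instead and
agrees to `1e−12` for `N ≤ 6`. Rare-mutation abundance is the limiting
distribution of the embedded chain over monomorphic states with
transitions `ρ(mutant invades resident)/(K−1)`, solved by the same
machinery as the outcome chains. Abundance experiments use the four
named strategies (PSO Gambler, generous ZD with χ = 2, TFT,
extortionate ZD with χ = 2); under strong selection (β = 1, N = 100)
the extortioner's abundance collapses below 0.01 while each unbending
strategy exceeds the population average.

## Monte-Carlo sweeps

Random coplayers are drawn uniformly from `[0, 1]⁴` with a seeded
generator; the ZD player's φ is drawn uniformly from its admissible
interval `(0, φ_upper]`, so no inadmissible strategy is ever evaluated.
Dominance counts are strict (`sX − sY > 10⁻¹²`; ties excluded). Default
sample size is 2000 per grid point; the test suite uses 300–1000 for
speed, which keeps binomial standard errors below the asserted margins.
Payoff surfaces over `(φ, χ)` grid absolute φ values masked by
admissibility; the one-humped non-monotonicity in χ appears along
fixed-φ sections of the surface, while every per-χ section is monotone
(or constant) in φ.

## What the random-coplayer model does and does not show

Uniform sampling of `[0, 1]⁴` is the standard reference ensemble for
dominance-probability statements, and all property suites (enforced
linear relation, payoff bounds, generosity comparisons) hold pointwise,
not just on average. But uniform coplayers are not a model of human or
evolved play: they have no error correction, no memory beyond one round,
and no strategic structure, so passing sweeps say nothing about
longer-memory opponents, discounted games, or noisy perception beyond
the implementation-error map studied explicitly.

## Known limitations

* Only infinite-horizon average payoffs: no discounting / finite
  continuation probability, no memory-two strategies.
* Unbending regions are numerical approximations on grids; exact
  symbolic boundaries are out of scope, and grid resolution trades
  accuracy for time.
* The strictness margin `−10⁻¹⁰` per unit χ is a choice: profiles
  decreasing more slowly than that are classified flat.
* Learning dynamics are deterministic gradient flows; stochastic
  (reinforcement-style) updates are not modelled.
* The rare-mutation limit is computed analytically; the Moran process
  itself is never simulated, and nonzero mutation rates are out of
  scope.
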