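# Methods

## The model

Species compete through their individuals.  An individual's *competitive
ability* (CA) is a scalar in `[0, 1]` summarising one generation's worth of
ecologically relevant performance; a pairwise contest is zero-sum with
payoffs +1 (win → self-replicate), −1 (lose → die), 0 (draw).  A species'
*strategy* is the distribution of CAs over its individuals together with its
population abundance:

* **Discrete model.** Weights `B(x_j) ≥ 0` on a finite ability set, with
  abundance `|B| = Σ B(x_j) > 0` and mean competitive ability
  `MCA(B) ≤ 1/2`.  The canonical ability set is the grid `{j/M}`, but the
  package admits arbitrary finite supports so designer strategies with
  off-grid points (e.g. Lake Wobegon's compensating ability
  `m = μ·n/(n−1)`) are represented exactly; the payoff engine merges
  supports onto their union before evaluating.
* **Continuous model.** A nonnegative density `f` on `[0, 1]` with
  `F(1) = ∫f > 0` and `MCA(f) ≤ 1/2`.  Piecewise-polynomial densities are
  integrated exactly through antiderivatives; arbitrary callables fall back
  to adaptive quadrature (absolute tolerance 1e-10, error reported, failure
  raises).

The MCA bound encodes that no species is made of perfect competitors;
abundances are positive reals and need not be integers (the simulator keeps
separate integer head-counts).

The multi-species payoff divides the signed mass comparison by the *total*
community abundance, focal species included.  Self-interaction cancels
exactly (the win/lose terms pair off), which has two load-bearing
consequences: a species' payoff is unchanged by its internal competition,
and a unilateral deviation's payoff is **linear** in the deviating weights.

## Equilibrium machinery

Equilibrium points are strategy collections in which no single species can
raise its payoff by changing only its own strategy.  Two independent routes
are implemented:

1. **Closed-form classifier.**  On the grid `{j/M}`: all weights equal and
   positive (`M` odd), or an alternating two-value pattern
   `B(x_{2j}) = B(x_0)`, `B(x_{2j+1}) = B(x_1)` with `MCA = 1/2` (`M` even).
   Continuous case: positive constant densities.  Equality checks use a
   relative tolerance of 1e-9 (constructors produce exact rationals only
   sometimes).  Per-value positivity is *not* required in the even case
   beyond `|B| > 0`: patterns such as `(a, 0, a, 0, a)` make the pooled
   bracket exactly linear in `x`, so no deviation with `MCA ≤ 1/2` scores
   positively — the oracle below confirms they are genuine grid equilibria.
2. **Best-response oracle.**  Because the deviation objective is linear, its
   maximum over the polytope `{weights ≥ 0, fixed abundance, MCA ≤ 1/2}` is
   attained at a vertex: a single ability `x ≤ 1/2`, or a two-point mixture
   straddling 1/2 with mean pinned at 1/2.  All `O(M²)` vertices are
   enumerated exactly.  A community is verified as an equilibrium point when
   every species' best-response gain is ≤ 1e-9 (relative to community
   abundance).  Deviations are evaluated at the incumbent's abundance: the
   definition permits any positive abundance, but the normalised objective's
   sign is abundance-invariant and matching makes gains comparable.

Single-strategy classification via the oracle uses the duplicated community
`[B, B]`: a singleton community is degenerate (with no opponents every
payoff is zero, so any lone strategy trivially "verifies"), whereas `[B, B]`
is an equilibrium point exactly when `B` is an equilibrium strategy.

**Grid-relativity.**  Equilibrium is a statement about the grid the game is
played on.  A point mass at 1/2 happens to satisfy the even-pattern test on
the coarse `M = 2` embedding `{0, 1/2, 1}` — deviations confined to three
abilities genuinely cannot beat it — but fails on every refinement, which is
where its defeaters live.  More generally any *atomic* distribution can be
beaten by an off-grid strategy that shifts mass infinitesimally above its
atoms and pays the mean-bound bill with mass at 0; only in the continuum
limit (constant densities, no atoms) does undefeatability become absolute.
The classifier and oracle therefore always agree *at a given M*, and the
counter designer controls the grid explicitly, as follows.

## Counter-strategy design

Given a target strategy, the designer first checks whether the target's
positive support is a complete canonical grid `{j/K}` on which it passes the
classifier; if so it is flagged as an equilibrium — within the game on its
grid no defeating strategy exists.  Otherwise it maximises the expected
pairwise score against the target over vertices with `MCA ≤ MCA(target)`
(the counter is cumulatively equally fit), drawing candidate abilities from
the target's support plus uniform refinements of `[0, 1]` at 16, 64, 256 and
1024 subdivisions — refinement supplies the "slightly above an atom"
abilities that designer strategies exploit.  A strictly positive score
certifies that the target's payoff is negative in the two-species
equal-abundance community.  Degenerate targets with `MCA = 0` (all mass at
ability 0) admit no matched-MCA counter — any winning mass forces a positive
mean — and produce an explicit no-counter result rather than a silently
relaxed bound.

## Individual-based simulator

Each round: every individual draws a fresh ability from its species'
normalised strategy (no heritability of the realised ability — heterogeneity
is a species property); a uniform random perfect matching is formed over the
pooled community, one uniformly chosen individual sitting out when the total
is odd; each pair is resolved by the sign kernel, transferring one
individual from the loser's species to the winner's.  Consequences used as
invariants and tests: the total head-count is conserved, intra-species pairs
never change counts, extinction is exactly zero individuals and is
absorbing, and trajectories are bit-reproducible from (community, rounds,
seed) through a single named `numpy` generator.

The expected one-round change equals the payoff functional evaluated at the
integer head-counts, times `N/(N−1)` for even pooled count `N` (pairing
probability `1/(N−1)`) and times 1 for odd `N` (sit-out makes it `1/N`).
`estimate_expected_change` verifies this by Monte Carlo within 3 standard
errors.

## Scenario defaults

The figure-level experiments are registered with declared defaults (the
model fixes none of these quantitatively):

| scenario | community | rounds | replicates |
|---|---|---|---|
| fig4 | invariant(0.5) ×1000 vs Lake Wobegon ×1000 | 10 | 100 |
| fig5 | uniform ×1000 vs Lake Wobegon ×1000 | 50 | 100 |
| fig6 | uniform ×1000 vs invariant(0.5) ×1000 | 50 | 100 |
| fig7 | uniform + invariant + Lake Wobegon + bimodal + gaussian, ×1000 each | 50 | 100 |
| fig8 | uniform ×200 vs invariant(0.5) ×20000 (1% relative abundance) | 50 | 100 |
| fig9 | 25 uniform species ×200 (fig9_full: 301 species) | 50 | 50 |
| s1 | uniform ×1000 vs invariant(0.3) ×1000 | 50 | 100 |
| s2 | uniform vs Lake Wobegon at n ∈ {10, 100, 1000} | 50 | 100 |

Rationale: "uniform" strategies are discretised at `M = 1000`, fine enough
that the residual discretisation drift against off-grid equal-MCA opponents
is O(1e-6) per cross pairing (the theory's neutrality is a continuum
statement; a coarse uniform grid would leak a small systematic advantage to
Lake Wobegon via tie-breaking).  1000 individuals per species is the regime
in which demographic noise (per-round standard deviation ≈ √(cross-pairs) ≈
22) cannot plausibly bridge the distance to extinction within the horizon;
fig8 scales the same 1% ratio to 200 vs 20 000 for the same reason; fig9 is
a deliberately scaled-down coexistence panel — the full 301-species
community is registered as `fig9_full` but not part of the default run.
Replicate batches derive per-replicate seeds by seed-sequence spawning, so a
scenario summary is a pure function of (name, seed).  Success thresholds
(e.g. "extinct in ≥ 90% of replicates") are declared interpretations of
qualitative claims, not measured constants.

## What the generator does and does not emulate

The synthetic communities realise the game's own assumptions: well-mixed
pairing, synchronous rounds, zero-sum bookkeeping, fresh per-round trait
draws.  They do not emulate spatial structure, resource dynamics,
environmental fluctuation, overlapping generations, or evolution of the
strategies themselves (all declared non-goals).  Passing scenario tests
therefore demonstrates internal consistency between the analytic payoffs
and the stochastic tournament under the model's assumptions — not that real
microbial communities obey them.

## Known limitations

* Equilibrium classification is exact only on a declared grid; callers
  comparing strategies across grids should classify on the common
  refinement (`infer_grid_resolution` helps).
* The counter designer's refinement ladder is finite (up to 1024
  subdivisions); targets whose defeaters require still finer structure
  would return no-counter, though none were observed in randomized suites.
* Quadrature-based continuous payoffs for arbitrary callables are limited
  by `scipy.integrate.quad` behaviour near non-smooth densities; prefer the
  exact piecewise-polynomial representation where possible.
* Simulated head-counts are bounded only by memory; communities of ~10⁵
  individuals per round are routine, far larger ones are not the intended
  regime.
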