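# phenogame

A non-cooperative competition game for asexually reproducing microbes, built
for theoretical ecologists studying why phenotypically heterogeneous species
coexist.  Each species is a *player* whose mixed strategy is the probability
distribution of competitive abilities (traits) across its individuals, scaled
by population abundance.  Individuals meet pairwise in a zero-sum contest —
the higher ability wins (+1, self-replicate), the lower loses (−1, die),
ties draw (0) — and the species-level payoff aggregates those contests over
the whole community.

## Model

A discrete strategy on the ability grid `{j/M}` is a map
`B : {x_j} → [0, ∞)` with abundance `|B| = Σ_j B(x_j) > 0` and mean
competitive ability `MCA(B) = (1/|B|) Σ_j x_j B(x_j) ≤ 1/2` (individuals are
not perfect).  The payoff to species `A_k` when `A_1, …, A_n` compete
simultaneously is

    ℘(A_k) = (1 / Σ_ℓ |A_ℓ|) Σ_j A_k(x_j) [ Σ_{i<j} pooled(x_i) − Σ_{i>j} pooled(x_i) ],

with `pooled(x_i) = Σ_ℓ A_ℓ(x_i)`; the continuous model replaces sums by
integrals of a nonnegative density `f` on `[0, 1]`.  Payoffs are zero-sum and
internal competition within a species cancels.

The equilibrium strategies — those no species can unilaterally improve on —
are exactly the maximally heterogeneous ones: all weights equal and positive
(`M` odd), a two-value alternating pattern with `MCA = 1/2` (`M` even), and
positive constant densities in the continuous model.  They are *neutral*
towards any strategy of equal MCA (unlimited coexistence) and strictly beat
any lower-MCA strategy (competitive exclusion).  Every non-equilibrium
strategy can be defeated by a "cumulatively equally fit" designer
counter-strategy; the package constructs one by exact vertex enumeration of
the linear best-response problem.  An individual-based tournament simulator
(fresh ability draws each round, uniform random pairing, integer
head-counts) reproduces these outcomes stochastically.

## Worked example

```python
from phenogame import (make_invariant, make_lake_wobegon, payoff_discrete,
                       design_counter_strategy, run_simulation)

inv = make_invariant(0.5, 1000, label="invariant")        # all abilities 0.5
lw  = make_lake_wobegon(1000, 0.5, 1000, label="wobegon") # one 0, rest 0.5005…

print(payoff_discrete([inv, lw]).as_dict())
# {'invariant': -499.0, 'wobegon': 499.0}

traj = run_simulation([inv, lw], rounds=10, seed=42)
print(traj.counts[:, 0].tolist())
# [1000, 504, 124, 14, 0, 0, 0, 0, 0, 0, 0]
print(traj.extinction_events)
# (('invariant', 4),)

print(design_counter_strategy(make_invariant(0.5, 100)).counter)
# DiscreteStrategy('counter_invariant', n_points=2, abundance=100, mca=0.5)
```

Both species have MCA exactly 0.5, yet the Lake Wobegon strategy wins 99.8%
of cross pairings (payoff −499 of the invariant's 1000 individuals per
round), and in the stochastic tournament the invariant species is extinct by
round 4.  The counter designer, asked to defeat the invariant strategy,
rediscovers a Lake-Wobegon-type two-point strategy (mass 1/9 at 0, 8/9 at
0.5625) with the same MCA and expected pairwise score +0.78.  Against the
*uniform* (equilibrium) strategy the designer instead reports that no
defeating strategy exists, and simulated uniform cohorts coexist with any
equal-MCA competitor — run `phenogame reproduce fig6` to watch.

The same commands are available from the shell: `phenogame payoff`,
`phenogame equilibrium-check`, `phenogame counter`, `phenogame simulate`,
and `phenogame reproduce <scenario>` for the registered figure-level
experiments (fig4–fig9, s1, s2); see `phenogame --help`.

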