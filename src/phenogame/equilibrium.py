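"""Equilibrium classification, best-response oracle, counter-strategy design.

The complete characterisation of equilibrium strategies on the canonical
ability grid ``{j/M}`` is:

* ``M`` odd  — equilibrium iff all ``M + 1`` weights are equal and positive;
* ``M`` even — equilibrium iff MCA = 1/2 and the weights alternate between
  two values, ``B(x_{2j}) = B(x_0)`` and ``B(x_{2j+1}) = B(x_1)``;
* continuous — equilibrium iff the density is a positive constant.

Sums of equilibrium strategies are again equilibrium strategies, and any
collection of equilibrium strategies forms an equilibrium point.

An independent numerical oracle backs the closed-form classifier: because
self-interaction cancels, a unilateral deviation's payoff is *linear* in its
normalised weights, so the best response over the constraint polytope
(weights >= 0, fixed abundance, MCA <= 1/2) is attained at a vertex — a
single support point at or below 1/2, or a two-point mixture straddling 1/2
with MCA exactly 1/2.  Enumerating all O(M^2) vertices yields the exact
best response without relying on the classifier.

The counter-strategy designer operationalises the recipe for defeating any
non-equilibrium strategy: it searches the same vertex family, constrained to
MCA at most the target's own MCA (the counter is "cumulatively equally
fit"), over the target's support augmented with progressively refined
off-grid candidate abilities.  Against the invariant strategy this recovers
a Lake-Wobegon-type two-point counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .payoff_engine import (
    PayoffError,
    _bracket,
    expected_pairwise_score,
    merged_weight_table,
    payoff_discrete,
)
from .strategies import (
    MCA_BOUND,
    Community,
    ContinuousStrategy,
    DiscreteStrategy,
    StrategyError,
    grid_weights,
    infer_grid_resolution,
    is_on_grid,
)

__all__ = [
    "ClassificationResult",
    "BestResponseResult",
    "EquilibriumVerdict",
    "CounterDesign",
    "is_equilibrium_strategy_discrete",
    "is_equilibrium_strategy_continuous",
    "best_response",
    "verify_equilibrium_point",
    "oracle_is_equilibrium_strategy",
    "design_counter_strategy",
]

GAIN_TOL = 1e-9


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the closed-form equilibrium test, with the failing condition."""

    is_equilibrium: bool
    reason: str

    def __bool__(self) -> bool:
        return self.is_equilibrium


@dataclass(frozen=True)
class BestResponseResult:
    """Exact constrained best response of one species against fixed opponents."""

    optimal_deviation: DiscreteStrategy
    deviation_gain: float
    argmax_vertex: str
    incumbent_payoff: float
    deviation_payoff: float


@dataclass(frozen=True)
class EquilibriumVerdict:
    """Community-level equilibrium check: per-species best-response gains."""

    is_equilibrium: bool
    gains: dict[str, float]
    tolerance: float

    def __bool__(self) -> bool:
        return self.is_equilibrium


@dataclass(frozen=True)
class CounterDesign:
    """Result of the counter-strategy search against a single target."""

    is_equilibrium: bool
    counter: DiscreteStrategy | None
    expected_score: float
    reason: str


# ---------------------------------------------------------------------------
# closed-form classifiers
# ---------------------------------------------------------------------------


def _relative_spread(values: np.ndarray) -> float:
    scale = float(np.max(np.abs(values))) if values.size else 0.0
    if scale == 0.0:
        return 0.0
    return float((values.max() - values.min()) / scale)


def is_equilibrium_strategy_discrete(
    strategy: DiscreteStrategy, M: int, tol: float = 1e-9
) -> ClassificationResult:
    """Closed-form equilibrium test on the canonical grid ``{j/M}``.

    The strategy's support must lie on the grid (a domain error otherwise);
    missing grid points are treated as zero weights.
    """
    if int(M) != M or M < 1:
        raise StrategyError("grid resolution M must be an integer >= 1")
    M = int(M)
    if not is_on_grid(strategy, M, tol):
        raise StrategyError(
            f"strategy {strategy.label!r} is not supported on the grid {{j/{M}}}; "
            "the characterisation is a grid statement"
        )
    w = grid_weights(strategy, M, tol)
    if M % 2 == 1:
        if _relative_spread(w) > tol:
            return ClassificationResult(
                False, f"M={M} odd: weights are not all identical"
            )
        if w[0] <= 0.0:
            return ClassificationResult(False, f"M={M} odd: weights are not positive")
        return ClassificationResult(True, f"M={M} odd: constant positive weights")
    even, odd = w[0::2], w[1::2]
    if _relative_spread(even) > tol or (odd.size and _relative_spread(odd) > tol):
        return ClassificationResult(
            False, f"M={M} even: weights do not follow the two-value alternating pattern"
        )
    m = strategy.mca
    if abs(m - MCA_BOUND) > tol:
        return ClassificationResult(
            False, f"M={M} even: MCA {m:.12g} differs from 1/2"
        )
    return ClassificationResult(
        True, f"M={M} even: alternating two-value pattern with MCA = 1/2"
    )


def is_equilibrium_strategy_continuous(
    strategy: ContinuousStrategy, n_probe: int = 257, tol: float = 1e-9
) -> bool:
    """True iff the density is a positive constant on [0, 1]."""
    probe = np.linspace(0.0, 1.0, int(n_probe))
    if strategy.is_piecewise_polynomial:
        probe = np.unique(np.concatenate([probe, strategy.density.x]))
    vals = np.asarray(strategy(probe), dtype=float)
    if vals.min() <= 0.0:
        return False
    return _relative_spread(vals) <= tol


# ---------------------------------------------------------------------------
# vertex enumeration (the independent oracle)
# ---------------------------------------------------------------------------


def _best_vertex(
    scores: np.ndarray, points: np.ndarray, mca_bound: float, tol: float = 1e-12
) -> tuple[float, np.ndarray, np.ndarray, str]:
    """Maximise a linear objective over {p >= 0, sum p = 1, p . x <= bound}.

    Vertices are single points with ``x <= bound`` and two-point mixtures
    ``x_i < bound < x_j`` with mean exactly ``bound``.  Returns the best
    value, its support, mixture weights, and a human-readable description.
    """
    best_val = -np.inf
    best: tuple[np.ndarray, np.ndarray, str] | None = None
    feasible = points <= mca_bound + tol
    if np.any(feasible):
        idx = int(np.argmax(np.where(feasible, scores, -np.inf)))
        best_val = float(scores[idx])
        best = (
            points[idx : idx + 1],
            np.array([1.0]),
            f"single support point x={points[idx]:.6g}",
        )
    lo = np.where(points < mca_bound - tol)[0]
    hi = np.where(points > mca_bound + tol)[0]
    if lo.size and hi.size:
        xi, xj = points[lo][:, None], points[hi][None, :]
        wi = (xj - mca_bound) / (xj - xi)
        vals = wi * scores[lo][:, None] + (1.0 - wi) * scores[hi][None, :]
        i, j = np.unravel_index(int(np.argmax(vals)), vals.shape)
        if float(vals[i, j]) > best_val:
            best_val = float(vals[i, j])
            a, b = lo[i], hi[j]
            w = float((points[b] - mca_bound) / (points[b] - points[a]))
            best = (
                np.array([points[a], points[b]]),
                np.array([w, 1.0 - w]),
                f"two-point mixture x=({points[a]:.6g}, {points[b]:.6g}) "
                f"with MCA pinned at {mca_bound:.6g}",
            )
    if best is None:
        raise PayoffError("constraint polytope is empty: no feasible deviation")
    return best_val, best[0], best[1], best[2]


def _community_grid_M(strategies: Sequence[DiscreteStrategy], max_M: int = 4096) -> int:
    merged = strategies[0]
    for s in strategies[1:]:
        merged = merged + s
    M = infer_grid_resolution(merged, max_M=max_M)
    if M is None:
        raise StrategyError(
            "community strategies do not share a canonical grid {j/M} with "
            f"M <= {max_M}; the equilibrium oracle is a grid statement"
        )
    return M


def best_response(
    community,
    focal_index: int,
    deviation_abundance: float | None = None,
    M: int | None = None,
) -> BestResponseResult:
    """Exact best response of one species, opponents held fixed.

    Deviations range over grid strategies with the given abundance (default:
    the incumbent's, making gains well-posed; the sign of the normalised
    objective is abundance-invariant).  ``deviation_gain`` is the deviation's
    payoff minus the incumbent's and is always >= 0 because the incumbent
    itself is feasible.
    """
    strategies = (
        list(community.strategies) if isinstance(community, Community) else list(community)
    )
    if not strategies:
        raise PayoffError("empty community")
    focal = strategies[focal_index]
    if M is None:
        M = _community_grid_M(strategies)
    grid = np.arange(int(M) + 1) / int(M)
    opponents_pooled = np.zeros(grid.size)
    for i, s in enumerate(strategies):
        if i != focal_index:
            opponents_pooled += grid_weights(s, int(M))
    bracket = _bracket(opponents_pooled)

    ab = focal.abundance if deviation_abundance is None else float(deviation_abundance)
    if not ab > 0.0:
        raise StrategyError("deviation abundance must be positive")
    total = float(opponents_pooled.sum()) + ab
    best_val, supp, mix, desc = _best_vertex(bracket, grid, MCA_BOUND)
    incumbent_val = float(grid_weights(focal, int(M)) / focal.abundance @ bracket)
    deviation = DiscreteStrategy(supp, mix * ab, f"best_response_to_{focal.label}")
    inc_payoff = ab * incumbent_val / total
    dev_payoff = ab * best_val / total
    return BestResponseResult(
        optimal_deviation=deviation,
        deviation_gain=max(dev_payoff - inc_payoff, 0.0),
        argmax_vertex=desc,
        incumbent_payoff=inc_payoff,
        deviation_payoff=dev_payoff,
    )


def verify_equilibrium_point(
    community, tol: float = GAIN_TOL, M: int | None = None
) -> EquilibriumVerdict:
    """Numerical equilibrium-point check: no species has an improving deviation."""
    strategies = (
        list(community.strategies) if isinstance(community, Community) else list(community)
    )
    if not strategies:
        raise PayoffError("empty community")
    if M is None:
        M = _community_grid_M(strategies)
    gains: dict[str, float] = {}
    for k, s in enumerate(strategies):
        gains[s.label] = best_response(strategies, k, M=M).deviation_gain
    scale = max(1.0, sum(s.abundance for s in strategies))
    ok = all(g <= tol * scale for g in gains.values())
    return EquilibriumVerdict(ok, gains, tol)


def oracle_is_equilibrium_strategy(
    strategy: DiscreteStrategy, M: int | None = None, tol: float = GAIN_TOL
) -> bool:
    """Best-response oracle for a single strategy.

    A strategy is an equilibrium strategy iff the duplicated community
    ``[B, B]`` is an equilibrium point (collections of equilibrium strategies
    are equilibrium points, and equilibrium points decompose into equilibrium
    strategies).  The singleton community is degenerate — with no opponents
    every payoff is zero — so duplication is what gives the test power.
    """
    pair = [strategy.relabeled("incumbent"), strategy.relabeled("twin")]
    return bool(verify_equilibrium_point(pair, tol=tol, M=M))


# ---------------------------------------------------------------------------
# counter-strategy design
# ---------------------------------------------------------------------------


def _score_vs_target(points: np.ndarray, target: DiscreteStrategy) -> np.ndarray:
    """E[sign kernel] of a deterministic ability against the target distribution."""
    p = target.probabilities
    cum = np.concatenate([[0.0], np.cumsum(p)])
    lo = np.searchsorted(target.support, points, side="left")
    hi = np.searchsorted(target.support, points, side="right")
    return cum[lo] - (1.0 - cum[hi])


def design_counter_strategy(
    target: DiscreteStrategy,
    tol: float = GAIN_TOL,
    refinements: Sequence[int] = (16, 64, 256, 1024),
    max_natural_M: int = 4096,
) -> CounterDesign:
    """Construct a strategy that defeats a non-equilibrium target.

    If the target's positive-weight support is exactly a canonical grid
    ``{j/K}`` on which it passes the closed-form equilibrium test, no
    defeating strategy exists within the game and the equilibrium flag is
    returned.  Otherwise the search maximises the expected pairwise score
    over strategies with MCA at most ``MCA(target)`` (equal cumulative
    fitness), enumerating vertices over the target's support joined with
    uniformly refined candidate abilities; refinement supplies the
    slightly-above-a-mass-point abilities that designer counters such as
    Lake Wobegon exploit.  A positive score implies the target's payoff is
    strictly negative in the two-species equal-abundance community.
    """
    pos = target.support[target.weights > 0.0]
    K = pos.size - 1
    if K >= 1 and np.allclose(pos, np.arange(K + 1) / K, atol=1e-12):
        compacted = target.compact()
        cls = is_equilibrium_strategy_discrete(compacted, K)
        if cls:
            return CounterDesign(
                True, None, 0.0, f"equilibrium — no defeating strategy exists ({cls.reason})"
            )
    mu = target.mca
    for n_grid in refinements:
        candidates = np.unique(
            np.concatenate([pos, [0.0, 1.0], np.linspace(0.0, 1.0, n_grid + 1)])
        )
        scores = _score_vs_target(candidates, target)
        best_val, supp, mix, desc = _best_vertex(scores, candidates, mu)
        if best_val > tol:
            counter = DiscreteStrategy(
                supp, mix * target.abundance, f"counter_{target.label}"
            )
            achieved = expected_pairwise_score(counter, target)
            return CounterDesign(False, counter, float(achieved), desc)
    return CounterDesign(
        False,
        None,
        0.0,
        "no counter found at matched mean competitive ability; the target's MCA "
        "leaves no room for a winning mass (e.g. all mass at ability 0)",
    )
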