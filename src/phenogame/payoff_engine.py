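"""Multi-species payoff functionals and the pairwise sign kernel.

Competition between two individuals is zero-sum: the one with the higher
competitive ability scores +1 (self-replicates), the other scores -1 (dies),
and equal abilities draw (0).  At the species level the payoff to species
``A_k`` in a community ``A_1..A_n`` on a shared ability grid is

    P(A_k) = (1 / sum_l |A_l|) * sum_j A_k(x_j) *
             [ sum_{i<j} pooled(x_i) - sum_{i>j} pooled(x_i) ]

with ``pooled(x_i) = sum_l A_l(x_i)`` (empty sums are zero), and analogously
with integrals for continuous densities.  Payoffs sum to zero over the
community; internal competition within a species cancels and never changes
its own payoff.  Finite-support strategies are merged onto the union of their
supports before evaluation, so communities mixing different grids (or
off-grid designer strategies) are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.integrate import quad

from .strategies import (
    Community,
    ContinuousStrategy,
    DiscreteStrategy,
    StrategyError,
    _pp_product_integral,
    _pp_sum,
)

__all__ = [
    "PayoffError",
    "PayoffVector",
    "sign_kernel",
    "merged_weight_table",
    "payoff_discrete",
    "payoff_continuous",
    "payoff",
    "expected_pairwise_score",
]

ZERO_SUM_TOL = 1e-10


class PayoffError(ValueError):
    """Raised for invalid payoff evaluations or quadrature failures."""


@dataclass(frozen=True)
class PayoffVector:
    """Per-species payoffs for one community state; sums to zero."""

    labels: tuple[str, ...]
    values: np.ndarray
    total_abundance: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if abs(values.sum()) > ZERO_SUM_TOL * max(1.0, self.total_abundance):
            raise PayoffError(
                f"payoffs violate the zero-sum invariant: residual {values.sum():.3e}"
            )

    @property
    def residual(self) -> float:
        """Deviation of the payoff sum from zero (diagnostic)."""
        return float(self.values.sum())

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.values[self.labels.index(label)])
        except ValueError:
            raise KeyError(label) from None

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(self.labels, map(float, self.values)))

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.labels, self.values)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{l}={v:.6g}" for l, v in self)
        return f"PayoffVector({body})"


def sign_kernel(ca_a: float, ca_b: float) -> int:
    """Outcome of one pairwise contest for the first individual.

    +1 if ``ca_a > ca_b`` (win, self-replicate), -1 if ``ca_a < ca_b``
    (lose, die), 0 on a tie (draw, status quo).
    """
    if not (0.0 <= ca_a <= 1.0) or not (0.0 <= ca_b <= 1.0):
        raise PayoffError(
            f"competitive abilities must lie in [0, 1], got ({ca_a}, {ca_b})"
        )
    if ca_a > ca_b:
        return 1
    if ca_a < ca_b:
        return -1
    return 0


def _strategy_list(community) -> list:
    if isinstance(community, Community):
        return list(community.strategies)
    strategies = list(community)
    if not strategies:
        raise PayoffError("empty community")
    return strategies


def merged_weight_table(
    strategies: Sequence[DiscreteStrategy], tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Union support grid and the (species x support) weight matrix.

    Support values closer than ``tol`` are identified (they would tie in the
    sign kernel anyway up to floating error).
    """
    raw = np.unique(np.concatenate([s.support for s in strategies]))
    keep = np.ones(raw.size, dtype=bool)
    keep[1:] = np.diff(raw) > tol
    grid = raw[keep]
    W = np.zeros((len(strategies), grid.size))
    for row, s in enumerate(strategies):
        idx = np.searchsorted(grid, s.support)
        idx = np.clip(idx, 0, grid.size - 1)
        left = np.clip(idx - 1, 0, grid.size - 1)
        idx = np.where(
            np.abs(grid[left] - s.support) < np.abs(grid[idx] - s.support), left, idx
        )
        if np.any(np.abs(grid[idx] - s.support) > tol):
            raise PayoffError("failed to align supports on the merged grid")
        np.add.at(W[row], idx, s.weights)
    return grid, W


def _bracket(pooled: np.ndarray) -> np.ndarray:
    """Per grid point: pooled mass strictly below minus strictly above."""
    cum = np.cumsum(pooled)
    below = cum - pooled
    above = pooled.sum() - cum
    return below - above


def payoff_discrete(community) -> PayoffVector:
    """Evaluate the finite-support payoff functional for a whole community."""
    strategies = _strategy_list(community)
    for s in strategies:
        if not isinstance(s, DiscreteStrategy):
            raise PayoffError("payoff_discrete requires finite-support strategies")
    _, W = merged_weight_table(strategies)
    total = float(W.sum())
    values = W @ _bracket(W.sum(axis=0)) / total
    abundances = W.sum(axis=1)
    if np.any(np.abs(values) > abundances * (1.0 + 1e-12) + 1e-12):
        raise PayoffError("per-species payoff exceeded its abundance bound")
    return PayoffVector(tuple(s.label for s in strategies), values, total)


def payoff_continuous(community) -> PayoffVector:
    """Evaluate the continuous payoff functional.

    All-piecewise-polynomial communities are integrated exactly via
    antiderivatives; otherwise adaptive quadrature at absolute tolerance
    1e-10 is used and non-convergence raises :class:`PayoffError`.
    """
    strategies = _strategy_list(community)
    for s in strategies:
        if not isinstance(s, ContinuousStrategy):
            raise PayoffError("payoff_continuous requires continuous strategies")
    total = float(sum(s.abundance for s in strategies))
    if all(s.is_piecewise_polynomial for s in strategies):
        pooled_cdf = _pp_sum([s.density for s in strategies]).antiderivative()
        values = np.array(
            [
                2.0 * _pp_product_integral(s.density, pooled_cdf)
                - total * s.abundance
                for s in strategies
            ]
        ) / total
    else:
        cdfs = [s.cumulative for s in strategies]

        def pooled_cdf_at(x: float) -> float:
            return float(sum(c(x) for c in cdfs))

        values = np.empty(len(strategies))
        for i, s in enumerate(strategies):
            integrand = lambda x: float(s(np.array([x]))[0]) * (
                2.0 * pooled_cdf_at(x) - total
            )
            val, err = quad(integrand, 0.0, 1.0, epsabs=1e-10, limit=200)
            if err > 1e-6 * max(1.0, abs(val)):
                raise PayoffError(
                    f"quadrature did not converge for species {s.label!r}: "
                    f"value {val:.6g}, estimated error {err:.3g}"
                )
            values[i] = val
        values /= total
        # enforce exact zero-sum bookkeeping against quadrature round-off
        values -= values.sum() / len(values)
    return PayoffVector(tuple(s.label for s in strategies), values, total)


def payoff(community) -> PayoffVector:
    """Dispatch to the discrete or continuous payoff functional."""
    strategies = _strategy_list(community)
    if isinstance(strategies[0], DiscreteStrategy):
        return payoff_discrete(strategies)
    return payoff_continuous(strategies)


def _score_against_discrete(points: np.ndarray, target: DiscreteStrategy) -> np.ndarray:
    """P(target draws below each point) - P(above), i.e. E[sign] per ability."""
    p = target.probabilities
    cum = np.cumsum(p)
    # mass strictly below / strictly above each query point
    lo = np.searchsorted(target.support, points, side="left")
    hi = np.searchsorted(target.support, points, side="right")
    total_below = np.concatenate([[0.0], cum])[lo]
    total_above = 1.0 - np.concatenate([[0.0], cum])[hi]
    return total_below - total_above


def expected_pairwise_score(strategy_a, strategy_b) -> float:
    """Expected sign-kernel score of a random A individual vs a random B individual.

    Equals ``P(X_a > X_b) - P(X_a < X_b)`` under independent draws from the
    normalised strategies; antisymmetric in its arguments and zero for
    identical distributions.
    """
    if isinstance(strategy_a, DiscreteStrategy) and isinstance(strategy_b, DiscreteStrategy):
        s = _score_against_discrete(strategy_a.support, strategy_b)
        return float(strategy_a.probabilities @ s)
    if isinstance(strategy_a, ContinuousStrategy) and isinstance(strategy_b, ContinuousStrategy):
        fb1 = strategy_b.abundance
        if strategy_a.is_piecewise_polynomial and strategy_b.is_piecewise_polynomial:
            val = _pp_product_integral(
                strategy_a.density, strategy_b.density.antiderivative()
            )
            return float(2.0 * val / (strategy_a.abundance * fb1) - 1.0)
        fa = strategy_a

        def integrand(x: float) -> float:
            return float(fa(np.array([x]))[0]) * (
                2.0 * float(strategy_b.cumulative(x)) / fb1 - 1.0
            )

        val, _ = quad(integrand, 0.0, 1.0, epsabs=1e-10, limit=200)
        return float(val / strategy_a.abundance)
    if isinstance(strategy_a, DiscreteStrategy) and isinstance(strategy_b, ContinuousStrategy):
        cdf = strategy_b.cumulative(strategy_a.support) / strategy_b.abundance
        return float(strategy_a.probabilities @ (2.0 * np.asarray(cdf) - 1.0))
    if isinstance(strategy_a, ContinuousStrategy) and isinstance(strategy_b, DiscreteStrategy):
        return -expected_pairwise_score(strategy_b, strategy_a)
    raise PayoffError("unsupported strategy types for expected_pairwise_score")
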