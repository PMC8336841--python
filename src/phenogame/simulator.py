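"""Individual-based stochastic tournament.

Each round, every individual is assigned a fresh competitive ability drawn
from its species' strategy (no heritability of a specific ability across
rounds — phenotypic heterogeneity is a property of the species, not the
lineage).  A uniform-random perfect matching is formed over the pooled
community (with an odd head-count one uniformly chosen individual sits
out), and every pair is resolved zero-sum: the higher ability wins and its
species gains one individual, the loser's species loses one, ties draw.
Intra-species pairs therefore never change that species' count, matching
the cancellation of internal competition in the payoff functional.

Head-counts are integers; extinction is exactly zero individuals, and an
extinct species is never resampled.  Trajectories are bit-reproducible from
(community, rounds, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .payoff_engine import payoff_discrete
from .strategies import Community, DiscreteStrategy, StrategyError

__all__ = [
    "SimulationComplete",
    "PopulationState",
    "Trajectory",
    "assign_abilities",
    "run_round",
    "run_simulation",
    "estimate_expected_change",
    "expected_change_analytic",
]


class SimulationComplete(RuntimeError):
    """Raised by run_round when fewer than two individuals remain."""


def _sampler(strategy: DiscreteStrategy) -> tuple[np.ndarray, np.ndarray]:
    """(support, cumulative probabilities) for fast inverse-CDF sampling."""
    return strategy.support, np.cumsum(strategy.probabilities)


def assign_abilities(
    strategy: DiscreteStrategy, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_individuals`` fresh abilities from the normalised strategy."""
    if n_individuals < 0:
        raise StrategyError("cannot assign abilities to a negative head-count")
    support, cum = _sampler(strategy)
    if support.size == 1:
        return np.full(n_individuals, support[0])
    idx = np.searchsorted(cum, rng.random(n_individuals), side="right")
    return support[np.minimum(idx, support.size - 1)]


@dataclass
class PopulationState:
    """Integer head-counts plus the transient per-round abilities."""

    labels: tuple[str, ...]
    strategies: tuple[DiscreteStrategy, ...]
    counts: np.ndarray
    round_index: int = 0
    abilities: np.ndarray | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Trajectory:
    """Per-round head-counts for every species, with extinction events."""

    labels: tuple[str, ...]
    counts: np.ndarray  # shape (rounds + 1, n_species), row 0 = initial state
    seed: int
    extinction_events: tuple[tuple[str, int], ...]
    fingerprint: str

    @property
    def rounds(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def final_counts(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(self.labels, self.counts[-1])}

    def extinct(self, label: str) -> bool:
        return self.final_counts[label] == 0

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns round, species, count."""
        rounds = np.repeat(np.arange(self.counts.shape[0]), len(self.labels))
        species = np.tile(np.array(self.labels, dtype=object), self.counts.shape[0])
        return pd.DataFrame(
            {"round": rounds, "species": species, "count": self.counts.ravel()}
        )

    def summary(self) -> dict:
        return {
            "seed": int(self.seed),
            "rounds": int(self.rounds),
            "final_counts": self.final_counts,
            "extinction_events": [[lab, int(r)] for lab, r in self.extinction_events],
            "config_fingerprint": self.fingerprint,
        }


def _fingerprint(strategies: Sequence[DiscreteStrategy], counts: np.ndarray, rounds: int) -> str:
    payload = {
        "species": [
            {
                "label": s.label,
                "support": [repr(float(x)) for x in s.support],
                "weights": [repr(float(w)) for w in s.weights],
            }
            for s in strategies
        ],
        "counts": [int(c) for c in counts],
        "rounds": int(rounds),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_round(state: PopulationState, rng: np.random.Generator) -> PopulationState:
    """Advance one round: assign abilities, match uniformly, resolve pairs."""
    counts = state.counts
    total = int(counts.sum())
    if total < 2:
        raise SimulationComplete(f"only {total} individual(s) remain")
    k = counts.size
    species = np.repeat(np.arange(k), counts)
    abilities = np.empty(total)
    offset = 0
    for i in range(k):
        n_i = int(counts[i])
        if n_i:
            abilities[offset : offset + n_i] = assign_abilities(
                state.strategies[i], n_i, rng
            )
        offset += n_i
    perm = rng.permutation(total)
    m = total - (total % 2)  # one uniformly chosen individual sits out if odd
    a, b = perm[0:m:2], perm[1:m:2]
    outcome = np.sign(abilities[a] - abilities[b]).astype(np.int64)
    delta = np.zeros(k, dtype=np.int64)
    np.add.at(delta, species[a], outcome)
    np.add.at(delta, species[b], -outcome)
    return PopulationState(
        labels=state.labels,
        strategies=state.strategies,
        counts=counts + delta,
        round_index=state.round_index + 1,
        abilities=abilities,
    )


def _initial_counts(community, counts: Sequence[int] | None) -> np.ndarray:
    strategies = (
        list(community.strategies) if isinstance(community, Community) else list(community)
    )
    if counts is None:
        counts = [int(round(s.abundance)) for s in strategies]
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size != len(strategies):
        raise StrategyError("one initial count per species is required")
    if np.any(counts < 1):
        raise StrategyError("every species needs at least one individual to start")
    return counts


def run_simulation(
    community,
    rounds: int,
    seed: int,
    counts: Sequence[int] | None = None,
    stop_on_extinction: bool = False,
) -> Trajectory:
    """Run the tournament for a fixed number of rounds.

    Initial head-counts default to each strategy's rounded abundance.  The
    trajectory always has ``rounds + 1`` rows; once fewer than two
    individuals remain (or, with ``stop_on_extinction``, after the first
    extinction) the state is frozen for the remaining rows.
    """
    if rounds < 1:
        raise StrategyError("at least one round is required")
    strategies = tuple(
        community.strategies if isinstance(community, Community) else community
    )
    labels = tuple(s.label for s in strategies)
    counts = _initial_counts(strategies, counts)
    rng = np.random.default_rng(seed)
    state = PopulationState(labels=labels, strategies=strategies, counts=counts)
    history = np.empty((rounds + 1, len(strategies)), dtype=np.int64)
    history[0] = counts
    alive = counts > 0
    extinctions: list[tuple[str, int]] = []
    frozen = False
    for r in range(1, rounds + 1):
        if not frozen:
            try:
                state = run_round(state, rng)
            except SimulationComplete:
                frozen = True
        history[r] = state.counts
        newly_dead = alive & (state.counts == 0)
        for i in np.nonzero(newly_dead)[0]:
            extinctions.append((labels[i], r))
        alive = state.counts > 0
        if stop_on_extinction and extinctions and not frozen:
            history[r + 1 :] = state.counts
            break
    return Trajectory(
        labels=labels,
        counts=history,
        seed=int(seed),
        extinction_events=tuple(extinctions),
        fingerprint=_fingerprint(strategies, counts, rounds),
    )


def expected_change_analytic(community, counts: Sequence[int] | None = None) -> np.ndarray:
    """Exact expected one-round head-count change per species.

    Under uniform random perfect matching the probability that two given
    individuals are paired is ``1/(N-1)`` for even pooled count ``N`` and
    ``1/N`` when odd (one sits out), so the expectation is the payoff
    functional evaluated at the integer head-counts, rescaled by
    ``N/(N-1)`` (even) or left as is (odd).
    """
    strategies = (
        list(community.strategies) if isinstance(community, Community) else list(community)
    )
    counts = _initial_counts(strategies, counts)
    scaled = [
        s.scaled(float(c)) for s, c in zip(strategies, counts)
    ]
    values = payoff_discrete(scaled).values
    total = int(counts.sum())
    factor = total / (total - 1) if total % 2 == 0 else 1.0
    return values * factor


def estimate_expected_change(
    community,
    replicates: int = 1000,
    seed: int = 0,
    counts: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Monte Carlo mean one-round change per species, with standard errors.

    Used as the simulator/payoff agreement oracle: the ``mean`` column
    should match :func:`expected_change_analytic` within a few ``se``.
    """
    if replicates < 2:
        raise StrategyError("at least two replicates are required")
    strategies = tuple(
        community.strategies if isinstance(community, Community) else community
    )
    labels = tuple(s.label for s in strategies)
    counts = _initial_counts(strategies, counts)
    rng = np.random.default_rng(seed)
    deltas = np.empty((replicates, len(strategies)), dtype=np.int64)
    base = PopulationState(labels=labels, strategies=strategies, counts=counts)
    for r in range(replicates):
        deltas[r] = run_round(base, rng).counts - counts
    mean = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(replicates)
    return pd.DataFrame(
        {
            "species": list(labels),
            "mean": mean,
            "se": se,
            "analytic": expected_change_analytic(strategies, counts),
        }
    )
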