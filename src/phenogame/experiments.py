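"""Figure-level scenario registry: named, seeded, reproducible experiments.

Each scenario packages a community, a round count, a replicate count and a
success criterion computable from the trajectories alone (extinction
frequencies and extant fractions).  Replicates use seed-sequence spawning,
so a batch is bit-reproducible from (scenario name, seed).

The registered scenarios mirror the model's headline simulation results:

* ``fig4`` — the invariant strategy is eliminated by Lake Wobegon (equal MCA);
* ``fig5`` — Lake Wobegon coexists with the uniform (equilibrium) strategy;
* ``fig6`` — the uniform strategy coexists with the invariant strategy;
* ``fig7`` — the uniform strategy persists amid several equal-MCA strategies;
* ``fig8`` — a rare uniform cohort (1% relative abundance) persists;
* ``fig9`` — many equilibrium species coexist with few extinctions
  (scaled to 25 species; ``fig9_full`` keeps the 301-species setting);
* ``s1``  — a lower-MCA competitor is competitively excluded;
* ``s2``  — small uniform cohorts go extinct more often (sampling noise
  obscures the strategy), with extinction frequency falling as n grows.

Numbers not fixed by the model (population sizes, rounds) are declared
defaults chosen to sit in the regimes the figures depict; every threshold in
a criterion is an interpretation of a qualitative claim, not a measured
value.  See docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simulator import Trajectory, run_simulation
from .strategies import (
    Community,
    make_invariant,
    make_lake_wobegon,
    make_bimodal,
    make_truncated_gaussian,
    make_uniform,
)

__all__ = [
    "Scenario",
    "BatchResult",
    "ScenarioResult",
    "SCENARIOS",
    "run_scenario",
    "sweep",
]

#: Grid resolution used for "uniform" strategies in scenarios: fine enough
#: that discretisation drift against off-grid equal-MCA opponents is
#: negligible over the simulated horizons (near-continuum regime).
UNIFORM_M = 1000


@dataclass(frozen=True)
class BatchResult:
    """All replicate trajectories of one scenario run."""

    trajectories: tuple[Trajectory, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.trajectories[0].labels

    def extinction_frequency(self, label: str) -> float:
        return float(np.mean([t.extinct(label) for t in self.trajectories]))

    def survival_frequency(self, label: str) -> float:
        return 1.0 - self.extinction_frequency(label)

    def all_extant_frequency(self) -> float:
        return float(
            np.mean(
                [all(c > 0 for c in t.final_counts.values()) for t in self.trajectories]
            )
        )

    def mean_fraction_extant(self) -> float:
        return float(
            np.mean(
                [
                    np.mean([c > 0 for c in t.final_counts.values()])
                    for t in self.trajectories
                ]
            )
        )

    def final_counts_frame(self) -> pd.DataFrame:
        rows = [
            {"replicate": i, "species": lab, "final_count": c}
            for i, t in enumerate(self.trajectories)
            for lab, c in t.final_counts.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Scenario:
    """A named, config-determined experiment with a declared success criterion."""

    name: str
    description: str
    community_factory: Callable[[], Community]
    rounds: int
    replicates: int
    criterion: Callable[[BatchResult], bool]
    criterion_description: str
    runner: Callable | None = None  # non-standard scenarios (sweeps)


@dataclass(frozen=True)
class ScenarioResult:
    name: str
    seed: int
    replicates: int
    rounds: int
    criterion_passed: bool
    criterion_description: str
    summary: dict
    batch: BatchResult | None = None
    table: pd.DataFrame | None = None


SCENARIOS: dict[str, Scenario] = {}


def _register(scenario: Scenario) -> Scenario:
    SCENARIOS[scenario.name] = scenario
    return scenario


def _run_batch(
    community: Community, rounds: int, replicates: int, seed: int
) -> BatchResult:
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    trajectories = tuple(
        run_simulation(community, rounds, int(s)) for s in child_seeds
    )
    return BatchResult(trajectories)


def _quantiles(batch: BatchResult) -> dict[str, dict[str, float]]:
    frame = batch.final_counts_frame()
    out: dict[str, dict[str, float]] = {}
    for label, grp in frame.groupby("species"):
        q = grp["final_count"].quantile([0.05, 0.5, 0.95])
        out[str(label)] = {
            "q05": float(q.loc[0.05]),
            "median": float(q.loc[0.5]),
            "q95": float(q.loc[0.95]),
        }
    return out


def run_scenario(
    name: str,
    seed: int = 0,
    replicates: int | None = None,
    rounds: int | None = None,
    keep_trajectories: bool = True,
) -> ScenarioResult:
    """Run a registered scenario and evaluate its success criterion."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}"
        )
    sc = SCENARIOS[name]
    replicates = sc.replicates if replicates is None else int(replicates)
    rounds = sc.rounds if rounds is None else int(rounds)
    if sc.runner is not None:
        return sc.runner(sc, seed=seed, replicates=replicates, rounds=rounds)
    community = sc.community_factory()
    batch = _run_batch(community, rounds, replicates, seed)
    passed = bool(sc.criterion(batch))
    summary = {
        "scenario": name,
        "seed": int(seed),
        "replicates": replicates,
        "rounds": rounds,
        "extinction_frequency": {
            lab: batch.extinction_frequency(lab) for lab in batch.labels
        },
        "final_abundance_quantiles": _quantiles(batch),
        "criterion": sc.criterion_description,
        "criterion_passed": passed,
    }
    return ScenarioResult(
        name=name,
        seed=int(seed),
        replicates=replicates,
        rounds=rounds,
        criterion_passed=passed,
        criterion_description=sc.criterion_description,
        summary=summary,
        batch=batch if keep_trajectories else None,
    )


def sweep(
    community_factory: Callable[..., Community],
    grid: dict[str, Sequence],
    rounds: int,
    replicates: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Run a factory over a parameter grid; long-format results table.

    One row per (grid cell, replicate, species) with the final count and an
    extinction flag.  An empty grid yields an empty table.
    """
    keys = list(grid)
    cells = list(itertools.product(*(grid[k] for k in keys))) if keys else []
    rows: list[dict] = []
    root = np.random.SeedSequence(seed)
    cell_seeds = root.generate_state(max(len(cells), 1)) % (2**31)
    for cell_idx, values in enumerate(cells):
        params = dict(zip(keys, values))
        community = community_factory(**params)
        batch = _run_batch(community, rounds, replicates, int(cell_seeds[cell_idx]))
        for rep, traj in enumerate(batch.trajectories):
            for lab, count in traj.final_counts.items():
                rows.append(
                    {
                        **params,
                        "replicate": rep,
                        "species": lab,
                        "final_count": int(count),
                        "extinct": count == 0,
                    }
                )
    columns = keys + ["replicate", "species", "final_count", "extinct"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# registered scenarios
# ---------------------------------------------------------------------------


def _fig4_community() -> Community:
    return Community(
        [
            make_invariant(0.5, 1000, label="invariant"),
            make_lake_wobegon(1000, 0.5, 1000, label="lake_wobegon"),
        ]
    )


_register(
    Scenario(
        name="fig4",
        description="Invariant strategy eliminated by the equal-MCA Lake Wobegon strategy.",
        community_factory=_fig4_community,
        rounds=10,
        replicates=100,
        criterion=lambda b: b.extinction_frequency("invariant") >= 0.90,
        criterion_description="invariant extinct in >= 90% of replicates",
    )
)


def _fig5_community() -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, 1000, label="uniform"),
            make_lake_wobegon(1000, 0.5, 1000, label="lake_wobegon"),
        ]
    )


_register(
    Scenario(
        name="fig5",
        description="Lake Wobegon (which defeats invariant) coexists with the uniform equilibrium strategy.",
        community_factory=_fig5_community,
        rounds=50,
        replicates=100,
        criterion=lambda b: b.all_extant_frequency() >= 0.90,
        criterion_description="both species extant at the final round in >= 90% of replicates",
    )
)


def _fig6_community() -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, 1000, label="uniform"),
            make_invariant(0.5, 1000, label="invariant"),
        ]
    )


_register(
    Scenario(
        name="fig6",
        description="Uniform equilibrium strategy coexists with the invariant strategy (equal MCA).",
        community_factory=_fig6_community,
        rounds=50,
        replicates=100,
        criterion=lambda b: b.all_extant_frequency() >= 0.90,
        criterion_description="both species extant at the final round in >= 90% of replicates",
    )
)


def _fig7_community() -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, 1000, label="uniform"),
            make_invariant(0.5, 1000, label="invariant"),
            make_lake_wobegon(1000, 0.5, 1000, label="lake_wobegon"),
            make_bimodal(UNIFORM_M, 0.5, 0.5, 1000, label="bimodal"),
            make_truncated_gaussian(UNIFORM_M, 0.5, 0.1, 1000, label="gaussian"),
        ]
    )


_register(
    Scenario(
        name="fig7",
        description="Uniform equilibrium strategy resists invasion among equal-MCA competitors.",
        community_factory=_fig7_community,
        rounds=50,
        replicates=100,
        criterion=lambda b: b.survival_frequency("uniform") >= 0.90,
        criterion_description="uniform extant at the final round in >= 90% of replicates",
    )
)


def _fig8_community() -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, 200, label="uniform"),
            make_invariant(0.5, 20000, label="invariant"),
        ]
    )


_register(
    Scenario(
        name="fig8",
        description="Rare uniform cohort (1% relative abundance) persists against an equal-MCA majority.",
        community_factory=_fig8_community,
        rounds=50,
        replicates=100,
        criterion=lambda b: b.survival_frequency("uniform") >= 0.90,
        criterion_description="uniform extant at the final round in >= 90% of replicates",
    )
)


def _many_uniform_community(n_species: int, per_species: int) -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, per_species, label=f"uniform_{i:03d}")
            for i in range(n_species)
        ]
    )


_register(
    Scenario(
        name="fig9",
        description="Many equilibrium species coexist: 25 uniform species of 200 individuals.",
        community_factory=lambda: _many_uniform_community(25, 200),
        rounds=50,
        replicates=50,
        criterion=lambda b: b.mean_fraction_extant() >= 0.90,
        criterion_description="on average >= 90% of species extant at the final round",
    )
)

_register(
    Scenario(
        name="fig9_full",
        description="Full-size coexistence run: 301 uniform species of 200 individuals (long).",
        community_factory=lambda: _many_uniform_community(301, 200),
        rounds=100,
        replicates=3,
        criterion=lambda b: b.mean_fraction_extant() >= 0.90,
        criterion_description="on average >= 90% of species extant at the final round",
    )
)


def _s1_community() -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, 1000, label="uniform"),
            make_invariant(0.3, 1000, label="inferior"),
        ]
    )


_register(
    Scenario(
        name="s1",
        description="Competitive exclusion: a lower-MCA competitor is eliminated by the uniform strategy.",
        community_factory=_s1_community,
        rounds=50,
        replicates=100,
        criterion=lambda b: b.extinction_frequency("inferior") >= 0.95,
        criterion_description="lower-MCA competitor extinct in >= 95% of replicates",
    )
)


def _uniform_vs_wobegon(n: int) -> Community:
    return Community(
        [
            make_uniform(UNIFORM_M, n, label="uniform"),
            make_lake_wobegon(max(int(n), 2), 0.5, n, label="lake_wobegon"),
        ]
    )


def _s2_runner(sc: Scenario, seed: int, replicates: int, rounds: int) -> ScenarioResult:
    sizes = [10, 100, 1000]
    table = sweep(
        _uniform_vs_wobegon,
        {"n": sizes},
        rounds=rounds,
        replicates=replicates,
        seed=seed,
    )
    focal = table[table["species"] == "uniform"]
    freqs = {int(n): float(g["extinct"].mean()) for n, g in focal.groupby("n")}
    ordered = [freqs[n] for n in sizes]
    passed = all(a >= b for a, b in zip(ordered, ordered[1:])) and ordered[0] > ordered[-1]
    summary = {
        "scenario": sc.name,
        "seed": int(seed),
        "replicates": replicates,
        "rounds": rounds,
        "uniform_extinction_frequency_by_n": freqs,
        "criterion": sc.criterion_description,
        "criterion_passed": bool(passed),
    }
    return ScenarioResult(
        name=sc.name,
        seed=int(seed),
        replicates=replicates,
        rounds=rounds,
        criterion_passed=bool(passed),
        criterion_description=sc.criterion_description,
        summary=summary,
        table=table,
    )


_register(
    Scenario(
        name="s2",
        description=(
            "Small populations fail to realise the uniform strategy: extinction "
            "frequency of the uniform cohort decreases with population size."
        ),
        community_factory=lambda: _uniform_vs_wobegon(100),
        rounds=50,
        replicates=100,
        criterion=lambda b: True,  # handled by the sweep runner
        criterion_description=(
            "uniform extinction frequency non-increasing over n in {10, 100, 1000} "
            "and strictly lower at n=1000 than at n=10"
        ),
        runner=_s2_runner,
    )
)
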