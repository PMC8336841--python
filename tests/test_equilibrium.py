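"""Equilibrium classification, best-response oracle, counter-strategy design."""

import numpy as np
import pytest

from phenogame import (
    StrategyError,
    best_response,
    constant_density,
    density_from_callable,
    density_from_ppoly,
    design_counter_strategy,
    expected_pairwise_score,
    is_equilibrium_strategy_continuous,
    is_equilibrium_strategy_discrete,
    make_custom,
    make_invariant,
    make_lake_wobegon,
    make_truncated_gaussian,
    make_uniform,
    oracle_is_equilibrium_strategy,
    payoff_discrete,
    verify_equilibrium_point,
)

from conftest import random_grid_strategy


class TestDiscreteClassifier:
    @pytest.mark.parametrize("M", [1, 3, 5, 7])
    def test_odd_grid_constant_weights(self, M):
        assert is_equilibrium_strategy_discrete(make_uniform(M, 12.0), M)

    def test_even_grid_alternating_pattern(self):
        s = make_custom([0.0, 0.5, 1.0], [2.0, 6.0, 2.0])
        res = is_equilibrium_strategy_discrete(s, 2)
        assert res.is_equilibrium
        assert s.mca == pytest.approx(0.5)  # automatic for the pattern

    def test_even_grid_equal_weights(self):
        # equal weights are the a == b special case of the alternating pattern
        assert is_equilibrium_strategy_discrete(make_uniform(4, 1.0), 4)

    @pytest.mark.parametrize("M", [4, 5])
    def test_perturbed_weights_rejected(self, M):
        w = np.ones(M + 1)
        w[1] *= 1.1  # perturb a below-midpoint weight; strategy stays valid
        s = make_custom(np.arange(M + 1) / M, w)
        res = is_equilibrium_strategy_discrete(s, M)
        assert not res.is_equilibrium
        assert res.reason

    def test_off_grid_support_is_a_domain_error(self):
        with pytest.raises(StrategyError):
            is_equilibrium_strategy_discrete(make_lake_wobegon(10, 0.5, 1.0), 10)

    def test_classification_depends_on_grid_resolution(self):
        # a point mass at 1/2 happens to satisfy the even-M pattern on the
        # coarse M=2 grid but fails on any refinement of it
        inv = make_invariant(0.5, 1.0)
        assert is_equilibrium_strategy_discrete(inv, 2).is_equilibrium
        assert not is_equilibrium_strategy_discrete(inv, 4).is_equilibrium


class TestContinuousClassifier:
    def test_positive_constant(self):
        assert is_equilibrium_strategy_continuous(constant_density(3.0))

    def test_non_constant_density(self):
        ramp = density_from_ppoly([0.0, 1.0], [[-2.0], [2.0]])  # 2 - 2x
        assert not is_equilibrium_strategy_continuous(ramp)

    def test_sum_of_constants(self):
        assert is_equilibrium_strategy_continuous(
            constant_density(1.0, "a") + constant_density(2.0, "b")
        )

    def test_callable_constant(self):
        assert is_equilibrium_strategy_continuous(density_from_callable(lambda x: 0.75 + 0 * x))


class TestBestResponse:
    def test_gain_zero_against_uniform_incumbents(self):
        com = [make_uniform(5, 10.0, label="a"), make_uniform(5, 3.0, label="b")]
        res = best_response(com, focal_index=1)
        assert res.deviation_gain == pytest.approx(0.0, abs=1e-12)

    def test_improving_deviation_straddles_invariant(self):
        com = [
            make_invariant(0.5, 10.0, label="inc"),
            make_invariant(0.5, 10.0, label="other"),
        ]
        res = best_response(com, focal_index=0, M=10)
        assert res.deviation_gain > 0.0
        dev = res.optimal_deviation
        assert dev.mca <= 0.5 + 1e-9
        assert dev.support.size == 2 and dev.support[0] < 0.5 < dev.support[1]

    def test_gain_nonnegative_random(self, rng):
        for _ in range(20):
            com = [
                random_grid_strategy(rng, 6, "a").scaled(float(rng.uniform(1, 50))),
                random_grid_strategy(rng, 6, "b").scaled(float(rng.uniform(1, 50))),
                random_grid_strategy(rng, 6, "c").scaled(float(rng.uniform(1, 50))),
            ]
            for k in range(3):
                assert best_response(com, k).deviation_gain >= 0.0


class TestEquilibriumPoint:
    def test_collection_of_uniforms_any_abundances(self):
        com = [
            make_uniform(5, 1.0, label="a"),
            make_uniform(5, 10.0, label="b"),
            make_uniform(5, 100.0, label="c"),
        ]
        assert verify_equilibrium_point(com)

    def test_uniform_plus_invariant_is_not(self):
        com = [make_uniform(10, 10.0, label="u"), make_invariant(0.5, 10.0, label="i")]
        verdict = verify_equilibrium_point(com, M=10)
        assert not verdict.is_equilibrium
        assert verdict.gains["i"] > 0.0

    def test_singleton_is_trivially_an_equilibrium_point(self):
        # with no opponents every payoff vanishes (self-interaction cancels)
        assert verify_equilibrium_point([make_uniform(5, 3.0)])
        assert verify_equilibrium_point([make_invariant(0.3, 5.0)], M=10)

    def test_mixture_of_odd_and_even_pattern_equilibria(self):
        # sums/collections of equilibrium strategies stay equilibrium points:
        # uniform on M=3 and an alternating M=6 pattern share the M=6 grid
        alt = make_custom(np.arange(7) / 6, [1.0, 4.0, 1.0, 4.0, 1.0, 4.0, 1.0], label="alt")
        com = [make_uniform(3, 2.0, label="u3"), alt]
        assert verify_equilibrium_point(com, M=6)


class TestOracleConcordance:
    """Both directions of the characterisation against the vertex oracle."""

    @pytest.mark.parametrize("M", range(1, 9))
    def test_random_and_structured_suite(self, M):
        rng = np.random.default_rng(1000 + M)
        n_random = 40
        suite = []
        for i in range(n_random):
            suite.append(random_grid_strategy(rng, M, f"r{i}", allow_zeros=(i % 3 == 0)))
        # structured equilibria: constant and alternating patterns at random scales
        for i in range(10):
            scale = float(rng.uniform(0.1, 20.0))
            suite.append(make_uniform(M, scale, label=f"u{i}"))
            if M % 2 == 0:
                a, b = rng.uniform(0.1, 5.0, 2)
                w = np.where(np.arange(M + 1) % 2 == 0, a, b)
                suite.append(make_custom(np.arange(M + 1) / M, w, label=f"alt{i}"))
        for s in suite:
            closed_form = bool(is_equilibrium_strategy_discrete(s, M))
            oracle = oracle_is_equilibrium_strategy(s, M=M)
            assert closed_form == oracle, (M, s.label, s.weights)

    def test_closure_under_sums(self, rng):
        for M in (3, 4, 6, 7):
            for _ in range(10):
                if M % 2 == 1:
                    a = make_uniform(M, float(rng.uniform(0.5, 5.0)), label="a")
                    b = make_uniform(M, float(rng.uniform(0.5, 5.0)), label="b")
                else:
                    w1 = np.where(np.arange(M + 1) % 2 == 0, rng.uniform(0.2, 3.0), rng.uniform(0.2, 3.0))
                    w2 = np.where(np.arange(M + 1) % 2 == 0, rng.uniform(0.2, 3.0), rng.uniform(0.2, 3.0))
                    a = make_custom(np.arange(M + 1) / M, w1, label="a")
                    b = make_custom(np.arange(M + 1) / M, w2, label="b")
                assert is_equilibrium_strategy_discrete(a, M)
                assert is_equilibrium_strategy_discrete(b, M)
                assert is_equilibrium_strategy_discrete(a + b, M)


class TestNeutralityAndDominance:
    def test_equilibrium_neutral_vs_equal_mean(self, rng):
        # any strategy with MCA exactly 1/2 draws against an equilibrium pool
        u = make_uniform(9, 4.0)
        for _ in range(10):
            x = np.sort(rng.choice(np.arange(10) / 9, size=4, replace=False))
            w = rng.gamma(2.0, 1.0, 4)
            # symmetrise with the mirror image: the mean becomes exactly 1/2
            xs = np.concatenate([x, 1.0 - x])
            ws = np.concatenate([w, w])
            uniq, inv = np.unique(xs, return_inverse=True)
            agg = np.zeros_like(uniq)
            np.add.at(agg, inv, ws)
            g = make_custom(uniq, agg, label="g")
            assert g.mca == pytest.approx(0.5, abs=1e-12)
            pv = payoff_discrete([u, g])
            assert pv["g"] == pytest.approx(0.0, abs=1e-10)

    def test_equilibrium_beats_lower_mean(self, rng):
        u = make_uniform(9, 4.0)
        for _ in range(10):
            g = random_grid_strategy(rng, 9, "g")
            if g.mca >= 0.5 - 1e-6:
                g = make_custom(g.support, g.weights * np.linspace(2, 0.5, 10), label="g")
            if g.mca < 0.5 - 1e-9:
                pv = payoff_discrete([u, g])
                assert pv["g"] < 0.0


class TestCounterDesign:
    def test_invariant_gets_wobegon_type_counter(self):
        design = design_counter_strategy(make_invariant(0.5, 100.0))
        assert not design.is_equilibrium
        c = design.counter
        assert c is not None
        assert c.mca <= 0.5 + 1e-9
        assert c.support.size == 2 and c.support[0] < 0.5 < c.support[1]
        assert design.expected_score > 0.0
        # the two-species equal-abundance community punishes the target
        pv = payoff_discrete([make_invariant(0.5, 100.0, label="target"), c])
        assert pv["target"] < 0.0

    @pytest.mark.parametrize("M", [3, 4, 7, 10])
    def test_uniform_flagged_as_equilibrium(self, M):
        design = design_counter_strategy(make_uniform(M, 5.0))
        assert design.is_equilibrium
        assert design.counter is None

    def test_alternating_flagged_as_equilibrium(self):
        s = make_custom(np.arange(5) / 4, [3.0, 1.0, 3.0, 1.0, 3.0])
        assert design_counter_strategy(s).is_equilibrium

    def test_gaussian_counter_verified_by_payoff(self):
        target = make_truncated_gaussian(20, 0.5, 0.1, 50.0, label="target")
        design = design_counter_strategy(target)
        assert not design.is_equilibrium
        assert design.expected_score > 0.0
        assert design.counter.mca <= target.mca + 1e-9
        pv = payoff_discrete([target, design.counter])
        assert pv["target"] < 0.0

    def test_counter_never_exceeds_target_mean(self, rng):
        for i in range(25):
            M = int(rng.integers(2, 12))
            target = random_grid_strategy(rng, M, f"t{i}", allow_zeros=(i % 2 == 0))
            if target.mca == 0.0:
                continue  # degenerate: no winning mass fits under a zero mean
            design = design_counter_strategy(target)
            if design.counter is not None:
                assert design.counter.mca <= target.mca + 1e-9
                assert design.expected_score > 0.0
                assert expected_pairwise_score(design.counter, target) > 0.0

    def test_point_mass_at_zero_has_no_matched_mean_counter(self):
        design = design_counter_strategy(make_invariant(0.0, 5.0))
        assert not design.is_equilibrium
        assert design.counter is None
        assert "no counter" in design.reason
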