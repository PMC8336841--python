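"""Competitive-ability strategies.

A species in the competition game is characterised by a *strategy*: a
distribution of competitive abilities (scalars in ``[0, 1]``, higher wins a
pairwise contest) together with a total population abundance.  Discrete
strategies place nonnegative weight on a finite set of ability values — the
canonical model uses the grid ``{j/M}`` — while continuous strategies carry
a nonnegative density on ``[0, 1]``.  Both are constrained to a mean
competitive ability (MCA) of at most ``1/2``, reflecting the biological
assumption that no species is composed of perfect competitors.

Abundances are positive reals, not necessarily integers; the individual-based
simulator separately maintains integer head-counts.  Arbitrary finite supports
(a superset of the canonical grid) are permitted so designer distributions
such as Lake Wobegon, whose compensating ability ``m = mu * n / (n - 1)``
generally falls off-grid, are represented exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PPoly

__all__ = [
    "MCA_BOUND",
    "MCA_TOL",
    "StrategyError",
    "DiscreteStrategy",
    "ContinuousStrategy",
    "Community",
    "make_uniform",
    "make_invariant",
    "make_lake_wobegon",
    "make_bimodal",
    "make_truncated_gaussian",
    "make_custom",
    "constant_density",
    "density_from_ppoly",
    "density_from_callable",
    "mca",
    "total_abundance",
    "as_probabilities",
    "is_on_grid",
    "grid_weights",
    "infer_grid_resolution",
]

MCA_BOUND = 0.5
#: Tolerance absorbed into the MCA <= 1/2 check (floating-point construction error).
MCA_TOL = 1e-9


class StrategyError(ValueError):
    """Raised when a strategy violates the model's constraints."""


# ---------------------------------------------------------------------------
# discrete strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class DiscreteStrategy:
    """Finite-support distribution of competitive abilities, scaled by abundance.

    Parameters
    ----------
    support
        Strictly increasing ability values in ``[0, 1]``.
    weights
        Nonnegative weight per support point; the total is the population
        abundance and must be positive.
    label
        Identifier used in communities, payoff vectors and trajectories.
    """

    support: np.ndarray
    weights: np.ndarray
    label: str = "strategy"

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        if support.ndim != 1 or weights.ndim != 1 or support.size != weights.size:
            raise StrategyError("support and weights must be 1-D arrays of equal length")
        if support.size == 0:
            raise StrategyError("a strategy needs at least one support point")
        if np.any(support < 0.0) or np.any(support > 1.0):
            raise StrategyError("competitive abilities must lie in [0, 1]")
        if np.any(np.diff(support) <= 0.0):
            raise StrategyError("support values must be strictly increasing")
        if np.any(weights < 0.0):
            raise StrategyError("weights must be nonnegative")
        total = float(weights.sum())
        if not total > 0.0:
            raise StrategyError(
                "a species whose population abundance is zero cannot compete"
            )
        m = float((support * weights).sum() / total)
        if m > MCA_BOUND + MCA_TOL:
            raise StrategyError(
                f"mean competitive ability {m:.12g} exceeds the 1/2 bound"
            )
        self.support.setflags(write=False)
        self.weights.setflags(write=False)

    # -- derived quantities -------------------------------------------------

    @property
    def abundance(self) -> float:
        """Total population abundance ``|B|``."""
        return float(self.weights.sum())

    @property
    def mca(self) -> float:
        """Abundance-weighted mean competitive ability."""
        return float((self.support * self.weights).sum() / self.weights.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Weights normalised to sum to one."""
        return self.weights / self.weights.sum()

    # -- transforms ---------------------------------------------------------

    def scaled(self, abundance: float, label: str | None = None) -> "DiscreteStrategy":
        """Same distribution at a different total abundance."""
        if not abundance > 0.0:
            raise StrategyError("abundance must be positive")
        return DiscreteStrategy(
            self.support,
            self.probabilities * abundance,
            label if label is not None else self.label,
        )

    def relabeled(self, label: str) -> "DiscreteStrategy":
        return DiscreteStrategy(self.support, self.weights, label)

    def compact(self) -> "DiscreteStrategy":
        """Drop zero-weight support points."""
        keep = self.weights > 0.0
        return DiscreteStrategy(self.support[keep], self.weights[keep], self.label)

    def __add__(self, other: "DiscreteStrategy") -> "DiscreteStrategy":
        if not isinstance(other, DiscreteStrategy):
            return NotImplemented
        support = np.unique(np.concatenate([self.support, other.support]))
        weights = np.zeros_like(support)
        for s in (self, other):
            idx = np.searchsorted(support, s.support)
            np.add.at(weights, idx, s.weights)
        return DiscreteStrategy(support, weights, f"{self.label}+{other.label}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DiscreteStrategy({self.label!r}, n_points={self.support.size}, "
            f"abundance={self.abundance:.6g}, mca={self.mca:.6g})"
        )


# ---------------------------------------------------------------------------
# continuous strategies
# ---------------------------------------------------------------------------


def _as_vectorized(fn: Callable[[np.ndarray], np.ndarray]) -> Callable[[np.ndarray], np.ndarray]:
    def wrapped(x):
        x = np.asarray(x, dtype=float)
        out = fn(x)
        return np.broadcast_to(np.asarray(out, dtype=float), x.shape).copy()

    return wrapped


@dataclass(frozen=True, eq=False)
class ContinuousStrategy:
    """Nonnegative density of competitive abilities on ``[0, 1]``.

    The density is either a :class:`scipy.interpolate.PPoly` (piecewise
    polynomial; integrals are evaluated exactly from antiderivatives) or an
    arbitrary callable (handled by adaptive quadrature).  The abundance is
    ``F(1) = \\int_0^1 f`` and must be positive; the MCA bound of ``1/2``
    applies as in the discrete model.
    """

    density: object
    label: str = "density"
    _abundance: float = field(default=0.0, repr=False)
    _mca: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.density, PPoly):
            pp = self.density
            if not (math.isclose(pp.x[0], 0.0, abs_tol=1e-12) and math.isclose(pp.x[-1], 1.0, abs_tol=1e-12)):
                raise StrategyError("piecewise density must be defined on [0, 1]")
            probe = np.unique(np.concatenate([np.linspace(0.0, 1.0, 513), pp.x]))
            vals = pp(probe)
            anti = pp.antiderivative()
            f1 = float(anti(1.0))
            xf = _pp_product_integral(pp, _x_ppoly())
        elif callable(self.density):
            fn = _as_vectorized(self.density)
            object.__setattr__(self, "density", fn)
            probe = np.linspace(0.0, 1.0, 513)
            vals = fn(probe)
            f1, err1 = quad(lambda t: float(fn(np.array([t]))[0]), 0.0, 1.0, epsabs=1e-10, limit=200)
            xf, _ = quad(lambda t: t * float(fn(np.array([t]))[0]), 0.0, 1.0, epsabs=1e-10, limit=200)
        else:
            raise StrategyError("density must be a PPoly or a callable")
        if np.any(np.asarray(vals) < -1e-9):
            raise StrategyError("density must be nonnegative on [0, 1]")
        if not f1 > 0.0:
            raise StrategyError(
                "a species whose population abundance is zero cannot compete"
            )
        m = xf / f1
        if m > MCA_BOUND + MCA_TOL:
            raise StrategyError(
                f"mean competitive ability {m:.12g} exceeds the 1/2 bound"
            )
        object.__setattr__(self, "_abundance", float(f1))
        object.__setattr__(self, "_mca", float(m))

    @property
    def abundance(self) -> float:
        """Total population abundance ``F(1)``."""
        return self._abundance

    @property
    def mca(self) -> float:
        return self._mca

    @property
    def is_piecewise_polynomial(self) -> bool:
        return isinstance(self.density, PPoly)

    def __call__(self, x) -> np.ndarray:
        return self.density(np.asarray(x, dtype=float))

    def cumulative(self, x) -> np.ndarray:
        """Unnormalised CDF ``F(x)``."""
        x = np.asarray(x, dtype=float)
        if self.is_piecewise_polynomial:
            return self.density.antiderivative()(x)
        fn = self.density
        flat = np.atleast_1d(x)
        out = np.array(
            [quad(lambda t: float(fn(np.array([t]))[0]), 0.0, float(v), epsabs=1e-10, limit=200)[0] for v in flat]
        )
        return out.reshape(x.shape) if x.shape else out[0]

    def __add__(self, other: "ContinuousStrategy") -> "ContinuousStrategy":
        if not isinstance(other, ContinuousStrategy):
            return NotImplemented
        label = f"{self.label}+{other.label}"
        if self.is_piecewise_polynomial and other.is_piecewise_polynomial:
            return ContinuousStrategy(_pp_sum([self.density, other.density]), label)
        a, b = self.density, other.density
        return ContinuousStrategy(lambda x: a(np.asarray(x, float)) + b(np.asarray(x, float)), label)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "ppoly" if self.is_piecewise_polynomial else "callable"
        return (
            f"ContinuousStrategy({self.label!r}, {kind}, "
            f"abundance={self.abundance:.6g}, mca={self.mca:.6g})"
        )


# ---------------------------------------------------------------------------
# exact piecewise-polynomial helpers (shared with the payoff engine)
# ---------------------------------------------------------------------------


def _x_ppoly() -> PPoly:
    """The identity polynomial x on [0, 1]."""
    return PPoly(np.array([[1.0], [0.0]]), np.array([0.0, 1.0]))


def _shift_ascending(c: np.ndarray, d: float) -> np.ndarray:
    """Re-centre ascending-power coefficients: p(t) -> p(t + d)."""
    out = np.zeros_like(np.asarray(c, dtype=float))
    for n, cn in enumerate(c):
        if cn == 0.0:
            continue
        for k in range(n + 1):
            out[k] += cn * math.comb(n, k) * d ** (n - k)
    return out


def _local_ascending_at(pp: PPoly, a: float) -> np.ndarray:
    """Ascending coefficients of pp on the segment containing a, centred at a."""
    i = int(np.searchsorted(pp.x, a, side="right") - 1)
    i = min(max(i, 0), pp.c.shape[1] - 1)
    return _shift_ascending(pp.c[::-1, i], a - pp.x[i])


def _rebreak(pp: PPoly, new_x: np.ndarray) -> PPoly:
    """Re-express pp on a refined breakpoint set covering the same interval."""
    k = pp.c.shape[0]
    m = new_x.size - 1
    c = np.zeros((k, m))
    for seg in range(m):
        c[:, seg] = _local_ascending_at(pp, float(new_x[seg]))[::-1]
    return PPoly(c, new_x)


def _pp_sum(pps: Sequence[PPoly]) -> PPoly:
    xs = np.unique(np.concatenate([pp.x for pp in pps]))
    k = max(pp.c.shape[0] for pp in pps)
    total = np.zeros((k, xs.size - 1))
    for pp in pps:
        rb = _rebreak(pp, xs)
        total[k - rb.c.shape[0]:, :] += rb.c
    return PPoly(total, xs)


def _pp_product_integral(f: PPoly, g: PPoly) -> float:
    """Exact integral of f * g over their (shared) domain."""
    xs = np.unique(np.concatenate([f.x, g.x]))
    total = 0.0
    for seg in range(xs.size - 1):
        a, b = float(xs[seg]), float(xs[seg + 1])
        p = np.polynomial.polynomial.polymul(
            _local_ascending_at(f, a), _local_ascending_at(g, a)
        )
        h = b - a
        total += sum(p[i] * h ** (i + 1) / (i + 1) for i in range(len(p)))
    return float(total)


# ---------------------------------------------------------------------------
# named constructors (the strategy zoo)
# ---------------------------------------------------------------------------


def make_uniform(M: int, abundance: float, label: str = "uniform") -> DiscreteStrategy:
    """Uniform strategy on the canonical grid ``{j/M}``: maximal heterogeneity.

    All ``M + 1`` abilities are equally likely; the MCA is exactly ``1/2``
    by symmetry.  For odd ``M`` this is the canonical equilibrium strategy.
    """
    if int(M) != M or M < 1:
        raise StrategyError("grid resolution M must be an integer >= 1")
    if not abundance > 0.0:
        raise StrategyError("abundance must be positive")
    M = int(M)
    support = np.arange(M + 1) / M
    weights = np.full(M + 1, abundance / (M + 1))
    return DiscreteStrategy(support, weights, label)


def make_invariant(value: float, abundance: float, label: str = "invariant") -> DiscreteStrategy:
    """Degenerate strategy: every individual has the same ability (no variability)."""
    if not 0.0 <= value <= MCA_BOUND + MCA_TOL:
        raise StrategyError(
            f"invariant ability {value} violates the MCA <= 1/2 constraint"
        )
    if not abundance > 0.0:
        raise StrategyError("abundance must be positive")
    return DiscreteStrategy(np.array([value]), np.array([abundance]), label)


def make_lake_wobegon(
    n: int, target_mca: float, abundance: float, label: str = "lake_wobegon"
) -> DiscreteStrategy:
    """Designer two-point strategy: one loser at 0, everyone else 'above average'.

    A fraction ``1/n`` of the population has ability 0 and the remaining
    ``(n-1)/n`` has ability ``m = target_mca * n / (n - 1)``, so the MCA
    equals ``target_mca`` exactly.  At equal MCA it defeats the invariant
    strategy (it wins ``(n-1)/n`` of cross pairings).
    """
    if int(n) != n or n < 2:
        raise StrategyError("population size n must be an integer >= 2")
    if not 0.0 < target_mca <= MCA_BOUND + MCA_TOL:
        raise StrategyError("target MCA must lie in (0, 1/2]")
    if not abundance > 0.0:
        raise StrategyError("abundance must be positive")
    n = int(n)
    m = target_mca * n / (n - 1)
    if m > 1.0 + 1e-12:
        raise StrategyError(
            f"compensating ability m = {m:.6g} exceeds 1: population of size {n} "
            f"cannot realise MCA {target_mca} with a single zero individual"
        )
    m = min(m, 1.0)
    support = np.array([0.0, m])
    weights = abundance * np.array([1.0 / n, (n - 1.0) / n])
    return DiscreteStrategy(support, weights, label)


def make_bimodal(
    M: int,
    low_frac: float,
    high_frac: float,
    abundance: float,
    low: float = 0.0,
    high: float = 1.0,
    label: str = "bimodal",
) -> DiscreteStrategy:
    """Two-spike strategy with mass fractions at the grid points nearest low/high."""
    if int(M) != M or M < 1:
        raise StrategyError("grid resolution M must be an integer >= 1")
    if low_frac < 0 or high_frac < 0 or low_frac + high_frac <= 0:
        raise StrategyError("mode fractions must be nonnegative with positive total")
    if not abundance > 0.0:
        raise StrategyError("abundance must be positive")
    M = int(M)
    lo = round(low * M) / M
    hi = round(high * M) / M
    if lo == hi:
        raise StrategyError("the two modes coincide on the grid")
    if lo > hi:
        lo, hi = hi, lo
        low_frac, high_frac = high_frac, low_frac
    p_hi = high_frac / (low_frac + high_frac)
    m = (1.0 - p_hi) * lo + p_hi * hi
    if m > MCA_BOUND + MCA_TOL:
        raise StrategyError(f"bimodal MCA {m:.6g} exceeds the 1/2 bound")
    support = np.array([lo, hi])
    weights = abundance * np.array([1.0 - p_hi, p_hi])
    return DiscreteStrategy(support, weights, label)


def make_truncated_gaussian(
    M: int, mean: float, sd: float, abundance: float, label: str = "gaussian"
) -> DiscreteStrategy:
    """Gaussian weights evaluated on the grid and truncated to [0, 1]."""
    if int(M) != M or M < 1:
        raise StrategyError("grid resolution M must be an integer >= 1")
    if not sd > 0.0:
        raise StrategyError("standard deviation must be positive")
    if not abundance > 0.0:
        raise StrategyError("abundance must be positive")
    M = int(M)
    x = np.arange(M + 1) / M
    w = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    w *= abundance / w.sum()
    m = float((x * w).sum() / w.sum())
    if m > MCA_BOUND + MCA_TOL:
        raise StrategyError(
            f"truncated gaussian at mean {mean} has MCA {m:.6g} > 1/2"
        )
    return DiscreteStrategy(x, w, label)


def make_custom(
    support: Sequence[float],
    weights: Sequence[float],
    abundance: float | None = None,
    label: str = "custom",
) -> DiscreteStrategy:
    """Explicit finite-support strategy; optionally rescaled to a total abundance."""
    s = DiscreteStrategy(np.asarray(support, float), np.asarray(weights, float), label)
    return s if abundance is None else s.scaled(abundance)


def constant_density(c: float, label: str = "constant") -> ContinuousStrategy:
    """Positive constant density on [0, 1] — the continuous equilibrium strategy."""
    if not c > 0.0:
        raise StrategyError("constant density must be positive")
    return ContinuousStrategy(PPoly(np.array([[float(c)]]), np.array([0.0, 1.0])), label)


def density_from_ppoly(
    breakpoints: Sequence[float], coefficients: np.ndarray, label: str = "piecewise"
) -> ContinuousStrategy:
    """Piecewise-polynomial density from descending-power local coefficients."""
    return ContinuousStrategy(
        PPoly(np.asarray(coefficients, float), np.asarray(breakpoints, float)), label
    )


def density_from_callable(fn: Callable, label: str = "callable") -> ContinuousStrategy:
    return ContinuousStrategy(fn, label)


# ---------------------------------------------------------------------------
# accessors shared by both strategy kinds
# ---------------------------------------------------------------------------

Strategy = DiscreteStrategy | ContinuousStrategy


def mca(strategy: Strategy) -> float:
    """Abundance-weighted mean competitive ability."""
    return strategy.mca


def total_abundance(strategy: Strategy) -> float:
    """Population abundance |B| (discrete) or F(1) (continuous)."""
    return strategy.abundance


def as_probabilities(strategy: DiscreteStrategy) -> np.ndarray:
    """Normalised weights (sum to one) of a finite-support strategy."""
    return strategy.probabilities


# ---------------------------------------------------------------------------
# canonical-grid helpers
# ---------------------------------------------------------------------------


def is_on_grid(strategy: DiscreteStrategy, M: int, tol: float = 1e-9) -> bool:
    """True if every support point coincides with some ``j/M``."""
    j = np.round(strategy.support * M)
    return bool(np.all(np.abs(strategy.support - j / M) <= tol))


def grid_weights(strategy: DiscreteStrategy, M: int, tol: float = 1e-9) -> np.ndarray:
    """Weights re-expressed on the full grid ``{j/M}`` (zero-padded)."""
    if not is_on_grid(strategy, M, tol):
        raise StrategyError(
            f"strategy {strategy.label!r} does not live on the grid with M={M}"
        )
    w = np.zeros(int(M) + 1)
    j = np.round(strategy.support * M).astype(int)
    np.add.at(w, j, strategy.weights)
    return w


def infer_grid_resolution(
    strategy: DiscreteStrategy, max_M: int = 4096, tol: float = 1e-9
) -> int | None:
    """Smallest M <= max_M such that the positive support lies on ``{j/M}``.

    Returns None when no such grid exists (genuinely off-grid support).
    """
    from fractions import Fraction

    pos = strategy.support[strategy.weights > 0.0]
    denom = 1
    for x in pos:
        frac = Fraction(float(x)).limit_denominator(max_M)
        if abs(float(frac) - float(x)) > tol:
            return None
        denom = denom * frac.denominator // math.gcd(denom, frac.denominator)
        if denom > max_M:
            return None
    return int(denom)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------


class Community:
    """Ordered collection of labelled strategies competing simultaneously."""

    def __init__(self, strategies: Sequence[Strategy]):
        strategies = list(strategies)
        if not strategies:
            raise StrategyError("a community needs at least one species")
        labels = [s.label for s in strategies]
        if len(set(labels)) != len(labels):
            raise StrategyError(f"species labels must be unique, got {labels}")
        kinds = {type(s) for s in strategies}
        if len(kinds) > 1:
            raise StrategyError("a community must be all-discrete or all-continuous")
        self.strategies: tuple[Strategy, ...] = tuple(strategies)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.strategies)

    @property
    def is_discrete(self) -> bool:
        return isinstance(self.strategies[0], DiscreteStrategy)

    @property
    def total_abundance(self) -> float:
        return float(sum(s.abundance for s in self.strategies))

    def __len__(self) -> int:
        return len(self.strategies)

    def __iter__(self) -> Iterator[Strategy]:
        return iter(self.strategies)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.strategies:
                if s.label == key:
                    return s
            raise KeyError(key)
        return self.strategies[key]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Community({list(self.labels)!r})"
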