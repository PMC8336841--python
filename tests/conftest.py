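import numpy as np
import pytest

from phenogame import (
    make_invariant,
    make_lake_wobegon,
    make_uniform,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def uniform10():
    return make_uniform(10, 1.0)


@pytest.fixture
def invariant_half():
    return make_invariant(0.5, 100.0, label="invariant")


@pytest.fixture
def wobegon10():
    return make_lake_wobegon(10, 0.5, 100.0, label="wobegon")


def random_grid_strategy(rng, M, label="random", allow_zeros=False):
    """Random valid strategy on the canonical grid {j/M}.

    Weights are positive (optionally with some zeroed entries); if the mean
    ability exceeds 1/2 the weights are mirrored, which maps the mean m to
    1 - m and preserves validity.
    """
    w = rng.gamma(2.0, 1.0, M + 1)
    if allow_zeros:
        mask = rng.random(M + 1) < 0.3
        if mask.all():
            mask[rng.integers(M + 1)] = False
        w[mask] = 0.0
    x = np.arange(M + 1) / M
    if (x * w).sum() / w.sum() > 0.5:
        w = w[::-1].copy()
    from phenogame import DiscreteStrategy

    return DiscreteStrategy(x, w, label)
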