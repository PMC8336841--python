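"""YAML/JSON community configuration.

A community file holds a list of strategy specification blocks::

    community:
      - label: uniform
        kind: uniform
        params: {M: 1000}
        abundance: 1000
      - label: wobegon
        kind: lake_wobegon
        params: {n: 1000, target_mca: 0.5}
        abundance: 1000

Recognised discrete kinds: uniform, invariant, lake_wobegon, bimodal,
gaussian, custom (explicit ``support``/``weights`` lists in params).
Continuous kinds (for the continuous payoff functional): constant, linear
(``a + b x``), piecewise (breakpoints + descending-power coefficients).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .strategies import (
    Community,
    ContinuousStrategy,
    DiscreteStrategy,
    StrategyError,
    constant_density,
    density_from_ppoly,
    make_bimodal,
    make_custom,
    make_invariant,
    make_lake_wobegon,
    make_truncated_gaussian,
    make_uniform,
)

__all__ = ["ConfigError", "strategy_from_spec", "community_from_config", "load_config", "strategy_to_spec"]


class ConfigError(ValueError):
    """Raised for malformed configuration with a field-level message."""


_DISCRETE_KINDS = {"uniform", "invariant", "lake_wobegon", "bimodal", "gaussian", "custom"}
_CONTINUOUS_KINDS = {"constant", "linear", "piecewise"}


def _require(spec: dict, key: str, context: str):
    if key not in spec:
        raise ConfigError(f"{context}: missing required field {key!r}")
    return spec[key]


def strategy_from_spec(spec: dict) -> DiscreteStrategy | ContinuousStrategy:
    """Build a strategy from one configuration block."""
    if not isinstance(spec, dict):
        raise ConfigError(f"strategy spec must be a mapping, got {type(spec).__name__}")
    kind = _require(spec, "kind", "strategy spec")
    label = spec.get("label", kind)
    params = dict(spec.get("params", {}))
    ctx = f"strategy {label!r} (kind {kind!r})"
    try:
        if kind in _DISCRETE_KINDS:
            abundance = float(_require(spec, "abundance", ctx))
            if kind == "uniform":
                return make_uniform(int(_require(params, "M", ctx)), abundance, label)
            if kind == "invariant":
                return make_invariant(float(_require(params, "value", ctx)), abundance, label)
            if kind == "lake_wobegon":
                return make_lake_wobegon(
                    int(_require(params, "n", ctx)),
                    float(_require(params, "target_mca", ctx)),
                    abundance,
                    label,
                )
            if kind == "bimodal":
                return make_bimodal(
                    int(_require(params, "M", ctx)),
                    float(_require(params, "low_frac", ctx)),
                    float(_require(params, "high_frac", ctx)),
                    abundance,
                    low=float(params.get("low", 0.0)),
                    high=float(params.get("high", 1.0)),
                    label=label,
                )
            if kind == "gaussian":
                return make_truncated_gaussian(
                    int(_require(params, "M", ctx)),
                    float(_require(params, "mean", ctx)),
                    float(_require(params, "sd", ctx)),
                    abundance,
                    label,
                )
            return make_custom(
                [float(x) for x in _require(params, "support", ctx)],
                [float(w) for w in _require(params, "weights", ctx)],
                abundance=float(spec["abundance"]) if "abundance" in spec else None,
                label=label,
            )
        if kind in _CONTINUOUS_KINDS:
            if kind == "constant":
                return constant_density(float(_require(params, "c", ctx)), label)
            if kind == "linear":
                a = float(_require(params, "a", ctx))
                b = float(params.get("b", 0.0))
                return density_from_ppoly([0.0, 1.0], [[b], [a]], label)
            return density_from_ppoly(
                [float(x) for x in _require(params, "breakpoints", ctx)],
                np.asarray(_require(params, "coefficients", ctx), dtype=float),
                label,
            )
    except StrategyError as exc:
        raise ConfigError(f"{ctx}: {exc}") from exc
    raise ConfigError(
        f"{ctx}: unknown kind; expected one of "
        f"{sorted(_DISCRETE_KINDS | _CONTINUOUS_KINDS)}"
    )


def strategy_to_spec(strategy: DiscreteStrategy) -> dict:
    """Serialise a finite-support strategy as a ``custom`` block."""
    return {
        "label": strategy.label,
        "kind": "custom",
        "params": {
            "support": [float(x) for x in strategy.support],
            "weights": [float(w) for w in strategy.weights],
        },
        "abundance": strategy.abundance,
    }


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def community_from_config(source: str | Path | dict) -> Community:
    """Load and validate a community from a config file or mapping."""
    cfg = load_config(source) if not isinstance(source, dict) else source
    if not isinstance(cfg, dict) or "community" not in cfg:
        raise ConfigError("config must be a mapping with a 'community' list")
    blocks = cfg["community"]
    if not isinstance(blocks, list) or not blocks:
        raise ConfigError("'community' must be a non-empty list of strategy specs")
    strategies = [strategy_from_spec(b) for b in blocks]
    try:
        return Community(strategies)
    except StrategyError as exc:
        raise ConfigError(str(exc)) from exc
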