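"""Structured configuration: calibrated defaults plus YAML overlays."""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import yaml

from .assessment import StrategyConfig, StrategyMode
from .models import Climatology, ParameterSet
from .policy import Grids, UtilityConfig
from .synthetic_data import calibrate_defaults


@dataclass(frozen=True, eq=False)
class Config:
    """Everything the pipeline needs besides the monitoring data."""

    params: ParameterSet
    climatology: Climatology
    grids: Grids
    utility: UtilityConfig
    strategy: StrategyConfig
    discount: float = 0.95


@lru_cache(maxsize=1)
def default_config() -> Config:
    """Package defaults with the calibrated reproduction intercept."""
    return Config(
        params=calibrate_defaults(),
        climatology=Climatology.discretized(),
        grids=Grids.default(),
        utility=UtilityConfig(),
        strategy=StrategyConfig(),
        discount=0.95,
    )


def load_config(path=None) -> Config:
    """Overlay a YAML file onto the defaults.

    Recognized sections (any subset of keys in each): ``params``
    (ParameterSet fields; an absent ``gamma0`` stays calibrated),
    ``climatology`` (days_mean, days_sd), ``grids`` (n_max, n_step, days_max,
    days_step, action_max, action_step), ``utility`` (target, band_low,
    band_high), ``strategy`` (mode, block_length, shares, rounding,
    closure_threshold) and ``discount``.
    """
    base = default_config()
    if path is None:
        return base
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    params = base.params
    if "params" in raw:
        params = replace(params, **raw["params"])
    climatology = base.climatology
    if "climatology" in raw:
        climatology = Climatology.discretized(
            days_mean=raw["climatology"].get("days_mean", climatology.days_mean),
            days_sd=raw["climatology"].get("days_sd", climatology.days_sd),
        )
    grids = base.grids
    if "grids" in raw:
        g = raw["grids"]
        grids = Grids(
            N_grid=np.arange(0.0, g.get("n_max", 150.0) + 1e-9, g.get("n_step", 2.5)),
            days_grid=np.arange(0.0, g.get("days_max", 24.0) + 1e-9, g.get("days_step", 2.0)),
            action_grid=np.arange(
                0.0, g.get("action_max", 30.0) + 1e-9, g.get("action_step", 2.5)
            ),
        )
    utility = base.utility
    if "utility" in raw:
        utility = replace(utility, **raw["utility"])
    strategy = base.strategy
    if "strategy" in raw:
        s = dict(raw["strategy"])
        if "mode" in s:
            s["mode"] = StrategyMode(s["mode"])
        strategy = replace(strategy, **s)
    return Config(
        params=params,
        climatology=climatology,
        grids=grids,
        utility=utility,
        strategy=strategy,
        discount=raw.get("discount", base.discount),
    )
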