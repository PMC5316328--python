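"""Synthetic monitoring data, default-parameter calibration, reference values.

No deposited monitoring dataset exists for this population, so this module
emulates the range states' monitoring streams: spring and autumn counts with
lognormal observation error (and an optional range-shift undercount in named
years), the DAYS climatology, proportion young, and realized harvest split
between Norway and Denmark.

``calibrate_defaults`` anchors the default parameter set to the published
planning facts: starting from the 2013 peak of 81.6 thousand under the
reference harvest of 11.3 thousand/yr, the deterministic baseline trajectory
first reaches the 60-thousand target after 8.5 years (the midpoint of the
published 8-9 year projection); the reproduction intercept is solved by a
one-dimensional root find given a default natural survival of 0.95.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logit

from .assessment import MonitoringRecord
from .models import (
    Climatology,
    ModelSpec,
    ParameterSet,
    enumerate_models,
    reproduction_rate,
    transition,
)

#: default free coefficients around the calibrated reproduction intercept:
#: modest DAYS effects and weak density dependence (little density dependence
#: is evident in the population at current sizes), K near the observed peak.
DEFAULT_COEFFICIENTS = dict(
    alpha1=0.1, alpha2=0.1, gamma1=0.2, gamma2=0.1, K=80.0,
    process_sd=0.05, obs_cv=0.05,
)


@dataclass(eq=False)
class ScenarioConfig:
    """A synthetic monitoring scenario: truth model, horizon, noise, harvest."""

    truth_spec: ModelSpec
    truth_params: ParameterSet
    climatology: Climatology
    n_years: int
    initial_N: float = 81.6  # thousands
    harvest: float | Sequence[float] = 11.3  # thousands per season
    obs_cv: float | None = None  # None -> truth_params.obs_cv
    undercount_years: Mapping[int, float] = field(default_factory=dict)
    shares: Mapping[str, float] = field(
        default_factory=lambda: {"norway": 0.3, "denmark": 0.7}
    )
    start_year: int = 2013
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")
        for y, u in self.undercount_years.items():
            if not 0 <= u < 1:
                raise ValueError(f"undercount fraction for {y} must lie in [0, 1)")

    def harvest_series(self) -> np.ndarray:
        h = np.asarray(self.harvest, dtype=float)
        if h.ndim == 0:
            return np.full(self.n_years, float(h))
        if len(h) != self.n_years:
            raise ValueError("harvest series length must equal n_years")
        return h


def generate_days_series(n_years: int, climatology: Climatology, seed=None) -> np.ndarray:
    """Seeded i.i.d. DAYS draws (non-negative integers) from the climatology."""
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    rng = np.random.default_rng(seed)
    return climatology.draw(rng, size=n_years).astype(int)


def generate_monitoring_series(scenario: ScenarioConfig) -> list[MonitoringRecord]:
    """Simulate the truth dynamics and observe them as monitoring records.

    Counts are true abundance x lognormal noise (CV ``obs_cv``), with the
    configured undercount fraction removed from the spring count in
    undercount years (the autumn count is not undercounted, mirroring how a
    later survey can catch birds missed in spring).  The record for year y
    carries the harvest of the season spanning y to y+1.
    """
    p = scenario.truth_params
    obs_cv = scenario.obs_cv if scenario.obs_cv is not None else p.obs_cv
    rng = np.random.default_rng(scenario.seed)
    days = scenario.climatology.draw(rng, size=scenario.n_years)
    harvest = scenario.harvest_series()
    records: list[MonitoringRecord] = []
    N = float(scenario.initial_N)
    for t in range(scenario.n_years):
        year = scenario.start_year + t
        day = float(days[t])
        z = float(scenario.climatology.standardize(day))
        r = reproduction_rate(N, z, p, scenario.truth_spec)
        pre = N * (1.0 + r)
        h_real = min(float(harvest[t]), pre)
        noise_spring = math.exp(rng.normal(0.0, obs_cv)) if obs_cv > 0 else 1.0
        noise_autumn = math.exp(rng.normal(0.0, obs_cv)) if obs_cv > 0 else 1.0
        undercount = scenario.undercount_years.get(year, 0.0)
        spring_count = N * noise_spring * (1.0 - undercount) * 1000.0
        autumn_count = (pre - h_real) * noise_autumn * 1000.0
        h_ind = h_real * 1000.0
        records.append(
            MonitoringRecord(
                year=year,
                spring_count=spring_count,
                days=day,
                autumn_count=autumn_count,
                proportion_young=r / (1.0 + r),
                harvest_norway=h_ind * scenario.shares["norway"],
                harvest_denmark=h_ind * scenario.shares["denmark"],
            )
        )
        N = float(
            transition(
                N, float(harvest[t]), z, p, scenario.truth_spec,
                stochastic=p.process_sd > 0, rng=rng,
            )
        )
    return records


def _crossing_time(r: float, s: float, initial_N: float, harvest: float,
                   target: float, max_years: int = 200) -> float:
    """First crossing time of the target under constant r, s and harvest.

    Deterministic recursion N' = (N(1+r) - min(h, N(1+r))) * s, with linear
    interpolation between the bracketing years; inf when never reached.
    """
    N = initial_N
    if N <= target:
        return 0.0
    for t in range(1, max_years + 1):
        pre = N * (1.0 + r)
        nxt = (pre - min(harvest, pre)) * s
        if nxt <= target:
            return (t - 1) + (N - target) / (N - nxt)
        N = nxt
    return math.inf


def calibrate_defaults(
    s_bar: float = 0.95,
    initial_N: float = 81.6,
    H_ref: float = 11.3,
    crossing_target_years: float = 8.5,
    target: float = 60.0,
    **overrides,
) -> ParameterSet:
    """Solve the reproduction intercept so the baseline trajectory matches
    the published planning projection, and return the full default set.

    Under the structural baseline (no DAYS, no density terms), the
    deterministic trajectory from ``initial_N`` with constant ``H_ref``
    harvest must first cross the target after ``crossing_target_years``
    (linear interpolation between years).  Crossing time is strictly
    increasing in the reproduction rate, so a bracketed root find on r in
    (0, 1) is well posed.  Keyword overrides replace any of the documented
    default coefficients.
    """
    if not 0 < s_bar < 1:
        raise ValueError("s_bar must lie in (0, 1)")

    def f(r: float) -> float:
        return _crossing_time(r, s_bar, initial_N, H_ref, target) - crossing_target_years

    # scan for a finite bracket before the growth rate turns positive
    r_lo, r_hi = None, None
    for r in np.arange(1e-4, 1.0, 1e-3):
        val = f(r)
        if not math.isfinite(val):
            break
        if val < 0:
            r_lo = r
        else:
            r_hi = r
            break
    if r_lo is None or r_hi is None:
        raise ValueError("no reproduction rate in (0, 1) matches the crossing time")
    r_star = brentq(f, r_lo, r_hi, xtol=1e-12)
    coeffs = {**DEFAULT_COEFFICIENTS, **overrides}
    return ParameterSet(
        alpha0=float(logit(s_bar)),
        gamma0=math.log(r_star),
        **coeffs,
    )


def reference_values() -> dict:
    """Published planning quantities (thousands unless noted) used as fixtures.

    Keys: the 2013 spring peak, the low 2015 spring count and the revised
    2015 autumn count, the record 2014/15 harvest, the 2011-2013 reference
    harvest, the reduced 2015 one-year quota, the 2013-2015 optimal harvest,
    the population target and acceptance band, and the Norway/Denmark shares.
    """
    return {
        "spring_2013": 81.6,
        "spring_2015_count": 59.0,
        "autumn_2015_count": 74.8,
        "harvest_2014": 14.8,
        "harvest_ref": 11.3,
        "quota_2015": 6.7,
        "optimum_2013_15": 15.0,
        "target": 60.0,
        "band": (50.0, 70.0),
        "shares": (0.3, 0.7),
    }


def stumble_scenario(seed: int = 0, undercount: float = 0.16) -> ScenarioConfig:
    """The 2015 'stumble': a one-year spring-survey undercount.

    Synthetic stand-in for the 2013-2018 monitoring window in which the 2015
    spring ground survey missed a sizeable fraction of the population (flocks
    outside the known range); the undercount fraction is illustrative, sized
    so that roughly 11-12 thousand birds go missing from a low-70s population.
    """
    fixtures = reference_values()
    return ScenarioConfig(
        truth_spec=enumerate_models()[0],
        truth_params=calibrate_defaults(),
        climatology=Climatology.discretized(),
        n_years=6,
        initial_N=fixtures["spring_2013"],
        harvest=[11.3, 14.8, 6.7, 11.3, 11.3, 11.3],
        undercount_years={2015: undercount},
        seed=seed,
    )
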