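"""Annual population dynamics of the Svalbard pink-footed goose.

The adaptive harvest management system entertains a set of nine alternative
models of how the population responds to harvest, to spring conditions on the
Svalbard breeding grounds, and to its own density.  The models form a 3x3
factorial over the structural form of the survival and reproduction
processes: each process is either constant (``NULL``), driven by the number
of days above freezing in May in Svalbard (``DAYS``, a proxy for the
advancement of spring), or driven by both DAYS and population density
(``DAYS_DENSITY``).

All abundances are carried in thousands of individuals.  One model step runs
spring to spring: recruitment (young per adult), then harvest (additive
mortality, truncated so the population cannot go negative), then natural
survival, optionally followed by multiplicative lognormal process error whose
mean is corrected to one.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm


class Form(str, enum.Enum):
    """Structural form of a demographic rate (survival or reproduction)."""

    NULL = "null"
    DAYS = "days"
    DAYS_DENSITY = "days_density"

    @property
    def has_days(self) -> bool:
        return self is not Form.NULL

    @property
    def has_density(self) -> bool:
        return self is Form.DAYS_DENSITY


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine structural hypotheses about population dynamics."""

    id: int
    survival_form: Form
    reproduction_form: Form


def enumerate_models() -> tuple[ModelSpec, ...]:
    """Return the full nine-model set, ordered by id.

    Every combination of survival form x reproduction form over
    {NULL, DAYS, DAYS_DENSITY}, ids 1..9 (survival form varying slowest).
    """
    forms = (Form.NULL, Form.DAYS, Form.DAYS_DENSITY)
    return tuple(
        ModelSpec(i + 1, s, r)
        for i, (s, r) in enumerate(itertools.product(forms, forms))
    )


@dataclass(frozen=True)
class ParameterSet:
    """Demographic coefficients shared by the model set.

    Coefficients enter a model only where its form includes the term, so a
    single ParameterSet parameterizes all nine models.

    Attributes
    ----------
    alpha0, alpha1, alpha2
        Survival intercept (logit scale), DAYS coefficient (per standardized
        DAYS unit) and density coefficient (per unit N/K, >= 0).
    gamma0, gamma1, gamma2
        Reproduction intercept (log scale, young per adult), DAYS coefficient
        and density coefficient (>= 0).
    K
        Density scaling abundance in thousands (> 0).
    process_sd
        Lognormal process-error SD on the log scale (>= 0).
    obs_cv
        Observation CV of population counts (>= 0), used both for simulating
        counts and as the log-sd of the observation likelihood.
    """

    alpha0: float
    alpha1: float
    alpha2: float
    gamma0: float
    gamma1: float
    gamma2: float
    K: float
    process_sd: float
    obs_cv: float

    def __post_init__(self) -> None:
        for name in ("alpha2", "gamma2", "process_sd", "obs_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.K <= 0:
            raise ValueError("K must be positive")


@dataclass(frozen=True)
class PopulationState:
    """The decision state: spring abundance (thousands) and current DAYS."""

    N: float
    days: float

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("abundance must be non-negative")
        if self.days < 0:
            raise ValueError("DAYS must be non-negative")

    def age_split(self, r: float) -> tuple[float, float]:
        """Adult/young split (A, Y) implied by a reproduction rate ``r``."""
        return derive_age_split(self.N, r)


@dataclass(frozen=True, eq=False)
class Climatology:
    """Distribution of DAYS (days above freezing in May in Svalbard).

    Carries a discrete support with probabilities, used both to draw random
    spring conditions and to take expectations over next year's conditions in
    the dynamic-programming step.
    """

    days_mean: float
    days_sd: float
    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.support < 0):
            raise ValueError("DAYS support must be non-negative")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("support probabilities must sum to 1")
        if np.any(self.probs < 0):
            raise ValueError("support probabilities must be non-negative")

    @classmethod
    def discretized(cls, days_mean: float = 10.0, days_sd: float = 4.0) -> "Climatology":
        """Integer support 0..mean+4sd with normal bin masses.

        The mass of each integer v is the normal probability of
        [v - 0.5, v + 0.5); the sub-zero tail is folded into v = 0 and the
        upper tail into the top value, then renormalized.
        """
        hi = int(math.ceil(days_mean + 4 * days_sd))
        values = np.arange(0, hi + 1, dtype=float)
        edges = np.concatenate(([-np.inf], values[:-1] + 0.5, [np.inf]))
        p = np.diff(norm.cdf(edges, loc=days_mean, scale=days_sd))
        p = p / p.sum()
        return cls(days_mean, days_sd, values, p)

    def standardize(self, days) -> float | np.ndarray:
        """z = (DAYS - mean) / sd, the covariate scale of the models."""
        return (np.asarray(days, dtype=float) - self.days_mean) / self.days_sd

    def draw(self, rng: np.random.Generator, size=None):
        return rng.choice(self.support, size=size, p=self.probs)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _linear_predictor(intercept, coef_days, coef_density, form: Form, N, days_z, K):
    eta = np.asarray(intercept + np.zeros_like(np.asarray(N, dtype=float)))
    if form.has_days:
        eta = eta + coef_days * np.asarray(days_z, dtype=float)
    if form.has_density:
        eta = eta - coef_density * (np.asarray(N, dtype=float) / K)
    return eta


def _maybe_scalar(x: np.ndarray):
    return float(x) if x.ndim == 0 else x


def survival_rate(N, days_z, params: ParameterSet, spec: ModelSpec):
    """Annual natural-survival probability under one structural model.

    s = expit(alpha0 + alpha1*z [if DAYS in form] - alpha2*(N/K) [if density]).
    Accepts scalar or array abundance.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance must be non-negative")
    eta = _linear_predictor(
        params.alpha0, params.alpha1, params.alpha2, spec.survival_form, N, days_z, params.K
    )
    return _maybe_scalar(np.asarray(expit(eta)))


def reproduction_rate(N, days_z, params: ParameterSet, spec: ModelSpec):
    """Expected young per adult: exp(gamma0 + gamma1*z [..] - gamma2*(N/K) [..])."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance must be non-negative")
    eta = _linear_predictor(
        params.gamma0, params.gamma1, params.gamma2, spec.reproduction_form, N, days_z, params.K
    )
    return _maybe_scalar(np.exp(np.asarray(eta)))


def transition(
    N,
    harvest,
    days_z,
    params: ParameterSet,
    spec: ModelSpec,
    stochastic: bool = False,
    rng=None,
):
    """One spring-to-spring population step (thousands).

    Deterministic core: N' = max(0, (N*(1+r) - h) * s), with realized harvest
    h truncated at the post-recruitment population N*(1+r).  The stochastic
    variant multiplies by lognormal noise with log-mean -process_sd^2/2 so
    its expectation equals the deterministic core.
    """
    N = np.asarray(N, dtype=float)
    harvest = np.asarray(harvest, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance must be non-negative")
    if np.any(harvest < 0):
        raise ValueError("harvest must be non-negative")
    r = reproduction_rate(N, days_z, params, spec)
    s = survival_rate(N, days_z, params, spec)
    post_recruitment = N * (1.0 + r)
    realized = np.minimum(harvest, post_recruitment)
    nxt = (post_recruitment - realized) * s
    if stochastic and params.process_sd > 0:
        sd = params.process_sd
        noise = _as_rng(rng).lognormal(-0.5 * sd * sd, sd, size=np.shape(nxt))
        nxt = nxt * noise
    return _maybe_scalar(np.maximum(np.asarray(nxt), 0.0))


def derive_age_split(N, r):
    """Split total abundance into adults and young: A = N/(1+r), Y = N*r/(1+r)."""
    N = np.asarray(N, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance must be non-negative")
    if np.any(r < 0):
        raise ValueError("reproduction rate must be non-negative")
    A = N / (1.0 + r)
    Y = N * r / (1.0 + r)
    return _maybe_scalar(A), _maybe_scalar(Y)
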