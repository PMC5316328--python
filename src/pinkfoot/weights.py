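"""Bayesian updating of the nine model probabilities.

Each year the observed spring count is compared with every model's
one-step-ahead prediction; model probabilities are reweighted by the
lognormal predictive density of the observation and renormalized.  Aggregate
probabilities over structural features (density-dependent survival,
density-dependent reproduction, any DAYS effect) summarize what the data say
about the competing hypotheses.
"""

from __future__ import annotations

import enum
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import lognorm

from .models import ModelSpec, enumerate_models

#: weights smaller than this are floored to zero and the vector renormalized,
#: avoiding underflow in long sequential runs
WEIGHT_FLOOR = 1e-12


class DegenerateUpdateError(ValueError):
    """All predictive densities vanished: the update is undefined."""


class Feature(str, enum.Enum):
    DD_SURVIVAL = "dd_survival"
    DD_REPRODUCTION = "dd_reproduction"
    DAYS_ANY = "days_any"


def _has_feature(spec: ModelSpec, feature: Feature) -> bool:
    if feature is Feature.DD_SURVIVAL:
        return spec.survival_form.has_density
    if feature is Feature.DD_REPRODUCTION:
        return spec.reproduction_form.has_density
    if feature is Feature.DAYS_ANY:
        return spec.survival_form.has_days or spec.reproduction_form.has_days
    raise ValueError(f"unknown feature: {feature!r}")


@dataclass(frozen=True, eq=False)
class WeightVector:
    """A simplex of model probabilities keyed by model id."""

    weights: Mapping[int, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("model weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("model weights must sum to 1")

    @classmethod
    def uniform(cls, model_ids: Sequence[int] | None = None) -> "WeightVector":
        ids = list(model_ids) if model_ids is not None else [m.id for m in enumerate_models()]
        return cls({i: 1.0 / len(ids) for i in ids})

    @classmethod
    def point_mass(cls, model_id: int, model_ids: Sequence[int] | None = None) -> "WeightVector":
        ids = list(model_ids) if model_ids is not None else [m.id for m in enumerate_models()]
        return cls({i: 1.0 if i == model_id else 0.0 for i in ids})

    def __getitem__(self, model_id: int) -> float:
        return self.weights[model_id]

    def __len__(self) -> int:
        return len(self.weights)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightVector):
            return NotImplemented
        return dict(self.weights) == dict(other.weights)

    def items(self):
        return self.weights.items()

    def as_array(self, model_ids: Sequence[int] | None = None) -> np.ndarray:
        ids = list(model_ids) if model_ids is not None else sorted(self.weights)
        return np.array([self.weights[i] for i in ids], dtype=float)


def predictive_density(observed_count: float, predicted_mean: float, obs_cv: float) -> float:
    """Lognormal density of an observed count given a model's prediction.

    The observation model is observed = predicted * exp(eps) with
    eps ~ Normal(0, obs_cv): log-median equal to the predicted mean and
    log-sd equal to the count CV.
    """
    if observed_count <= 0 or predicted_mean <= 0 or obs_cv <= 0:
        raise ValueError("observed count, prediction and CV must be positive")
    return float(lognorm.pdf(observed_count, s=obs_cv, scale=predicted_mean))


def update_weights(
    prior: WeightVector,
    per_model_predictions: Mapping[int, float],
    observed_count: float,
    obs_cv: float,
) -> WeightVector:
    """One Bayes step: posterior_m proportional to prior_m x density_m.

    Raises :class:`DegenerateUpdateError` when every model with positive
    prior weight assigns zero density to the observation.
    """
    post: dict[int, float] = {}
    for m, p in prior.items():
        if p > 0:
            if m not in per_model_predictions:
                raise ValueError(f"missing prediction for model {m}")
            post[m] = p * predictive_density(observed_count, per_model_predictions[m], obs_cv)
        else:
            post[m] = 0.0
    total = sum(post.values())
    if total <= 0 or not np.isfinite(total):
        raise DegenerateUpdateError(
            "all predictive densities are zero; the Bayes update is degenerate"
        )
    post = {m: v / total for m, v in post.items()}
    floored = {m: (0.0 if v < WEIGHT_FLOOR else v) for m, v in post.items()}
    total = sum(floored.values())
    return WeightVector({m: v / total for m, v in floored.items()})


def aggregate_weight(
    weights: WeightVector,
    feature: Feature | str,
    model_specs: Sequence[ModelSpec] | None = None,
) -> float:
    """Total probability on models that carry a structural feature."""
    feature = Feature(feature)
    specs = model_specs if model_specs is not None else enumerate_models()
    by_id = {m.id: m for m in specs}
    return float(
        sum(w for m, w in weights.items() if m in by_id and _has_feature(by_id[m], feature))
    )


def write_weight_trajectory(path, years: Sequence[int], trajectory: Sequence[WeightVector]) -> None:
    """Write a weight time series as tab-delimited text.

    Columns: year, one weight per model id, and the three aggregate
    probabilities (density-dependent survival / reproduction, any DAYS term).
    """
    rows = []
    for year, wv in zip(years, trajectory, strict=True):
        row = {"year": year}
        for m, w in sorted(wv.items()):
            row[f"w{m}"] = w
        row["p_dd_survival"] = aggregate_weight(wv, Feature.DD_SURVIVAL)
        row["p_dd_reproduction"] = aggregate_weight(wv, Feature.DD_REPRODUCTION)
        row["p_days_any"] = aggregate_weight(wv, Feature.DAYS_ANY)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
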