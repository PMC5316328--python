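"""Annual assessment: monitoring in, harvest decision out.

Orchestrates the annual decision cycle of the international management plan:
update the model weights from the new spring count, set the quota under the
agreed strategy mode (annual re-optimization, or a fixed 3-year block quota
with an annual emergency-closure check), split the quota 30/70 between
Norway and Denmark, and log the decision.  Also provides the Chapman
mark-resight estimator used to cross-check the ground surveys against the
neck-banded sample.

Quotas and counts cross this interface in individuals; the underlying
dynamics and optimization run in thousands.
"""

from __future__ import annotations

import enum
import math
import os
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Climatology, ModelSpec, ParameterSet, PopulationState, transition
from .policy import Grids, Policy, UtilityConfig, lookup_quota, optimize_policy
from .weights import WeightVector, update_weights

MONITORING_COLUMNS = (
    "year",
    "spring_count",
    "autumn_count",
    "prop_young",
    "harvest_no",
    "harvest_dk",
    "days",
)


@dataclass(frozen=True)
class MonitoringRecord:
    """One year of monitoring data (counts and harvest in individuals).

    The harvest fields refer to the hunting season that follows this year's
    spring count, so a record holds everything known by the June decision of
    the *next* year about the interval in between.
    """

    year: int
    spring_count: float | None
    days: float | None
    autumn_count: float | None = None
    proportion_young: float | None = None
    harvest_norway: float = 0.0
    harvest_denmark: float = 0.0

    def __post_init__(self) -> None:
        for name in ("spring_count", "autumn_count", "harvest_norway", "harvest_denmark"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.proportion_young is not None and not 0 <= self.proportion_young <= 1:
            raise ValueError("proportion_young must lie in [0, 1]")

    @property
    def total_harvest(self) -> float:
        return self.harvest_norway + self.harvest_denmark


class StrategyMode(str, enum.Enum):
    ONE_YEAR = "one_year"
    THREE_YEAR = "three_year"


@dataclass(frozen=True)
class StrategyConfig:
    """Decision-cycle settings: strategy mode, country shares, rounding."""

    mode: StrategyMode = StrategyMode.ONE_YEAR
    block_length: int = 3
    shares: Mapping[str, float] = field(
        default_factory=lambda: {"norway": 0.3, "denmark": 0.7}
    )
    rounding: int = 100  # individuals
    closure_threshold: float | None = None  # thousands; None -> utility target

    def __post_init__(self) -> None:
        if self.block_length < 1:
            raise ValueError("block_length must be at least 1")
        if abs(sum(self.shares.values()) - 1.0) > 1e-9:
            raise ValueError("country shares must sum to 1")
        if self.rounding < 1:
            raise ValueError("rounding unit must be at least 1")


@dataclass(frozen=True)
class Decision:
    """An issued harvest decision (quotas in individuals)."""

    year: int
    total_quota: int
    allocations: Mapping[str, int]
    closure: bool
    strategy_mode: StrategyMode
    weights: WeightVector
    predicted_next_spring: float

    def __post_init__(self) -> None:
        if self.closure and self.total_quota != 0:
            raise ValueError("a closure decision must carry a zero quota")
        if abs(sum(self.allocations.values()) - self.total_quota) > 0:
            raise ValueError("allocations must sum to the total quota")


def allocate_quota(
    total: float, shares: Mapping[str, float], rounding: int = 100
) -> dict[str, int]:
    """Split a total quota between countries by largest-remainder apportionment.

    Each share is rounded to the ``rounding`` unit (individuals) such that the
    parts sum exactly to the total rounded to that unit; remainders are
    awarded largest-first, ties broken alphabetically by country.
    """
    if total < 0:
        raise ValueError("total quota must be non-negative")
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    units_total = int(round(total / rounding))
    raw = {c: s * units_total for c, s in shares.items()}
    base = {c: math.floor(v) for c, v in raw.items()}
    remaining = units_total - sum(base.values())
    order = sorted(shares, key=lambda c: (-(raw[c] - base[c]), c))
    for c in order[:remaining]:
        base[c] += 1
    return {c: base[c] * rounding for c in sorted(shares)}


def expected_next_spring(
    state: PopulationState,
    weights: WeightVector,
    harvest: float,
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    climatology: Climatology,
) -> float:
    """Model-averaged deterministic one-step prediction (thousands)."""
    z = climatology.standardize(state.days)
    return float(
        sum(
            weights[m.id] * transition(state.N, harvest, z, params, m)
            for m in model_specs
        )
    )


def emergency_closure_check(
    state: PopulationState,
    weights: WeightVector,
    block_quota: float,
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    target: float,
    climatology: Climatology,
) -> bool:
    """Should the season be closed rather than run at the standing quota?

    True iff the standing quota is positive and the model-averaged expected
    next-spring population under it falls below the threshold (by default
    the population target).  A zero quota can never trigger a closure.
    """
    if block_quota <= 0:
        return False
    predicted = expected_next_spring(
        state, weights, block_quota, model_specs, params, climatology
    )
    return predicted < target


def annual_assessment(
    record: MonitoringRecord,
    weights: WeightVector,
    policy_or_block_quota: Policy | float,
    cfg: StrategyConfig,
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    utility_cfg: UtilityConfig,
    climatology: Climatology,
    grids: Grids | None = None,
    previous: MonitoringRecord | None = None,
    discount: float = 0.95,
) -> Decision:
    """Run one annual decision.

    Steps: (1) if the previous year's record is supplied, Bayes-update the
    model weights using each model's prediction of this spring's count from
    last spring's state and realized harvest; (2) in ONE_YEAR mode look up the
    quota in a policy freshly optimized at the updated weights (or in the
    supplied Policy); in THREE_YEAR mode keep the block quota unless the
    emergency-closure check fires, in which case the quota is zero and the
    closure flag set; (3) round to the rounding unit and allocate between
    countries.
    """
    if record.spring_count is None or record.spring_count <= 0:
        raise ValueError("a spring count is required to make a decision")
    if record.days is None:
        raise ValueError("the DAYS covariate is required to make a decision")

    obs = record.spring_count / 1000.0
    if previous is not None:
        if previous.spring_count is None or previous.days is None:
            raise ValueError("previous record must carry a spring count and DAYS")
        z_prev = climatology.standardize(previous.days)
        predictions = {
            m.id: transition(
                previous.spring_count / 1000.0,
                previous.total_harvest / 1000.0,
                z_prev,
                params,
                m,
            )
            for m in model_specs
        }
        weights = update_weights(weights, predictions, obs, params.obs_cv)

    state = PopulationState(obs, record.days)
    closure = False
    if cfg.mode is StrategyMode.ONE_YEAR:
        if isinstance(policy_or_block_quota, Policy):
            policy = policy_or_block_quota
        else:
            policy = optimize_policy(
                model_specs,
                params,
                weights,
                grids if grids is not None else Grids.default(),
                utility_cfg,
                climatology,
                discount=discount,
            )
        quota_thousands = lookup_quota(policy, state)
    else:
        if isinstance(policy_or_block_quota, Policy):
            raise TypeError("THREE_YEAR mode expects a block quota in individuals")
        block = float(policy_or_block_quota) / 1000.0
        threshold = (
            cfg.closure_threshold if cfg.closure_threshold is not None else utility_cfg.target
        )
        closure = emergency_closure_check(
            state, weights, block, model_specs, params, threshold, climatology
        )
        quota_thousands = 0.0 if closure else block

    total = int(round(quota_thousands * 1000.0 / cfg.rounding)) * cfg.rounding
    allocations = allocate_quota(total, cfg.shares, cfg.rounding)
    predicted = expected_next_spring(
        state, weights, total / 1000.0, model_specs, params, climatology
    )
    return Decision(
        year=record.year,
        total_quota=total,
        allocations=allocations,
        closure=closure,
        strategy_mode=cfg.mode,
        weights=weights,
        predicted_next_spring=predicted * 1000.0,
    )


def cmr_estimate(marked_alive: int, resight_sample: int, marked_in_sample: int):
    """Chapman mark-resight abundance estimate and its standard error.

    N = (M+1)(n+1)/(m+1) - 1 with the standard Chapman variance; finite even
    when no marked birds appear in the sample.
    """
    M, n, m = marked_alive, resight_sample, marked_in_sample
    if m < 0 or m > min(M, n):
        raise ValueError("marked_in_sample must satisfy 0 <= m <= min(M, n)")
    estimate = (M + 1) * (n + 1) / (m + 1) - 1.0
    variance = (M + 1) * (n + 1) * (M - m) * (n - m) / ((m + 1) ** 2 * (m + 2))
    return estimate, math.sqrt(variance)


# --- monitoring and decision-log text formats -------------------------------


def write_monitoring(path, records: Sequence[MonitoringRecord]) -> None:
    """Write monitoring records as tab-delimited text with a fixed header."""
    rows = [
        {
            "year": r.year,
            "spring_count": r.spring_count,
            "autumn_count": r.autumn_count,
            "prop_young": r.proportion_young,
            "harvest_no": r.harvest_norway,
            "harvest_dk": r.harvest_denmark,
            "days": r.days,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MONITORING_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_monitoring(path) -> list[MonitoringRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MONITORING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"monitoring file lacks columns: {sorted(missing)}")

    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        MonitoringRecord(
            year=int(row.year),
            spring_count=opt(row.spring_count),
            days=opt(row.days),
            autumn_count=opt(row.autumn_count),
            proportion_young=opt(row.prop_young),
            harvest_norway=float(row.harvest_no) if not pd.isna(row.harvest_no) else 0.0,
            harvest_denmark=float(row.harvest_dk) if not pd.isna(row.harvest_dk) else 0.0,
        )
        for row in df.itertuples()
    ]


def append_decision(path, decision: Decision) -> None:
    """Append a decision to the tab-delimited log (never rewrites past rows).

    Decisions already issued are immutable: revised counts enter only the
    next cycle, so the log is append-only by construction.
    """
    countries = sorted(decision.allocations)
    header = ["year", "total_quota", *[f"quota_{c}" for c in countries],
              "closure", "mode", "predicted_next_spring"]
    row = [
        decision.year,
        decision.total_quota,
        *[decision.allocations[c] for c in countries],
        int(decision.closure),
        decision.strategy_mode.value,
        f"{decision.predicted_next_spring:.1f}",
    ]
    new_file = not os.path.exists(path) or os.path.getsize(path) == 0
    with open(path, "a") as fh:
        if new_file:
            fh.write("\t".join(header) + "\n")
        fh.write("\t".join(str(v) for v in row) + "\n")


def read_decision_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
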