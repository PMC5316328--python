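"""Stochastic population projection and closed-loop strategy evaluation.

``project_fixed_harvest`` reproduces the planning exercise behind the
adoption of the increased quota: thousands of stochastic trajectories from a
given spring abundance under a constant annual harvest, with structural
(model) uncertainty, random spring conditions and process error, summarized
by the distribution of the first year the population reaches the target.

``closed_loop_simulate`` is a management-strategy evaluation: it simulates a
known "truth" model, noisy monitoring, the annual weight update and the
quota decision each year, and scores the resulting management performance.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import Climatology, ModelSpec, ParameterSet, PopulationState, transition
from .policy import (
    Grids,
    UtilityConfig,
    build_transition_kernels,
    lookup_quota,
    optimize_policy,
)
from .weights import DegenerateUpdateError, WeightVector, update_weights


@dataclass(eq=False)
class ProjectionResult:
    """Trajectories (thousands), per-year summaries and years-to-target."""

    trajectories: np.ndarray  # (n_sims, horizon + 1), column 0 = initial state
    target: float
    years_to_target: np.ndarray  # per trajectory; np.inf when never reached
    summaries: pd.DataFrame

    @classmethod
    def from_trajectories(cls, trajectories: np.ndarray, target: float) -> "ProjectionResult":
        below = trajectories[:, 1:] <= target
        any_cross = below.any(axis=1)
        first = below.argmax(axis=1) + 1.0
        years = np.where(any_cross, first, np.inf)
        q = np.quantile(trajectories, [0.025, 0.25, 0.5, 0.75, 0.975], axis=0)
        summaries = pd.DataFrame(
            {
                "year": np.arange(trajectories.shape[1]),
                "mean": trajectories.mean(axis=0),
                "median": q[2],
                "q25": q[1],
                "q75": q[3],
                "lo95": q[0],
                "hi95": q[4],
            }
        )
        return cls(trajectories, target, years, summaries)

    @property
    def median_years_to_target(self) -> float:
        return float(np.median(self.years_to_target))


@dataclass(eq=False)
class MSEMetrics:
    """Closed-loop performance scores, aggregated over simulations."""

    mean_abundance: float  # long-run mean N, thousands
    frac_years_in_band: float
    mean_harvest: float  # thousands per year
    closure_frequency: float
    truth_weight_final: float
    truth_weight_trajectory: np.ndarray  # mean across sims, length horizon


def _deterministic_core(N, harvest, z, params, specs, weights_arr):
    core = np.zeros_like(N)
    for w, spec in zip(weights_arr, specs):
        if w > 0:
            core += w * transition(N, harvest, z, params, spec)
    return core


def project_fixed_harvest(
    initial_N: float,
    harvest: float,
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    weights: WeightVector,
    climatology: Climatology,
    n_sims: int = 5000,
    horizon: int = 15,
    seed=None,
    target: float = 60.0,
    average_models: bool = False,
) -> ProjectionResult:
    """Open-loop projection under a constant annual harvest (thousands/yr).

    By default one structural model is sampled per trajectory from the weight
    vector, so model uncertainty appears as between-trajectory spread; with
    ``average_models`` the weighted-mean transition is used at every step
    instead.  DAYS are i.i.d. climatology draws; process error is applied
    each step.  Fully reproducible given ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    rng = np.random.default_rng(seed)
    w = np.array([weights[m.id] for m in model_specs])
    traj = np.empty((n_sims, horizon + 1))
    traj[:, 0] = initial_N
    days = climatology.draw(rng, size=(n_sims, horizon))
    z = climatology.standardize(days)
    model_idx = None if average_models else rng.choice(len(model_specs), size=n_sims, p=w)
    sd = params.process_sd
    for t in range(horizon):
        N = traj[:, t]
        if average_models:
            core = _deterministic_core(N, harvest, z[:, t], params, model_specs, w)
        else:
            core = np.empty(n_sims)
            for mi, spec in enumerate(model_specs):
                mask = model_idx == mi
                if mask.any():
                    core[mask] = transition(N[mask], harvest, z[mask, t], params, spec)
        noise = rng.lognormal(-0.5 * sd * sd, sd, size=n_sims) if sd > 0 else 1.0
        traj[:, t + 1] = np.maximum(core * noise, 0.0)
    return ProjectionResult.from_trajectories(traj, target)


def plot_projection(result: ProjectionResult, path=None):
    """Box-style summary plot: medians, interquartile boxes, 95% whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = result.summaries
    fig, ax = plt.subplots(figsize=(7, 4))
    for _, row in s.iterrows():
        x = row["year"]
        ax.vlines(x, row["lo95"], row["hi95"], color="0.4", lw=1)
        ax.add_patch(
            plt.Rectangle((x - 0.3, row["q25"]), 0.6, row["q75"] - row["q25"],
                          fill=False, edgecolor="0.2"))
        ax.hlines(row["median"], x - 0.3, x + 0.3, color="k", lw=1.5)
        ax.plot(x, row["mean"], "o", mfc="none", mec="k", ms=4)
    ax.axhline(result.target, color="firebrick", ls="--", lw=1)
    ax.set_xlabel("year")
    ax.set_ylabel("population size (thousands)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def closed_loop_simulate(
    truth_spec: ModelSpec,
    truth_params: ParameterSet,
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    strategy_mode,
    grids: Grids,
    utility_cfg: UtilityConfig,
    climatology: Climatology,
    horizon: int = 100,
    n_sims: int = 1,
    seed=None,
    initial_N: float = 81.6,
    prior: WeightVector | None = None,
    discount: float = 0.95,
    block_length: int = 3,
    closure_threshold: float | None = None,
) -> MSEMetrics:
    """Simulate the full monitoring-assessment-decision loop against a truth.

    Each year: the truth model advances the population; a spring count is
    observed with lognormal error (CV ``params.obs_cv``); the model weights
    are Bayes-updated from last year's prediction; the quota is set by the
    chosen strategy (annual re-optimization, or a block quota fixed for
    ``block_length`` years with an annual emergency-closure check); the quota
    is realized as harvest.  Per-model transition kernels are built once and
    the value function warm-started across years, so annual re-optimization
    is cheap.
    """
    from .assessment import StrategyMode, emergency_closure_check

    mode = StrategyMode(strategy_mode)
    kernels = build_transition_kernels(model_specs, params, grids, climatology)
    threshold = closure_threshold if closure_threshold is not None else utility_cfg.target
    obs_cv = params.obs_cv

    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.spawn(n_sims)
    all_N = np.empty((n_sims, horizon))
    all_h = np.empty((n_sims, horizon))
    all_closed = np.zeros((n_sims, horizon), dtype=bool)
    all_truthw = np.empty((n_sims, horizon))

    for si in range(n_sims):
        rng = np.random.default_rng(sim_seeds[si])
        weights = prior if prior is not None else WeightVector.uniform([m.id for m in model_specs])
        N = float(initial_N)
        prev = None  # (observed N, realized harvest, z) of the previous year
        V = None
        block_quota = None
        years_into_block = 0
        for t in range(horizon):
            day = float(climatology.draw(rng))
            z = float(climatology.standardize(day))
            obs = N * float(np.exp(rng.normal(0.0, obs_cv))) if obs_cv > 0 else N
            obs = max(obs, 1e-6)
            if prev is not None:
                predictions = {
                    m.id: max(transition(prev[0], prev[1], prev[2], params, m), 1e-12)
                    for m in model_specs
                }
                try:
                    weights = update_weights(weights, predictions, obs, obs_cv)
                except DegenerateUpdateError:
                    pass  # carry the prior forward on numerical underflow
            state = PopulationState(obs, day)
            if mode is StrategyMode.ONE_YEAR:
                policy = optimize_policy(
                    model_specs, params, weights, grids, utility_cfg, climatology,
                    discount=discount, kernels=kernels, v0=V,
                )
                V = policy.value
                quota = lookup_quota(policy, state)
                closed = False
            else:
                if block_quota is None or years_into_block >= block_length:
                    policy = optimize_policy(
                        model_specs, params, weights, grids, utility_cfg, climatology,
                        discount=discount, kernels=kernels, v0=V,
                    )
                    V = policy.value
                    block_quota = lookup_quota(policy, state)
                    years_into_block = 0
                closed = emergency_closure_check(
                    state, weights, block_quota, model_specs, params, threshold, climatology
                )
                quota = 0.0 if closed else block_quota
                years_into_block += 1
            N = float(
                transition(
                    N, quota, z, truth_params, truth_spec,
                    stochastic=truth_params.process_sd > 0, rng=rng,
                )
            )
            all_N[si, t] = N
            all_h[si, t] = quota
            all_closed[si, t] = closed
            all_truthw[si, t] = weights[truth_spec.id]
            prev = (obs, quota, z)

    in_band = (all_N >= utility_cfg.band_low) & (all_N <= utility_cfg.band_high)
    return MSEMetrics(
        mean_abundance=float(all_N.mean()),
        frac_years_in_band=float(in_band.mean()),
        mean_harvest=float(all_h.mean()),
        closure_frequency=float(all_closed.mean()),
        truth_weight_final=float(all_truthw[:, -1].mean()),
        truth_weight_trajectory=all_truthw.mean(axis=0),
    )
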