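"""Utility, stochastic-dynamic-programming harvest optimization, policy tree.

The management objective is a utility peaked at the agreed population target
(60 thousand) with half-utility at the edges of the acceptance band
(50-70 thousand).  Value iteration on a discretized (abundance, DAYS) state
space computes, for the current model weights, the quota (to the nearest 2.5
thousand) maximizing expected discounted utility of the post-transition
population, averaging over model uncertainty, process error and next year's
spring conditions.  A CART-style regression tree on (adults, young, DAYS)
gives the field-friendly yes/no summary of the lookup table.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import norm
from sklearn.tree import DecisionTreeRegressor

from .models import (
    Climatology,
    ModelSpec,
    ParameterSet,
    PopulationState,
    derive_age_split,
    transition,
)
from .weights import WeightVector


class ConvergenceError(RuntimeError):
    """Value iteration failed to reach the tolerance within max_iter."""

    def __init__(self, gap: float, max_iter: int):
        super().__init__(
            f"value iteration did not converge in {max_iter} iterations (gap {gap:.3e})"
        )
        self.gap = gap


@dataclass(frozen=True)
class UtilityConfig:
    """Management preference over population sizes (thousands).

    The Gaussian kernel exp(-(N - target)^2 / (2 shape_sd^2)) equals one at
    the target and, by construction of ``shape_sd``, one half at the band
    edges.
    """

    target: float = 60.0
    band_low: float = 50.0
    band_high: float = 70.0

    def __post_init__(self) -> None:
        if not self.band_low < self.target < self.band_high:
            raise ValueError("band_low < target < band_high required")

    @property
    def shape_sd(self) -> float:
        return (self.band_high - self.target) / math.sqrt(2.0 * math.log(2.0))


def utility(N, cfg: UtilityConfig):
    """Utility in [0, 1] of an abundance (thousands)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundance must be non-negative")
    u = np.exp(-((N - cfg.target) ** 2) / (2.0 * cfg.shape_sd**2))
    return float(u) if u.ndim == 0 else u


@dataclass(frozen=True, eq=False)
class Grids:
    """Discretization of abundance, DAYS and quota (all thousands but DAYS)."""

    N_grid: np.ndarray
    days_grid: np.ndarray
    action_grid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("N_grid", "days_grid", "action_grid"):
            g = getattr(self, name)
            if len(g) < 1 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    @classmethod
    def default(cls) -> "Grids":
        return cls(
            N_grid=np.arange(0.0, 150.0 + 1e-9, 2.5),
            days_grid=np.arange(0.0, 25.0, 2.0),
            action_grid=np.arange(0.0, 30.0 + 1e-9, 2.5),
        )


def _nearest_index(grid: np.ndarray, x: float) -> int:
    # ties broken toward the lower node: argmin returns the first minimum
    return int(np.abs(grid - x).argmin())


@dataclass(eq=False)
class Policy:
    """State -> quota lookup table on the (N, DAYS) grid."""

    table: np.ndarray  # (len(N_grid), len(days_grid)) quota in thousands
    grids: Grids
    metadata: dict[str, Any] = field(default_factory=dict)
    value: np.ndarray | None = None  # optimal values, same shape as table

    def __post_init__(self) -> None:
        if self.table.shape != (len(self.grids.N_grid), len(self.grids.days_grid)):
            raise ValueError("policy table does not cover the state grid")
        if not np.all(np.isin(self.table, self.grids.action_grid)):
            raise ValueError("policy table contains off-grid quotas")

    def to_frame(self):
        import pandas as pd

        nn, dd = np.meshgrid(self.grids.N_grid, self.grids.days_grid, indexing="ij")
        return pd.DataFrame(
            {"N": nn.ravel(), "days": dd.ravel(), "quota": self.table.ravel()}
        )


def lookup_quota(policy: Policy, state: PopulationState) -> float:
    """Quota (thousands) at the grid node nearest the state (clamped to hull)."""
    i = _nearest_index(policy.grids.N_grid, state.N)
    j = _nearest_index(policy.grids.days_grid, state.days)
    return float(policy.table[i, j])


def value_iteration(P: np.ndarray, R: np.ndarray, discount: float,
                    tol: float = 1e-10, max_iter: int = 100_000):
    """Generic infinite-horizon value iteration for a finite MDP.

    Parameters: P with shape (A, S, S) row-stochastic in its last axis, R
    with shape (A, S) the expected immediate reward of action a in state s.
    Returns (V, policy_index).
    """
    if not 0 < discount < 1:
        raise ValueError("discount must lie in (0, 1)")
    A, S, _ = P.shape
    V = np.zeros(S)
    gap = np.inf
    for _ in range(max_iter):
        Q = R + discount * P @ V
        Vn = Q.max(axis=0)
        gap = float(np.abs(Vn - V).max())
        V = Vn
        if gap < tol:
            break
    else:
        raise ConvergenceError(gap, max_iter)
    Q = R + discount * P @ V
    return V, Q.argmax(axis=0)


def build_transition_kernels(
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    grids: Grids,
    climatology: Climatology,
):
    """Per-model transition tensors on the state grid.

    Returns ``(K, day_probs)`` where ``K[m, d, a, i, j]`` is the probability
    of moving from abundance node i to node j under model m, quota
    ``action_grid[a]`` and current DAYS node d, and ``day_probs`` is the
    climatology mass aggregated onto the DAYS grid (next year's conditions
    are treated as i.i.d. draws).

    Process error is discretized by lognormal bin masses at the midpoints
    between abundance nodes; with zero process error the deterministic core
    is split linearly between its two neighbouring nodes.
    """
    n = grids.N_grid
    d = grids.days_grid
    a = grids.action_grid
    M, D, A, NN = len(model_specs), len(d), len(a), len(n)

    day_probs = np.zeros(D)
    for v, p in zip(climatology.support, climatology.probs):
        day_probs[_nearest_index(d, float(v))] += p

    z = climatology.standardize(d)  # (D,)
    # deterministic cores, shape (M, D, A, NN)
    core = np.empty((M, D, A, NN))
    for mi, spec in enumerate(model_specs):
        for di in range(D):
            for ai in range(A):
                core[mi, di, ai] = transition(n, a[ai], z[di], params, spec)

    K = np.zeros((M, D, A, NN, NN))
    sd = params.process_sd
    if sd == 0:
        # linear interpolation of the point mass between bracketing nodes
        lo = np.clip(np.searchsorted(n, core, side="right") - 1, 0, NN - 2)
        hi = lo + 1
        w_hi = np.clip((core - n[lo]) / (n[hi] - n[lo]), 0.0, 1.0)
        np.put_along_axis(K, lo[..., None], (1.0 - w_hi)[..., None], axis=-1)
        buf = np.take_along_axis(K, hi[..., None], axis=-1) + w_hi[..., None]
        np.put_along_axis(K, hi[..., None], buf, axis=-1)
    else:
        mids = (n[:-1] + n[1:]) / 2.0  # (NN-1,) interior bin edges, all > 0
        pos = core > 0
        mu = np.where(pos, np.log(np.where(pos, core, 1.0)) - 0.5 * sd * sd, 0.0)
        zscores = (np.log(mids)[None, None, None, None, :] - mu[..., None]) / sd
        cdf = norm.cdf(zscores)  # (M, D, A, NN, NN-1)
        K[..., 0] = cdf[..., 0]
        K[..., 1:-1] = np.diff(cdf, axis=-1)
        K[..., -1] = 1.0 - cdf[..., -1]
        # absorbing zero when the deterministic core is extinct
        K[~pos] = 0.0
        K[~pos, 0] = 1.0
    return K, day_probs


def optimize_policy(
    model_specs: Sequence[ModelSpec],
    params: ParameterSet,
    weights: WeightVector,
    grids: Grids,
    utility_cfg: UtilityConfig,
    climatology: Climatology,
    discount: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 1000,
    kernels=None,
    v0: np.ndarray | None = None,
) -> Policy:
    """Model-averaged value iteration returning the optimal quota table.

    The state is (abundance node, current DAYS node); next year's DAYS is an
    independent climatology draw, so the continuation value enters only
    through its DAYS-expectation.  The immediate reward of an action is the
    expected utility of the post-transition abundance.  ``kernels`` may be
    the precomputed output of :func:`build_transition_kernels` (reused across
    annual re-optimizations), and ``v0`` warm-starts the value function.
    """
    if not 0 < discount < 1:
        raise ValueError("discount must lie in (0, 1)")
    K, day_probs = (
        kernels if kernels is not None
        else build_transition_kernels(model_specs, params, grids, climatology)
    )
    w = np.array([weights[m.id] for m in model_specs])
    Kmix = np.einsum("m,mdaij->daij", w, K)  # (D, A, NN, NN)
    u = utility(grids.N_grid, utility_cfg)

    NN, D = len(grids.N_grid), len(grids.days_grid)
    V = np.zeros((NN, D)) if v0 is None else v0.copy()
    gap = np.inf
    for it in range(max_iter):
        W = V @ day_probs  # (NN,) DAYS-expected continuation
        Q = Kmix @ (u + discount * W)  # (D, A, NN)
        Vn = Q.max(axis=1).T
        gap = float(np.abs(Vn - V).max())
        V = Vn
        if gap < tol:
            break
    else:
        raise ConvergenceError(gap, max_iter)

    W = V @ day_probs
    Q = Kmix @ (u + discount * W)
    table = grids.action_grid[Q.argmax(axis=1)].T  # ties -> lowest action
    return Policy(
        table=table,
        grids=grids,
        metadata={
            "weights": dict(weights.items()),
            "discount": discount,
            "iterations": it + 1,
            "gap": gap,
        },
        value=V,
    )


def _snap_to_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.abs(grid[None, :] - np.asarray(values, dtype=float)[:, None]).argmin(axis=1)
    return grid[idx]


@dataclass(eq=False)
class PolicyTree:
    """Yes/no threshold summary of a policy, split on A, Y and DAYS."""

    estimator: DecisionTreeRegressor
    feature_names: tuple[str, ...]
    action_grid: np.ndarray
    max_depth: int

    def predict(self, A, Y, days):
        X = np.column_stack(
            [np.atleast_1d(np.asarray(v, dtype=float)) for v in (A, Y, days)]
        )
        raw = self.estimator.predict(X)
        snapped = _snap_to_grid(raw, self.action_grid)
        return float(snapped[0]) if np.isscalar(A) else snapped

    @property
    def n_leaves(self) -> int:
        return int(self.estimator.get_n_leaves())

    def split_variables(self) -> set[str]:
        tree = self.estimator.tree_
        return {self.feature_names[f] for f in tree.feature if f >= 0}

    def to_text(self) -> str:
        """Indented yes/no rendering (yes branch first, then no)."""
        tree = self.estimator.tree_
        lines: list[str] = []

        def recurse(node: int, depth: int) -> None:
            pad = "  " * depth
            f = tree.feature[node]
            if f < 0:
                q = _snap_to_grid(np.array([tree.value[node][0][0]]), self.action_grid)[0]
                lines.append(f"{pad}quota = {q:g}")
                return
            name = self.feature_names[f]
            thr = tree.threshold[node]
            lines.append(f"{pad}{name} <= {thr:g}?")
            lines.append(f"{pad}yes:")
            recurse(tree.children_left[node], depth + 1)
            lines.append(f"{pad}no:")
            recurse(tree.children_right[node], depth + 1)

        recurse(0, 0)
        return "\n".join(lines)

    def to_dot(self) -> str:
        from sklearn.tree import export_graphviz

        return export_graphviz(
            self.estimator, feature_names=list(self.feature_names), filled=False
        )


def fit_policy_tree(
    policy: Policy, reproduction_ref: float, max_depth: int = 6
) -> PolicyTree:
    """Fit a CART regression tree to the policy table.

    Grid states are expanded to (A, Y, DAYS) samples via the adult/young
    split at a reference reproduction rate; greedy variance-reduction splits,
    leaf quotas snapped to the action grid.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be at least 1")
    nn, dd = np.meshgrid(policy.grids.N_grid, policy.grids.days_grid, indexing="ij")
    A, Y = derive_age_split(nn.ravel(), reproduction_ref)
    X = np.column_stack([A, Y, dd.ravel()])
    y = policy.table.ravel()
    est = DecisionTreeRegressor(max_depth=max_depth, random_state=0)
    est.fit(X, y)
    # snap leaf predictions to admissible quotas in place
    tree = est.tree_
    leaves = tree.feature < 0
    tree.value[leaves, 0, 0] = _snap_to_grid(
        tree.value[leaves, 0, 0], policy.grids.action_grid
    )
    return PolicyTree(
        estimator=est,
        feature_names=("A", "Y", "DAYS"),
        action_grid=policy.grids.action_grid,
        max_depth=max_depth,
    )
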