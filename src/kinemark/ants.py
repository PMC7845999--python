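"""Ant-colony feature selection over RMK variables.

Each "ant" samples a subset of K features with probabilities proportional
to per-feature pheromone weights, a model is fitted on the subset, and the
training R^2 is mapped to a path length

    L(R^2) = (10^5 - 1) / (10^(5 R^2) - 1)

so that L increases about 10-fold for every 0.2 drop in R^2 (down to
R^2 ~ 0.2, below which the penalty grows faster still).  Weights of the
selected features are reinforced by dw / L while all weights evaporate by
a factor (1 - rho), so features that keep appearing in good subsets are
selected ever more often.  An exhaustive-search oracle is provided for
small instances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: finite surrogate for the infinite path length at R^2 = 0
DEFAULT_L_CAP = 1e12

#: weights never decay below this floor, keeping probabilities well-defined
WEIGHT_FLOOR = 1e-6

Evaluator = Callable[[tuple[str, ...]], float]


@dataclass(frozen=True)
class ColonyConfig:
    """Colony parameters.

    ``n_ants``, ``w0`` and ``dw`` default to the values used in the
    original application (3,000 ants, w0 = 0.01, dw = 0.1, 10 restarts).
    The evaporation coefficient ``rho`` is not pinned down by the source
    description; the default 0.1 is of the same order as ``dw`` so stale
    trails decay over tens of ants.
    """

    K: int
    n_ants: int = 3000
    w0: float = 0.01
    dw: float = 0.1
    rho: float = 0.1
    n_restarts: int = 10
    seed: int = 0
    #: if False, only the selected features evaporate (variant behavior)
    evaporate_all: bool = True
    l_cap: float = DEFAULT_L_CAP

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.dw < 0:
            raise ValueError("dw must be >= 0")


@dataclass
class ColonyState:
    """Pheromone weights plus the best subset found so far."""

    features: tuple[str, ...]
    weights: np.ndarray
    ant_index: int = 0
    best_subset: tuple[str, ...] = ()
    best_quality: float = 0.0

    def probabilities(self) -> np.ndarray:
        return selection_probabilities(self.weights)


def path_length(r_squared: float, l_cap: float = DEFAULT_L_CAP) -> float:
    """Map a training R^2 in [0, 1] to the ant's path length.

    L(1) = 1; L is strictly decreasing in R^2.  At R^2 = 0 the expression
    diverges, so a configured large cap is returned instead (and logged).
    """
    if not (0.0 <= r_squared <= 1.0):
        raise ValueError(f"r_squared must be in [0, 1], got {r_squared}")
    denom = 10.0 ** (5.0 * r_squared) - 1.0
    if denom <= 0.0:
        logger.debug("path length capped at %.3g for R^2 = 0", l_cap)
        return l_cap
    return min((10.0**5 - 1.0) / denom, l_cap)


def selection_probabilities(weights: np.ndarray | Sequence[float]) -> np.ndarray:
    """p_k = w_k / sum(w); requires strictly positive weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all pheromone weights must be strictly positive")
    return w / w.sum()


def sample_subset(state: ColonyState, K: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Draw K distinct features sequentially without replacement.

    After each draw the probabilities are renormalized over the remaining
    features, mirroring an ant extending its path one variable at a time.
    Returned in canonical (pool) order.
    """
    n = len(state.features)
    if K > n:
        raise ValueError(f"K = {K} exceeds the {n} available features")
    w = state.weights.copy()
    chosen: list[int] = []
    for _ in range(K):
        p = w / w.sum()
        idx = int(rng.choice(n, p=p))
        chosen.append(idx)
        w[idx] = 0.0
    chosen.sort()
    return tuple(state.features[i] for i in chosen)


def update_weights(
    state: ColonyState,
    subset: Sequence[str],
    L: float,
    config: ColonyConfig,
) -> ColonyState:
    """Apply the pheromone update after one ant.

    Selected features receive ``(1 - rho) * w + dw / L``; with
    ``evaporate_all`` (default) every other weight decays by ``(1 - rho)``
    as well, mimicking pheromone evaporating everywhere.  Weights are
    floored at a small positive constant.
    """
    if L <= 0:
        raise ValueError("path length must be positive")
    sel = np.isin(state.features, list(subset))
    w = state.weights.copy()
    if config.evaporate_all:
        w *= 1.0 - config.rho
    else:
        w[sel] *= 1.0 - config.rho
    w[sel] += config.dw / L
    np.maximum(w, WEIGHT_FLOOR, out=w)
    state.weights = w
    state.ant_index += 1
    return state


@dataclass
class ColonyTrace:
    """Per-ant log: subset sampled, its R^2, and the resulting path length."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def run_colony(
    features: Sequence[str],
    evaluator: Evaluator,
    config: ColonyConfig,
    keep_trace: bool = False,
) -> tuple[tuple[str, ...], float, ColonyTrace]:
    """Run the colony with restarts; return the best subset found.

    Each restart resets the weights to w0 and releases ``n_ants`` ants
    (sample -> evaluate -> path length -> weight update).  The evaluator
    maps a feature tuple to a training R^2; failures score R^2 = 0
    (maximal path length) and the run continues.  Results are cached per
    subset, so converged colonies re-sampling the same subset are cheap.
    Fully reproducible under a fixed seed.
    """
    features = tuple(features)
    root = np.random.SeedSequence(config.seed)
    restart_seeds = root.spawn(config.n_restarts)
    trace = ColonyTrace()
    cache: dict[tuple[str, ...], float] = {}

    best_subset: tuple[str, ...] = ()
    best_quality = -1.0
    restart_bests: list[tuple[tuple[str, ...], float]] = []

    for restart, seed in enumerate(restart_seeds):
        rng = np.random.default_rng(seed)
        state = ColonyState(
            features=features,
            weights=np.full(len(features), config.w0, dtype=float),
        )
        r_best_subset: tuple[str, ...] = ()
        r_best_quality = -1.0
        for ant in range(config.n_ants):
            subset = sample_subset(state, config.K, rng)
            if subset in cache:
                r2 = cache[subset]
            else:
                try:
                    r2 = float(evaluator(subset))
                except Exception:
                    logger.warning("evaluator failed on %s; scoring R^2 = 0", subset, exc_info=True)
                    r2 = 0.0
                r2 = min(max(r2, 0.0), 1.0)  # clamp degenerate fits
                cache[subset] = r2
            L = path_length(r2, config.l_cap)
            update_weights(state, subset, L, config)
            if r2 > r_best_quality:
                r_best_subset, r_best_quality = subset, r2
            if keep_trace:
                trace.records.append(
                    dict(restart=restart, ant=ant, subset="|".join(subset), r2=r2, L=L)
                )
        restart_bests.append((r_best_subset, r_best_quality))
        if r_best_quality > best_quality:
            best_subset, best_quality = r_best_subset, r_best_quality

    trace.restart_bests = restart_bests  # type: ignore[attr-defined]
    return best_subset, best_quality, trace


def exhaustive_search(
    features: Sequence[str],
    evaluator: Evaluator,
    K: int,
    cap: int = 10_000,
) -> tuple[tuple[str, ...], float]:
    """Evaluate every K-subset; the deterministic oracle for small N.

    Refuses when C(N, K) exceeds ``cap``, reporting the count.
    """
    features = tuple(features)
    n_comb = math.comb(len(features), K)
    if n_comb > cap:
        raise ValueError(f"C({len(features)}, {K}) = {n_comb} exceeds the cap of {cap}")
    best_subset: tuple[str, ...] = ()
    best_quality = -np.inf
    for combo in combinations(features, K):
        r2 = min(max(float(evaluator(combo)), 0.0), 1.0)
        if r2 > best_quality:
            best_subset, best_quality = combo, r2
    return best_subset, best_quality


def linear_r2_evaluator(table: pd.DataFrame, target: str) -> Evaluator:
    """Deterministic evaluator: OLS training R^2 on the subset columns."""
    y = table[target].to_numpy(float)
    yc = y - y.mean()
    sst = float(yc @ yc)

    def evaluate(subset: tuple[str, ...]) -> float:
        X = table[list(subset)].to_numpy(float)
        X = np.column_stack([X, np.ones(len(X))])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        if sst <= 0:
            return 0.0
        return 1.0 - float(resid @ resid) / sst

    return evaluate
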