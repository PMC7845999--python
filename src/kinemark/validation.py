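"""Cross-validation, external validation, the K x h experiment grid, and
leave-one-feature-out ("apo model") importance analysis.

Model quality is quantified by R^2_CV: the squared Pearson correlation
between the pooled out-of-fold predictions of a repeated 10-fold jackknife
and the actual clinical scores.  Because a single partition is itself a
source of variance, the procedure is repeated (10 times by default) with
different shuffles and the mean and sd of R^2_CV are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ants import ColonyConfig, run_colony
from .nets import NetworkConfig, network_evaluator, predict, train_ensemble

logger = logging.getLogger(__name__)

#: builder(table, target, features, seed) -> callable(rows) -> predictions
ModelBuilder = Callable[[pd.DataFrame, str, Sequence[str], int], Callable[[pd.DataFrame], np.ndarray]]


def r_squared(pred: np.ndarray, actual: np.ndarray) -> float:
    """Squared Pearson correlation; defined as 0 for constant inputs."""
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if np.std(pred) == 0 or np.std(actual) == 0:
        warnings.warn("constant predictions or targets; R^2 defined as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(pred, actual)[0, 1]
    return float(r * r)


def r_squared_sse(pred: np.ndarray, actual: np.ndarray) -> float:
    """1 - SSE/SST variant (can be negative); available behind this name."""
    actual = np.asarray(actual, float)
    sst = float(np.sum((actual - actual.mean()) ** 2))
    if sst == 0:
        return 0.0
    sse = float(np.sum((actual - np.asarray(pred, float)) ** 2))
    return 1.0 - sse / sst


@dataclass
class ValidationResult:
    """Pooled out-of-fold predictions and per-repetition R^2_CV values."""

    predictions: np.ndarray  # (repetitions, n_rows), aligned to table rows
    actual: np.ndarray
    r2cv: np.ndarray  # (repetitions,)
    training_r2: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.r2cv))

    @property
    def sd(self) -> float:
        return float(np.std(self.r2cv, ddof=1)) if len(self.r2cv) > 1 else 0.0


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle rows and split into ``folds`` near-equal disjoint subsets."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def kfold_cv(
    table: pd.DataFrame,
    target: str,
    builder: ModelBuilder,
    features: Sequence[str],
    folds: int = 10,
    rng: np.random.Generator | int | None = None,
) -> ValidationResult:
    """One repetition of the 10-fold jackknife.

    Rows are shuffled and partitioned into ``folds`` disjoint subsets;
    each subset is predicted by a model trained on its complement, and
    R^2_CV is the squared Pearson correlation between the pooled
    out-of-fold predictions and the actual scores.
    """
    if len(table) < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV, got {len(table)}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(table)
    pooled = np.empty(n)
    y = table[target].to_numpy(float)
    for fold, test_idx in enumerate(_fold_indices(n, folds, rng)):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = builder(table.iloc[train_idx], target, features, int(rng.integers(2**31)))
        pooled[test_idx] = model(table.iloc[test_idx])
    r2 = r_squared(pooled, y)
    return ValidationResult(predictions=pooled[None, :], actual=y, r2cv=np.array([r2]))


def repeated_cv(
    table: pd.DataFrame,
    target: str,
    builder: ModelBuilder,
    features: Sequence[str],
    repetitions: int = 10,
    folds: int = 10,
    base_seed: int = 0,
) -> ValidationResult:
    """Repeat the jackknife with different shuffles; report mean +/- sd."""
    preds, r2s = [], []
    for rep in range(repetitions):
        res = kfold_cv(
            table, target, builder, features, folds=folds,
            rng=np.random.default_rng(np.random.SeedSequence((base_seed, rep))),
        )
        preds.append(res.predictions[0])
        r2s.append(res.r2cv[0])
    return ValidationResult(
        predictions=np.vstack(preds),
        actual=table[target].to_numpy(float),
        r2cv=np.asarray(r2s),
    )


def external_validation(model: Callable[[pd.DataFrame], np.ndarray],
                        external: pd.DataFrame, target: str) -> float:
    """R^2 of a frozen model on held-out patients (e.g. non-completers)."""
    if len(external) < 3:
        raise ValueError(f"external validation needs >= 3 rows, got {len(external)}")
    return r_squared(model(external), external[target].to_numpy(float))


def ensemble_builder(
    config: NetworkConfig = NetworkConfig(),
    n_members: int = 10,
) -> ModelBuilder:
    """Standard model builder: a seed-varied logistic-net ensemble."""

    def build(table: pd.DataFrame, target: str, features: Sequence[str], seed: int):
        ens = train_ensemble(table, target, features, config, n_members=n_members, base_seed=seed)
        return lambda rows: predict(ens, rows)

    return build


def linear_builder() -> ModelBuilder:
    """Ordinary least-squares baseline builder (minimum-norm on collinear
    designs)."""

    def build(table: pd.DataFrame, target: str, features: Sequence[str], seed: int):
        X = np.column_stack([table[list(features)].to_numpy(float), np.ones(len(table))])
        y = table[target].to_numpy(float)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            warnings.warn("collinear design; using minimum-norm OLS solution", stacklevel=2)
        return lambda rows: np.column_stack(
            [rows[list(features)].to_numpy(float), np.ones(len(rows))]
        ) @ beta

    return build


@dataclass(frozen=True)
class ExperimentPlan:
    """The K x h experiment grid and its bookkeeping counts."""

    scales: tuple[str, ...] = ("FM", "MP", "NIH", "MR")
    k_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14)
    h_grid: tuple[int, ...] = (1, 2, 3)
    ant_restarts: int = 5
    ensemble_size: int = 10
    cv_repetitions: int = 10
    folds: int = 10
    n_ants: int = 3000

    def __post_init__(self) -> None:
        counts = (len(self.scales), len(self.k_grid), len(self.h_grid),
                  self.ant_restarts, self.ensemble_size, self.folds)
        if min(counts) < 1 or self.cv_repetitions < 0:
            raise ValueError("all plan counts must be >= 1 (cv repetitions >= 0)")


def count_planned_networks(plan: ExperimentPlan) -> int:
    """Total individual network trainings the plan implies.

    scales x |K| x |h| x restarts x ensemble x (cv reps + 1) x folds —
    the "+1" being the one training run per network alongside its
    cross-validation runs, and folds multiplying both, as conventionally
    tallied for this protocol.  The default plan gives 462,000.
    """
    return (
        len(plan.scales)
        * len(plan.k_grid)
        * len(plan.h_grid)
        * plan.ant_restarts
        * plan.ensemble_size
        * (plan.cv_repetitions + 1)
        * plan.folds
    )


def select_and_validate(
    table: pd.DataFrame,
    target: str,
    K: int,
    h: int = 2,
    n_ants: int = 3000,
    n_restarts: int = 10,
    cv_repetitions: int = 10,
    folds: int = 10,
    ensemble_size: int = 10,
    seed: int = 0,
    epochs: int = 100,
) -> dict:
    """Ant selection then ensemble cross-validation for one configuration.

    Returns the selected subset, its training R^2 during selection, and
    the repeated-CV result of the ensemble built on it.
    """
    features = [c for c in table.columns if c not in ("patient_id", "day", target)]
    net_cfg = NetworkConfig(n_hidden=h, epochs=epochs, seed=seed)
    evaluator = network_evaluator(table, target, net_cfg)
    colony_cfg = ColonyConfig(K=K, n_ants=n_ants, n_restarts=n_restarts, seed=seed)
    subset, train_r2, _ = run_colony(features, evaluator, colony_cfg)
    cv = repeated_cv(
        table, target, ensemble_builder(net_cfg, ensemble_size), subset,
        repetitions=cv_repetitions, folds=folds, base_seed=seed,
    )
    return dict(subset=subset, training_r2=train_r2, cv=cv)


def run_experiment_grid(
    table_by_scale: dict[str, pd.DataFrame],
    plan: ExperimentPlan,
    seed: int = 0,
    epochs: int = 100,
) -> pd.DataFrame:
    """Run the full (scale, K, h, restart) grid; one results row per cell.

    Each cell runs ant selection (one restart each, so restarts appear as
    separate rows, as in the source protocol) followed by ensemble
    training and repeated cross-validation.  Cell failures are recorded
    and the grid continues.
    """
    rows = []
    for scale in plan.scales:
        table = table_by_scale[scale]
        for K in plan.k_grid:
            for h in plan.h_grid:
                for restart in range(plan.ant_restarts):
                    cell_seed = abs(hash((seed, scale, K, h, restart))) % (2**31)
                    try:
                        res = select_and_validate(
                            table, scale, K, h=h, n_ants=plan.n_ants, n_restarts=1,
                            cv_repetitions=plan.cv_repetitions, folds=plan.folds,
                            ensemble_size=plan.ensemble_size, seed=cell_seed, epochs=epochs,
                        )
                        rows.append(dict(
                            scale=scale, K=K, h=h, restart=restart,
                            subset="|".join(res["subset"]),
                            training_r2=res["training_r2"],
                            r2cv_mean=res["cv"].mean, r2cv_sd=res["cv"].sd,
                            error="",
                        ))
                    except Exception as exc:
                        logger.warning("grid cell (%s, K=%d, h=%d, restart=%d) failed: %s",
                                       scale, K, h, restart, exc)
                        rows.append(dict(scale=scale, K=K, h=h, restart=restart,
                                         subset="", training_r2=np.nan,
                                         r2cv_mean=np.nan, r2cv_sd=np.nan, error=str(exc)))
    return pd.DataFrame(rows)


def feature_importance(
    table: pd.DataFrame,
    target: str,
    K: int = 8,
    h: int = 2,
    n_ants: int = 3000,
    n_restarts: int = 10,
    cv_repetitions: int = 10,
    folds: int = 10,
    ensemble_size: int = 10,
    seed: int = 0,
    epochs: int = 100,
    alpha: float = 0.05,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apo-model importance: drop each feature from the pool and redo
    selection + aggregation + cross-validation.

    For every feature f, the selection is re-run on the pool without f
    (still choosing K features), an ensemble is built and repeatedly
    cross-validated, and the replicate R^2_CV values are compared to the
    full-pool model's replicates with a two-sided Welch t-test.  A
    significant drop marks f as important; a redundant feature (one with
    correlated stand-ins in the pool) shows no significant change.
    """
    pool = list(features) if features is not None else [
        c for c in table.columns if c not in ("patient_id", "day", target)
    ]
    if len(pool) < K + 1:
        raise ValueError(f"need more than K={K} features in the pool, got {len(pool)}")

    kwargs = dict(K=K, h=h, n_ants=n_ants, n_restarts=n_restarts,
                  cv_repetitions=cv_repetitions, folds=folds,
                  ensemble_size=ensemble_size, seed=seed, epochs=epochs)
    full = select_and_validate(table[["patient_id", "day", *pool, target]]
                               if "patient_id" in table.columns else table[[*pool, target]],
                               target, **kwargs)
    full_r2s = full["cv"].r2cv
    rows = [dict(feature="<all>", r2cv_mean=full["cv"].mean, r2cv_sd=full["cv"].sd,
                 p_value=np.nan, significant=False)]
    for f in pool:
        apo_pool = [c for c in pool if c != f]
        cols = ([c for c in ("patient_id", "day") if c in table.columns] + apo_pool + [target])
        apo = select_and_validate(table[cols], target, **kwargs)
        t, p = stats.ttest_ind(full_r2s, apo["cv"].r2cv, equal_var=False)
        rows.append(dict(feature=f, r2cv_mean=apo["cv"].mean, r2cv_sd=apo["cv"].sd,
                         p_value=float(p), significant=bool(p < alpha)))
    return pd.DataFrame(rows)
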