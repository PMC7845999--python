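"""Correlation-structure visualization and linear baselines.

* A correlation-distance matrix d_ij = 1 - |Pearson R_ij| over the 35 RMK
  features and the four clinical scales, computed pairwise-complete (the
  modified Rankin scale exists only at days 30/90, so listwise deletion
  would discard most rows).
* Stochastic proximity embedding (SPE) of that matrix into 2-D: repeated
  random-pair updates pull each pair toward its target distance under an
  annealed learning rate, yielding a map where correlated variables
  cluster.
* PCA variance profiling (intrinsic dimensionality) and a PCA-based
  feature picker, plus multi-linear-regression baselines cross-validated
  with the same jackknife as the neural models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import Cohort
from .validation import ValidationResult, linear_builder, repeated_cv


@dataclass
class CorrelationDistanceMatrix:
    """Symmetric matrix of d_ij = 1 - |R_ij|; NaN marks unestimable pairs."""

    variables: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.variables),) * 2:
            raise ValueError("distance matrix shape does not match variables")
        if not np.allclose(np.nan_to_num(d), np.nan_to_num(d.T)):
            raise ValueError("distance matrix must be symmetric")
        finite = d[np.isfinite(d)]
        if np.any(finite < -1e-9) or np.any(finite > 1 + 1e-9):
            raise ValueError("correlation distances must lie in [0, 1]")


@dataclass(frozen=True)
class EmbeddingConfig:
    dimensions: int = 2
    steps: int | None = None  # default 50 * n_points^2
    lr_start: float = 1.0
    lr_end: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensions < 1:
            raise ValueError("dimensions must be >= 1")
        if self.steps is not None and self.steps < 1:
            raise ValueError("steps must be >= 1")


def correlation_distances(
    cohort: Cohort | pd.DataFrame,
    variables: Sequence[str] | None = None,
    min_periods: int = 3,
) -> CorrelationDistanceMatrix:
    """d_ij = 1 - |Pearson R| over all patients and time points.

    Pairs with fewer than ``min_periods`` jointly observed rows get a NaN
    entry and are excluded from the embedding stress.
    """
    data = cohort.data if isinstance(cohort, Cohort) else cohort
    if variables is None:
        if isinstance(cohort, Cohort):
            variables = list(cohort.schema.features) + ["FM", "MP", "NIH", "MR"]
        else:
            variables = list(data.columns)
    sub = data[list(variables)].astype(float)
    R = sub.corr(method="pearson", min_periods=min_periods).to_numpy()
    d = 1.0 - np.abs(R)
    np.fill_diagonal(d, 0.0)
    return CorrelationDistanceMatrix(variables=tuple(variables), distances=d)


def spe_stress(coords: np.ndarray, target: np.ndarray) -> float:
    """Normalized stress: sum (d_target - d_map)^2 / sum d_target^2."""
    diff = coords[:, None, :] - coords[None, :, :]
    current = np.sqrt((diff**2).sum(axis=2))
    mask = np.isfinite(target)
    np.fill_diagonal(mask, False)
    t = target[mask]
    denom = float((t**2).sum())
    if denom == 0:
        return 0.0
    return float(((t - current[mask]) ** 2).sum() / denom)


def spe_embed(
    matrix: CorrelationDistanceMatrix | np.ndarray,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> tuple[np.ndarray, float]:
    """Stochastic proximity embedding of a distance matrix.

    Starting from random coordinates, repeatedly pick a random pair
    (i, j) and move both points along their difference by
    lr * (d_target - d_current) / (d_current + eps) / 2, with the
    learning rate annealed linearly over the schedule.  Returns the
    coordinates and the final normalized stress.  Accepts either a
    :class:`CorrelationDistanceMatrix` or any symmetric distance array.
    """
    if isinstance(matrix, CorrelationDistanceMatrix):
        target = matrix.distances
    else:
        target = np.asarray(matrix, float)
    n = len(target)
    eps = 1e-9
    rng = np.random.default_rng(config.seed)
    finite = target[np.isfinite(target)]
    if n == 0:
        return np.zeros((0, config.dimensions)), 0.0
    if np.all(finite == 0):
        return np.zeros((n, config.dimensions)), 0.0
    scale = float(np.nanmax(target))
    coords = rng.uniform(-0.5 * scale, 0.5 * scale, size=(n, config.dimensions))
    steps = config.steps if config.steps is not None else 50 * n * n
    lrs = np.linspace(config.lr_start, config.lr_end, steps)
    pairs_i = rng.integers(0, n, size=steps)
    pairs_j = rng.integers(0, n - 1, size=steps)
    pairs_j = np.where(pairs_j >= pairs_i, pairs_j + 1, pairs_j)  # j != i
    for s in range(steps):
        i, j = pairs_i[s], pairs_j[s]
        t = target[i, j]
        if not np.isfinite(t):
            continue
        diff = coords[i] - coords[j]
        cur = np.sqrt((diff**2).sum())
        step = lrs[s] * 0.5 * (t - cur) / (cur + eps) * diff
        coords[i] += step
        coords[j] -= step
    return coords, spe_stress(coords, target)


def pca_variance_profile(table: pd.DataFrame) -> tuple[np.ndarray, dict[int, int]]:
    """Per-component variance fractions of the correlation matrix.

    Components are the eigenvalues of the correlation matrix of the
    complete rows (i.e., PCA on standardized variables).  Returns the
    fractions and the number of components needed to reach the 90%, 95%
    and 99% cumulative-variance levels.
    """
    clean = table.dropna()
    corr = np.corrcoef(clean.to_numpy(float), rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)  # trailing zero eigenvalues on rank-deficient input
    fractions = eig / eig.sum()
    cum = np.cumsum(fractions)
    levels = {p: int(np.searchsorted(cum, p / 100.0 - 1e-12) + 1) for p in (90, 95, 99)}
    return fractions, levels


def pca_select_features(table: pd.DataFrame, n_features: int = 8) -> list[str]:
    """Pick the variables dominating successive principal components.

    Walking down the components of a PCA on the standardized complete
    rows, each component contributes the not-yet-chosen variable with the
    largest absolute loading, until ``n_features`` are collected (cycling
    back through components if necessary).  One defensible reading of
    "PCA-selected most important features"; documented, not canonical.
    """
    cols = list(table.columns)
    if n_features > len(cols):
        raise ValueError(f"n_features={n_features} exceeds {len(cols)} variables")
    clean = table.dropna().to_numpy(float)
    std = clean.std(axis=0, ddof=1)
    std[std == 0] = 1.0
    z = (clean - clean.mean(axis=0)) / std
    pca = PCA()
    pca.fit(z)
    chosen: list[str] = []
    loadings = pca.components_  # (n_components, n_vars)
    while len(chosen) < n_features:
        for comp in loadings:
            if len(chosen) >= n_features:
                break
            order = np.argsort(-np.abs(comp))
            for idx in order:
                if cols[idx] not in chosen:
                    chosen.append(cols[idx])
                    break
    return chosen


def mlr_fit_cv(
    table: pd.DataFrame,
    target: str,
    features: Sequence[str],
    repetitions: int = 10,
    folds: int = 10,
    base_seed: int = 0,
) -> tuple[np.ndarray, ValidationResult]:
    """Multi-linear regression baseline, cross-validated like the nets.

    Returns the OLS coefficients (intercept last) fitted on all rows and
    the repeated jackknife result using the same 10-fold procedure as the
    ensemble models.
    """
    features = list(features)
    if len(table) <= len(features) + 1:
        raise ValueError("need more rows than features + 1 for MLR")
    X = np.column_stack([table[features].to_numpy(float), np.ones(len(table))])
    beta, *_ = np.linalg.lstsq(X, table[target].to_numpy(float), rcond=None)
    cv = repeated_cv(table, target, linear_builder(), features,
                     repetitions=repetitions, folds=folds, base_seed=base_seed)
    return beta, cv


def plot_embedding(
    matrix: CorrelationDistanceMatrix,
    coords: np.ndarray,
    path: str,
    schema=None,
) -> None:
    """Render the SPE map with variable-class coloring (clinical /
    affected / non-affected) to SVG or PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = []
    for v in matrix.variables:
        if v in ("FM", "MP", "NIH", "MR"):
            colors.append("red")
        elif v.endswith(" Aff"):
            colors.append("tab:blue")
        else:
            colors.append("tab:green")
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.scatter(coords[:, 0], coords[:, 1], c=colors, s=30)
    for (x, y), v in zip(coords, matrix.variables):
        ax.annotate(v, (x, y), fontsize=6, alpha=0.8)
    ax.set_title("SPE map of correlation distances (1 - |R|)")
    ax.set_aspect("equal")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
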