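"""Three-layer logistic feed-forward regression networks and seed ensembles.

Networks have K inputs, one hidden layer of h logistic units and a single
logistic output, and are trained by online (per-pattern) error
back-propagation for a fixed number of epochs with a linearly decaying
learning rate and momentum; the presentation order is reshuffled every
epoch.  An ensemble is 10 such networks sharing topology and training
parameters and differing only by their random seed (and hence initial
weights and presentation order); its prediction is the arithmetic mean of
the member outputs, mapped back to clinical-scale units.

The per-pattern update loop is compiled with numba; everything else is
plain numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit


class TrainingDivergedError(RuntimeError):
    """Non-finite weights appeared during training."""


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and training schedule of one network."""

    n_hidden: int = 2
    epochs: int = 100
    lr_start: float = 1.0
    lr_end: float = 0.01
    momentum: float = 0.8
    weight_init_range: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.n_hidden < 1:
            raise ValueError("epochs and n_hidden must be >= 1")
        if not (self.lr_start >= self.lr_end > 0):
            raise ValueError("require lr_start >= lr_end > 0")


@dataclass(frozen=True)
class TargetScaler:
    """Affine map from clinical-scale units into the logistic output range.

    The logistic output lives in (0, 1) and cannot reach the endpoints, so
    the observed training (min, max) of the target is mapped to a margin
    interval, [0.1, 0.9] by default, keeping gradients away from
    saturation.
    """

    lo: float
    hi: float
    margin: tuple[float, float] = (0.1, 0.9)

    @classmethod
    def fit(cls, y: np.ndarray, margin: tuple[float, float] = (0.1, 0.9)) -> "TargetScaler":
        return cls(lo=float(np.min(y)), hi=float(np.max(y)), margin=margin)

    def forward(self, y: np.ndarray | float) -> np.ndarray | float:
        m0, m1 = self.margin
        if self.hi == self.lo:
            return np.full_like(np.asarray(y, float), 0.5 * (m0 + m1))
        return m0 + (np.asarray(y, float) - self.lo) / (self.hi - self.lo) * (m1 - m0)

    def inverse(self, s: np.ndarray | float) -> np.ndarray | float:
        m0, m1 = self.margin
        return self.lo + (np.asarray(s, float) - m0) / (m1 - m0) * (self.hi - self.lo)

    @property
    def representable(self) -> tuple[float, float]:
        """Target-unit interval the logistic output can express."""
        return (float(self.inverse(0.0)), float(self.inverse(1.0)))


@njit(cache=True)
def _backprop_epochs(X, y, W1, W2, V1, V2, orders, lrs, momentum):  # pragma: no cover
    n, k = X.shape
    h = W1.shape[0]
    hid = np.empty(h)
    dh = np.empty(h)
    for e in range(orders.shape[0]):
        lr = lrs[e]
        for q in range(n):
            i = orders[e, q]
            # forward pass
            for j in range(h):
                s = W1[j, k]
                for m in range(k):
                    s += W1[j, m] * X[i, m]
                hid[j] = 1.0 / (1.0 + np.exp(-s))
            s = W2[h]
            for j in range(h):
                s += W2[j] * hid[j]
            out = 1.0 / (1.0 + np.exp(-s))
            # backward pass (deltas use pre-update output weights)
            dout = (y[i] - out) * out * (1.0 - out)
            for j in range(h):
                dh[j] = hid[j] * (1.0 - hid[j]) * W2[j] * dout
            for j in range(h):
                g = lr * dout * hid[j] + momentum * V2[j]
                V2[j] = g
                W2[j] += g
            g = lr * dout + momentum * V2[h]
            V2[h] = g
            W2[h] += g
            for j in range(h):
                for m in range(k):
                    g = lr * dh[j] * X[i, m] + momentum * V1[j, m]
                    V1[j, m] = g
                    W1[j, m] += g
                g = lr * dh[j] + momentum * V1[j, k]
                V1[j, k] = g
                W1[j, k] += g


@dataclass
class Network:
    """A trained network: hidden weights (h, K+1) and output weights (h+1,).

    The trailing column/entry holds the bias.
    """

    features: tuple[str, ...]
    W1: np.ndarray
    W2: np.ndarray
    config: NetworkConfig

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        """Forward pass; input rows in [0, 1], output in (0, 1)."""
        h = 1.0 / (1.0 + np.exp(-(X @ self.W1[:, :-1].T + self.W1[:, -1])))
        return 1.0 / (1.0 + np.exp(-(h @ self.W2[:-1] + self.W2[-1])))


def train_network(
    table: pd.DataFrame,
    target: str,
    features: Sequence[str],
    config: NetworkConfig,
) -> Network:
    """Train one network on scaled targets (values already in (0, 1)).

    Fully reproducible: the seed determines the initial weights and the
    per-epoch presentation order.
    """
    X = np.ascontiguousarray(table[list(features)].to_numpy(float))
    y = np.ascontiguousarray(table[target].to_numpy(float))
    if np.any((y < 0) | (y > 1)):
        raise ValueError("target must be scaled into (0, 1) before training")
    n, k = X.shape
    h = config.n_hidden
    rng = np.random.default_rng(config.seed)
    r = config.weight_init_range
    W1 = rng.uniform(-r, r, size=(h, k + 1))
    W2 = rng.uniform(-r, r, size=h + 1)
    V1 = np.zeros_like(W1)
    V2 = np.zeros_like(W2)
    orders = np.empty((config.epochs, n), dtype=np.int64)
    for e in range(config.epochs):
        orders[e] = rng.permutation(n)
    lrs = np.linspace(config.lr_start, config.lr_end, config.epochs)
    _backprop_epochs(X, y, W1, W2, V1, V2, orders, lrs, config.momentum)
    if not (np.all(np.isfinite(W1)) and np.all(np.isfinite(W2))):
        raise TrainingDivergedError(
            f"non-finite weights after training (n={n}, k={k}, h={h}, "
            f"lr={config.lr_start}->{config.lr_end}); lower the learning rate"
        )
    return Network(features=tuple(features), W1=W1, W2=W2, config=config)


@dataclass
class Ensemble:
    """Seed-varied ensemble; prediction = mean of member outputs, unscaled."""

    members: list[Network]
    scaler: TargetScaler
    features: tuple[str, ...]
    target: str


def train_ensemble(
    table: pd.DataFrame,
    target: str,
    features: Sequence[str],
    config: NetworkConfig = NetworkConfig(),
    n_members: int = 10,
    base_seed: int | None = None,
) -> Ensemble:
    """Train ``n_members`` networks differing only by seed.

    Member ``i`` uses ``base_seed + i`` (``config.seed + i`` when
    ``base_seed`` is None).  The target is scaled to the margin interval
    from its observed training range.
    """
    features = tuple(features)
    y = table[target].to_numpy(float)
    scaler = TargetScaler.fit(y)
    scaled = table[list(features)].copy()
    scaled["__target__"] = scaler.forward(y)
    seed0 = config.seed if base_seed is None else base_seed
    members = []
    for i in range(n_members):
        cfg = NetworkConfig(**{**asdict(config), "seed": seed0 + i})
        try:
            members.append(train_network(scaled, "__target__", features, cfg))
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} (seed {seed0 + i}) failed") from exc
    return Ensemble(members=members, scaler=scaler, features=features, target=target)


def predict(ensemble: Ensemble, rows: pd.DataFrame) -> np.ndarray:
    """Ensemble prediction in clinical-scale units.

    The member outputs are averaged in scaled space, inverse-mapped, and
    clipped to the scaler's representable range.
    """
    missing = [f for f in ensemble.features if f not in rows.columns]
    if missing:
        raise KeyError(f"prediction rows missing feature(s) {missing}")
    X = rows[list(ensemble.features)].to_numpy(float)
    scaled = np.mean([m.predict_scaled(X) for m in ensemble.members], axis=0)
    lo, hi = ensemble.scaler.representable
    return np.clip(np.asarray(ensemble.scaler.inverse(scaled), float), lo, hi)


def training_r2(ensemble: Ensemble, table: pd.DataFrame) -> float:
    """Squared Pearson correlation of ensemble predictions vs the target."""
    from .validation import r_squared

    return r_squared(predict(ensemble, table), table[ensemble.target].to_numpy(float))


def network_evaluator(
    table: pd.DataFrame,
    target: str,
    config: NetworkConfig = NetworkConfig(),
):
    """Subset -> training R^2 of a single fixed-seed network.

    This is the model-quality evaluator used inside the ant phase; the
    full 10-member ensemble is only built for the subsets that win, in a
    subsequent step.
    """
    from .validation import r_squared

    y = table[target].to_numpy(float)
    scaler = TargetScaler.fit(y)
    scaled = table.copy()
    scaled["__target__"] = scaler.forward(y)

    def evaluate(subset: tuple[str, ...]) -> float:
        net = train_network(scaled, "__target__", subset, config)
        pred = net.predict_scaled(scaled[list(subset)].to_numpy(float))
        return r_squared(pred, y)

    return evaluate


def save_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Serialize topology, weights, scaler and seeds as JSON."""
    doc = {
        "target": ensemble.target,
        "features": list(ensemble.features),
        "scaler": {"lo": ensemble.scaler.lo, "hi": ensemble.scaler.hi,
                   "margin": list(ensemble.scaler.margin)},
        "members": [
            {"config": asdict(m.config), "W1": m.W1.tolist(), "W2": m.W2.tolist()}
            for m in ensemble.members
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path: str | Path) -> Ensemble:
    doc = json.loads(Path(path).read_text())
    features = tuple(doc["features"])
    members = [
        Network(
            features=features,
            W1=np.asarray(m["W1"], float),
            W2=np.asarray(m["W2"], float),
            config=NetworkConfig(**m["config"]),
        )
        for m in doc["members"]
    ]
    scaler = TargetScaler(
        lo=doc["scaler"]["lo"], hi=doc["scaler"]["hi"], margin=tuple(doc["scaler"]["margin"])
    )
    return Ensemble(members=members, scaler=scaler, features=features, target=doc["target"])
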