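"""Feed-forward neural-network baseline for genome-based prediction.

A fully connected regression network — ReLU hidden layers with (inverted)
dropout, a linear output, mean-squared-error loss, trained by RMSprop with
mini-batches of 56 observations — implemented directly on numpy arrays.
Hyperparameters (hidden layers, units per layer, dropout rate) are tuned by
grid search with an inner fivefold cross-validation on the training set
only; the winning configuration is then refit on the complete training data.

The reference grid is 1–4 hidden layers × {80, 160, 240, 320, 400} units ×
dropout {0, .05, .10, .20, .25, .35} (120 configurations, ``full_grid()``),
with 1,000 epochs; both the grid and the epoch count are reducible for
desk-scale runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

FULL_LAYERS = (1, 2, 3, 4)
FULL_UNITS = (80, 160, 240, 320, 400)
FULL_DROPOUT = (0.0, 0.05, 0.10, 0.20, 0.25, 0.35)


@dataclass(frozen=True)
class DLConfig:
    n_hidden_layers: int = 1
    units_per_layer: int = 80
    dropout: float = 0.0
    batch_size: int = 56
    epochs: int = 1000
    activation: str = "relu"
    optimizer: str = "rmsprop"

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if self.units_per_layer < 1:
            raise ValueError("need at least one unit per layer")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if self.activation != "relu" or self.optimizer != "rmsprop":
            raise ValueError("only relu activation and rmsprop optimizer are supported")


def full_grid() -> list[DLConfig]:
    """The reference 4 x 5 x 6 = 120-configuration hyperparameter grid."""
    return [
        DLConfig(n_hidden_layers=l, units_per_layer=u, dropout=d)
        for l, u, d in itertools.product(FULL_LAYERS, FULL_UNITS, FULL_DROPOUT)
    ]


@dataclass
class DLTuneResult:
    best: DLConfig
    grid_scores: dict = field(default_factory=dict)


def build_feature_matrix(X, records, env_order, model: str = "g") -> np.ndarray:
    """Feature rows aligned to (line, env) records.

    ``model='g'``: marker dosages only.  ``model='e-g-ge'``: markers
    concatenated with a one-hot environment block.
    """
    line_pos = {l: i for i, l in enumerate(X.line_ids)}
    rows = np.array([line_pos[l] for l, _ in records])
    F = X.X[rows]
    if model == "g":
        return F
    if model == "e-g-ge":
        env_pos = {e: j for j, e in enumerate(env_order)}
        onehot = np.zeros((len(records), len(env_order)))
        for i, (_, env) in enumerate(records):
            onehot[i, env_pos[env]] = 1.0
        return np.hstack([F, onehot])
    raise ValueError(f"unknown model {model!r}")


class _MLP:
    """Minimal ReLU multilayer perceptron with RMSprop and inverted dropout."""

    def __init__(self, n_in: int, cfg: DLConfig, rng: np.random.Generator):
        sizes = [n_in] + [cfg.units_per_layer] * cfg.n_hidden_layers + [1]
        self.W = [rng.normal(scale=np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.cfg = cfg
        self._cache_W = [np.zeros_like(w) for w in self.W]
        self._cache_b = [np.zeros_like(b) for b in self.b]

    def forward(self, X, rng=None):
        """Returns predictions and the per-layer activations/masks for backprop."""
        drop = self.cfg.dropout if rng is not None else 0.0
        a = X
        acts, masks = [X], []
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if li < len(self.W) - 1:
                a = np.maximum(z, 0.0)
                if drop > 0:
                    m = (rng.random(a.shape) >= drop) / (1.0 - drop)
                    a = a * m
                else:
                    m = None
                masks.append(m)
                acts.append(a)
            else:
                a = z
        return a[:, 0], acts, masks

    def train_batch(self, X, y, rng, lr=1e-3, rho=0.9, eps=1e-7):
        yhat, acts, masks = self.forward(X, rng=rng)
        B = X.shape[0]
        delta = (2.0 / B) * (yhat - y)[:, None]  # dMSE/dz_out
        for li in range(len(self.W) - 1, -1, -1):
            gW = acts[li].T @ delta
            gb = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                if masks[li - 1] is not None:
                    delta = delta * masks[li - 1]
                delta = delta * (acts[li] > 0)
            self._cache_W[li] = rho * self._cache_W[li] + (1 - rho) * gW**2
            self._cache_b[li] = rho * self._cache_b[li] + (1 - rho) * gb**2
            self.W[li] -= lr * gW / (np.sqrt(self._cache_W[li]) + eps)
            self.b[li] -= lr * gb / (np.sqrt(self._cache_b[li]) + eps)
        return float(np.mean((yhat - y) ** 2))


def fit_predict(train_features, train_y, test_features, cfg: DLConfig, seed: int = 0) -> np.ndarray:
    """Train the network on the full training set and predict the test rows.

    The response is centered during training (the offset is added back to the
    predictions).  Raises on non-finite loss, echoing the configuration.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    y = np.asarray(train_y, dtype=float).ravel()
    if not (np.isfinite(Xtr).all() and np.isfinite(Xte).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs to fit_predict")
    rng = np.random.default_rng(seed)
    net = _MLP(Xtr.shape[1], cfg, rng)
    offset = y.mean()
    yc = y - offset
    n = y.size
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = net.train_batch(Xtr[idx], yc[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss with config {cfg}")
    yhat, _, _ = net.forward(Xte)
    return yhat + offset


def tune_grid(train_features, train_y, grid=None, inner_folds: int = 5, seed: int = 0) -> DLTuneResult:
    """Grid search by inner k-fold cross-validation on the training data only.

    A configuration whose training diverges scores +inf.  Ties are broken
    toward fewer layers, then fewer units, then lower dropout.
    """
    grid = list(grid) if grid is not None else full_grid()
    if not grid:
        raise ValueError("empty grid")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_y, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(seed)
    fold_of = np.tile(np.arange(inner_folds), n // inner_folds + 1)[:n]
    rng.shuffle(fold_of)
    scores = {}
    for cfg in grid:
        errs = []
        for f in range(inner_folds):
            tr, te = fold_of != f, fold_of == f
            if te.sum() == 0 or tr.sum() == 0:
                continue
            try:
                pred = fit_predict(X[tr], y[tr], X[te], cfg, seed=seed + f)
                errs.append(float(np.mean((pred - y[te]) ** 2)))
            except (RuntimeError, FloatingPointError):
                errs.append(np.inf)
        scores[cfg] = float(np.mean(errs)) if errs else np.inf
    best = min(
        grid,
        key=lambda c: (scores[c], c.n_hidden_layers, c.units_per_layer, c.dropout),
    )
    return DLTuneResult(best=best, grid_scores=scores)
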