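"""Decision-tree-guided sparse multilayer perceptron.

An ensemble of shallow CART trees is fit first (bootstrap resamples,
sqrt(p) feature subsampling).  Each tree contributes one hidden unit that
connects *only* to the features appearing in that tree's split nodes; the
resulting binary connectivity mask constrains the input->hidden weight
matrix of a one-hidden-layer perceptron trained by Adam with ridge
regularization and early stopping (patience 10, best-epoch weights
restored).  Classification uses class-weighted cross-entropy with a
sigmoid output; regression uses squared error with a linear output.

Feature importance is the number of hidden units wired to each feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

TREE_GRID = (10, 20, 40, 60, 80, 100)
DEPTH_GRID = (4, 6, 8, 10)

DEFAULT_RIDGE = 1e-3
DEFAULT_LR = 1e-3
DEFAULT_MAX_EPOCHS = 500
DEFAULT_PATIENCE = 10


@dataclass
class TreeEnsembleSpec:
    """Ensemble hyperparameters plus, after fitting, per-tree used features."""

    n_trees: int
    depth: int
    seed: int = 0
    used_features: list[set[int]] | None = None  # filled by fit_tree_ensemble
    trees: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.depth < 1:
            raise ValueError("n_trees and depth must be positive")


def fit_tree_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    spec: TreeEnsembleSpec,
    task: str = "classification",
) -> TreeEnsembleSpec:
    """Fit ``spec.n_trees`` depth-limited CART trees on bootstrap resamples.

    Records, per tree, the set of feature indices used in split nodes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    if task == "classification" and np.unique(y).size < 2:
        raise ValueError("need at least two classes to fit the ensemble")
    rng = np.random.default_rng(spec.seed)
    n = X.shape[0]
    trees, used = [], []
    cls = DecisionTreeClassifier if task == "classification" else DecisionTreeRegressor
    for _ in range(spec.n_trees):
        while True:
            idx = rng.integers(0, n, size=n)
            if task != "classification" or np.unique(y[idx]).size >= 2:
                break
        tree = cls(
            max_depth=spec.depth,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        feats = tree.tree_.feature
        used.append({int(f) for f in feats if f >= 0})
        trees.append(tree)
    return replace(spec, used_features=used, trees=trees)


def build_mask(ensemble: TreeEnsembleSpec, n_features: int) -> np.ndarray:
    """Binary (n_trees x n_features) connectivity: row j = tree j's split features."""
    if ensemble.used_features is None:
        raise ValueError("ensemble is not fitted")
    mask = np.zeros((ensemble.n_trees, n_features), dtype=np.float64)
    for j, feats in enumerate(ensemble.used_features):
        for f in feats:
            if f >= n_features:
                raise ValueError(f"tree {j} uses feature {f} >= n_features={n_features}")
            mask[j, f] = 1.0
    return mask


@dataclass
class SparseMLPModel:
    """One sparse hidden layer (ReLU) + dense output (sigmoid or linear)."""

    mask: np.ndarray
    task: str = "classification"  # | "regression"
    ridge: float = DEFAULT_RIDGE
    lr: float = DEFAULT_LR
    max_epochs: int = DEFAULT_MAX_EPOCHS
    patience: int = DEFAULT_PATIENCE
    seed: int = 0
    # learned state
    W1: np.ndarray | None = None
    b1: np.ndarray | None = None
    W2: np.ndarray | None = None
    b2: float = 0.0
    class_weights: dict[int, float] | None = None
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    # regression target scaling (fit on train targets)
    y_mean: float = 0.0
    y_sd: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_hidden(self) -> int:
        return self.mask.shape[0]

    @property
    def n_features(self) -> int:
        return self.mask.shape[1]

    @property
    def n_parameters(self) -> int:
        """Trainable parameter count (masked weights excluded)."""
        return int(self.mask.sum()) + self.n_hidden + self.n_hidden + 1

    def _init_weights(self) -> None:
        rng = np.random.default_rng(self.seed)
        fan_in = np.maximum(self.mask.sum(axis=1), 1.0)
        self.W1 = rng.normal(0.0, 1.0, self.mask.shape) * self.mask
        self.W1 /= np.sqrt(fan_in)[:, None]
        self.b1 = np.zeros(self.n_hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(self.n_hidden), self.n_hidden)
        self.b2 = 0.0

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.maximum(X @ self.W1.T + self.b1, 0.0)
        z = h @ self.W2 + self.b2
        if self.task == "classification":
            return h, 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return h, z

    def _loss(self, X: np.ndarray, y: np.ndarray, sw: np.ndarray) -> float:
        _, p = self._forward(X)
        if self.task == "classification":
            eps = 1e-12
            ll = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            data = float(np.sum(sw * ll) / np.sum(sw))
        else:
            data = float(np.sum(sw * (p - y) ** 2) / np.sum(sw))
        penalty = self.ridge * (float((self.W1**2).sum()) + float((self.W2**2).sum()))
        return data + penalty


def _sample_weights(y: np.ndarray, class_weights: dict[int, float] | None) -> np.ndarray:
    if class_weights is None:
        return np.ones_like(y, dtype=np.float64)
    return np.array([class_weights[int(v)] for v in y], dtype=np.float64)


def compute_class_weights(y: np.ndarray) -> dict[int, float]:
    """w_c = n_samples / (n_classes * n_c) — inverse class frequency."""
    classes, counts = np.unique(y, return_counts=True)
    n, k = y.size, classes.size
    return {int(c): n / (k * cnt) for c, cnt in zip(classes, counts)}


def train(
    model: SparseMLPModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> tuple[SparseMLPModel, dict[str, list[float]]]:
    """Full-batch Adam on masked weights; early stop on validation loss.

    Inputs are assumed already normalized (z-scores from train parameters).
    Halts when the validation loss has not improved for ``patience``
    consecutive epochs and restores the best-epoch weights.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    if X_val.shape[0] == 0:
        raise ValueError("empty validation set")

    if model.task == "classification":
        model.class_weights = compute_class_weights(y_train.astype(int))
    else:
        # standardize regression targets so the linear output trains on a
        # unit scale; predictions are mapped back in predict()
        model.y_mean = float(y_train.mean())
        model.y_sd = float(y_train.std()) or 1.0
        y_train = (y_train - model.y_mean) / model.y_sd
        y_val = (y_val - model.y_mean) / model.y_sd
    sw_train = _sample_weights(y_train, model.class_weights)
    sw_val = _sample_weights(y_val, model.class_weights)

    model._init_weights()
    params = [model.W1, model.b1, model.W2, np.array([model.b2])]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state: tuple | None = None
    stale = 0

    n = X_train.shape[0]
    for epoch in range(1, model.max_epochs + 1):
        # forward
        h = np.maximum(X_train @ model.W1.T + model.b1, 0.0)
        z = h @ model.W2 + model.b2
        if model.task == "classification":
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            dz = sw_train * (p - y_train) / sw_train.sum()
        else:
            dz = sw_train * 2.0 * (z - y_train) / sw_train.sum()
        # backward
        gW2 = h.T @ dz + 2.0 * model.ridge * model.W2
        gb2 = np.array([dz.sum()])
        dh = np.outer(dz, model.W2) * (h > 0)
        gW1 = (dh.T @ X_train + 2.0 * model.ridge * model.W1) * model.mask
        gb1 = dh.sum(axis=0)

        grads = [gW1, gb1, gW2, gb2]
        for i, (p_arr, g) in enumerate(zip(params, grads)):
            m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
            v_t[i] = beta2 * v_t[i] + (1 - beta2) * g**2
            m_hat = m_t[i] / (1 - beta1**epoch)
            v_hat = v_t[i] / (1 - beta2**epoch)
            p_arr -= model.lr * m_hat / (np.sqrt(v_hat) + eps)
        model.W1 *= model.mask  # keep masked positions exactly zero
        model.b2 = float(params[3][0])

        train_loss = model._loss(X_train, y_train, sw_train)
        val_loss = model._loss(X_val, y_val, sw_val)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = (model.W1.copy(), model.b1.copy(), model.W2.copy(), model.b2)
            stale = 0
        else:
            stale += 1
            if stale >= model.patience:
                break

    if best_state is not None:
        model.W1, model.b1, model.W2, model.b2 = best_state
    return model, history


def predict(model: SparseMLPModel, X: np.ndarray) -> np.ndarray:
    """Scores in [0,1] (classification) or real predictions (regression).

    If the model carries normalization parameters, X is z-scored with them.
    """
    if model.W1 is None:
        raise ValueError("model is not trained")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, model expects {model.n_features}"
        )
    if model.norm_mean is not None:
        X = (X - model.norm_mean) / model.norm_sd
    out = model._forward(X)[1]
    if model.task == "regression":
        out = out * model.y_sd + model.y_mean
    return out


def feature_importance(model: SparseMLPModel) -> np.ndarray:
    """Per-feature connection counts (number of hidden units wired to it)."""
    return model.mask.astype(bool).sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def _holdout_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Stratified index split: (1-fraction) train / fraction validation."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        n_val = min(n_val, idx.size - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def fit_sparse_mlp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_trees: int,
    depth: int,
    task: str = "classification",
    seed: int = 0,
    **mlp_kwargs,
) -> SparseMLPModel:
    """Convenience: fit ensemble, build mask, train the sparse MLP."""
    spec = fit_tree_ensemble(X_train, y_train, TreeEnsembleSpec(n_trees, depth, seed), task)
    mask = build_mask(spec, X_train.shape[1])
    model = SparseMLPModel(mask=mask, task=task, seed=seed, **mlp_kwargs)
    model, _ = train(model, X_train, y_train, X_val, y_val)
    return model


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    tree_grid: Sequence[int] = TREE_GRID,
    depth_grid: Sequence[int] = DEPTH_GRID,
    task: str = "classification",
    seed: int = 0,
    val_fraction: float = 0.25,
) -> tuple[tuple[int, int], SparseMLPModel, float]:
    """Evaluate every (n_trees, depth) cell on an internal stratified
    validation split; return the argmax by validation AUC.

    Ties break toward fewer trees, then smaller depth.  Per-cell failures
    are recorded and skipped unless every cell fails.
    """
    from speechmark.evaluation import auc_roc  # local import avoids cycle

    if not tree_grid or not depth_grid:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    train_idx, val_idx = _holdout_split(y, val_fraction, rng)
    results: dict[tuple[int, int], tuple[SparseMLPModel, float]] = {}
    failures: dict[tuple[int, int], Exception] = {}
    for n_trees in sorted(tree_grid):
        for depth in sorted(depth_grid):
            try:
                model = fit_sparse_mlp(
                    X[train_idx], y[train_idx], X[val_idx], y[val_idx],
                    n_trees, depth, task=task, seed=seed,
                )
                scores = predict(model, X[val_idx])
                score, _ = auc_roc(scores, y[val_idx])
                results[(n_trees, depth)] = (model, score)
            except Exception as exc:  # recorded, not fatal
                failures[(n_trees, depth)] = exc
    if not results:
        raise RuntimeError(f"all grid cells failed: {failures}")
    best_cell = max(results, key=lambda c: (results[c][1], -c[0], -c[1]))
    best_model, best_score = results[best_cell]
    return best_cell, best_model, best_score


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: SparseMLPModel, path: str | Path) -> None:
    """Serialize to a single JSON file (schema-versioned, text-only)."""
    payload = {
        "schema": 1,
        "task": model.task,
        "ridge": model.ridge,
        "lr": model.lr,
        "max_epochs": model.max_epochs,
        "patience": model.patience,
        "seed": model.seed,
        "mask": model.mask.tolist(),
        "W1": None if model.W1 is None else model.W1.tolist(),
        "b1": None if model.b1 is None else model.b1.tolist(),
        "W2": None if model.W2 is None else model.W2.tolist(),
        "b2": model.b2,
        "class_weights": model.class_weights,
        "norm_mean": None if model.norm_mean is None else model.norm_mean.tolist(),
        "norm_sd": None if model.norm_sd is None else model.norm_sd.tolist(),
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SparseMLPModel:
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") != 1:
        raise ValueError(f"unsupported model schema {raw.get('schema')!r}")
    model = SparseMLPModel(
        mask=np.array(raw["mask"]),
        task=raw["task"],
        ridge=raw["ridge"],
        lr=raw["lr"],
        max_epochs=raw["max_epochs"],
        patience=raw["patience"],
        seed=raw["seed"],
    )
    for name in ("W1", "b1", "W2", "norm_mean", "norm_sd"):
        value = raw[name]
        setattr(model, name, None if value is None else np.array(value))
    model.b2 = raw["b2"]
    model.y_mean = raw.get("y_mean", 0.0)
    model.y_sd = raw.get("y_sd", 1.0)
    if raw["class_weights"] is not None:
        model.class_weights = {int(k): v for k, v in raw["class_weights"].items()}
    return model
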