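"""Feed-forward binary classifier for 5hmC site prediction.

A fully connected network mapping the (PCA-reduced) hybrid feature vector
to a single sigmoid output: p(5hmC | x). Layer l computes
``y = f(x W_l + b_l)`` with ReLU (or tanh) hidden activations. Defaults:

    hidden layers   64 -> 32 -> 16 -> 8
    dropout         0.4 on hidden activations (training only, inverted)
    L2 penalty      1e-4 on all weight matrices
    optimizer       Adam, learning rate 0.01
    init            He-uniform (U[-sqrt(6/fan_in), +sqrt(6/fan_in)]), zero bias
    loss            binary cross-entropy + L2 penalty
    epochs          700, mini-batches of 32, seed 1234

Implemented directly on NumPy: forward/backward passes are explicit, which
keeps training bit-reproducible for a fixed seed. An exhaustive grid
search over learning rate x hidden activation (the shape of the published
tuning experiment: 9 learning rates x {ReLU, Tanh}) scores each cell by
mean cross-validated accuracy through the full pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_pipeline import FeatureMatrix

__all__ = [
    "DnnConfig",
    "DnnModel",
    "train_dnn",
    "predict_proba",
    "classify",
    "grid_search",
    "default_grid",
    "select_best",
]

_ACTIVATIONS = ("relu", "tanh")


@dataclass(frozen=True)
class DnnConfig:
    """Hyper-parameters of the feed-forward classifier."""

    hidden_sizes: tuple[int, ...] = (64, 32, 16, 8)
    hidden_activation: str = "relu"
    dropout_rate: float = 0.4
    l2_lambda: float = 1e-4
    learning_rate: float = 0.01
    epochs: int = 700
    batch_size: int = 32
    seed: int = 1234

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty positive integers")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(
                f"hidden_activation must be one of {_ACTIVATIONS}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class DnnModel:
    """A trained network: per-layer weights/biases plus provenance."""

    config: DnnConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_names: tuple[str, ...] | None
    training_history: list[float]
    training_ids: tuple[str, ...] | None = None

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "training_history": self.training_history,
            "training_ids": list(self.training_ids) if self.training_ids else None,
        }
        Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(f"{prefix}.npz", **arrays)

    @classmethod
    def load(cls, prefix: str | Path) -> "DnnModel":
        meta = json.loads(Path(f"{prefix}.json").read_text())
        arrays = np.load(f"{prefix}.npz")
        n_layers = len([k for k in arrays.files if k.startswith("W")])
        return cls(
            config=DnnConfig(**meta["config"]),
            weights=[arrays[f"W{i}"] for i in range(n_layers)],
            biases=[arrays[f"b{i}"] for i in range(n_layers)],
            feature_names=tuple(meta["feature_names"]) if meta["feature_names"] else None,
            training_history=meta["training_history"],
            training_ids=tuple(meta["training_ids"]) if meta["training_ids"] else None,
        )


def _as_array(features) -> tuple[np.ndarray, tuple[str, ...] | None, list[str] | None]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.feature_names, list(features.ids)
    X = np.asarray(features, dtype=float)
    return X, None, None


def _hidden(act: str, z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) if act == "relu" else np.tanh(z)


def _hidden_grad(act: str, z: np.ndarray) -> np.ndarray:
    if act == "relu":
        return (z > 0).astype(float)
    th = np.tanh(z)
    return 1.0 - th * th


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _he_uniform_init(
    sizes: Sequence[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_dnn(features, labels, cfg: DnnConfig | None = None) -> DnnModel:
    """Train the network by mini-batch backpropagation.

    ``features`` is a :class:`FeatureMatrix` or a plain 2-D array; both
    classes must be present in ``labels``. Dropout masks, batch shuffling
    and weight initialisation all draw from one generator seeded with
    ``cfg.seed``, so a fixed (data, config) pair trains to identical
    weights. ``training_history`` records the mean per-epoch loss
    (cross-entropy plus L2 penalty).
    """
    cfg = cfg or DnnConfig()
    X, names, ids = _as_array(features)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError(f"features {X.shape} do not align with {len(y)} labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all() or len(uniq) < 2:
        raise ValueError("labels must contain both classes (0 and 1)")

    rng = np.random.default_rng(cfg.seed)
    sizes = [X.shape[1], *cfg.hidden_sizes, 1]
    weights, biases = _he_uniform_init(sizes, rng)
    n_hidden = len(cfg.hidden_sizes)
    lam = cfg.l2_lambda
    keep = 1.0 - cfg.dropout_rate

    # Adam state
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    n = X.shape[0]
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = X[batch], y[batch]
            m = len(batch)

            # forward with inverted dropout on hidden activations
            acts = [xb]
            zs = []
            masks = []
            a = xb
            for i in range(n_hidden):
                z = a @ weights[i] + biases[i]
                a = _hidden(cfg.hidden_activation, z)
                if cfg.dropout_rate > 0:
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                else:
                    mask = None
                zs.append(z)
                masks.append(mask)
                acts.append(a)
            z_out = a @ weights[-1] + biases[-1]
            p = _sigmoid(z_out).ravel()

            p_clip = np.clip(p, 1e-12, 1.0 - 1e-12)
            bce = -np.mean(yb * np.log(p_clip) + (1 - yb) * np.log(1 - p_clip))
            l2 = lam * sum(float(np.sum(W * W)) for W in weights)
            epoch_loss += bce + l2
            n_batches += 1

            # backward: sigmoid + BCE collapse to (p - y)
            delta = ((p - yb) / m)[:, None]
            gW = [None] * len(weights)
            gb = [None] * len(biases)
            gW[-1] = acts[-1].T @ delta + 2 * lam * weights[-1]
            gb[-1] = delta.sum(axis=0)
            d = delta @ weights[-1].T
            for i in range(n_hidden - 1, -1, -1):
                if masks[i] is not None:
                    d = d * masks[i]
                d = d * _hidden_grad(cfg.hidden_activation, zs[i])
                gW[i] = acts[i].T @ d + 2 * lam * weights[i]
                gb[i] = d.sum(axis=0)
                if i > 0:
                    d = d @ weights[i].T

            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for i in range(len(weights)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                biases[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
        history.append(epoch_loss / n_batches)

    return DnnModel(
        config=cfg,
        weights=weights,
        biases=biases,
        feature_names=names,
        training_history=history,
        training_ids=tuple(ids) if ids else None,
    )


def predict_proba(model: DnnModel, features) -> np.ndarray:
    """Sigmoid output per row, dropout disabled. If both the model and the
    input carry feature names they must match exactly."""
    X, names, _ = _as_array(features)
    if (
        names is not None
        and model.feature_names is not None
        and names != model.feature_names
    ):
        diff = set(names) ^ set(model.feature_names)
        raise ValueError(f"feature schema mismatch: {sorted(diff)[:10]}")
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects "
            f"{model.weights[0].shape[0]}"
        )
    a = X
    act = model.config.hidden_activation
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = _hidden(act, a @ W + b)
    return _sigmoid(a @ model.weights[-1] + model.biases[-1]).ravel()


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Binary call: 1 iff p >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def default_grid() -> dict[str, list]:
    """The published tuning grid shape: 9 learning rates x 2 hidden
    activations (18 cells)."""
    return {
        "learning_rate": [0.008, 0.009, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07],
        "hidden_activation": ["relu", "tanh"],
    }


def select_best(table: pd.DataFrame, grid: Mapping[str, Sequence] | None = None) -> dict:
    """Argmax row of a grid-search result table by ``mean_accuracy``.

    Ties break toward the lower learning rate, then the first-listed
    activation in the grid (grid order; defaults to the table's row order
    for other parameters). Failed cells (NaN accuracy) never win.
    """
    ok = table.dropna(subset=["mean_accuracy"])
    if ok.empty:
        raise ValueError("every grid cell failed; nothing to select")
    best_acc = ok["mean_accuracy"].max()
    tied = ok[ok["mean_accuracy"] == best_acc]
    if "learning_rate" in tied.columns:
        tied = tied[tied["learning_rate"] == tied["learning_rate"].min()]
    if grid and "hidden_activation" in tied.columns and "hidden_activation" in grid:
        order = {a: i for i, a in enumerate(grid["hidden_activation"])}
        tied = tied.loc[
            tied["hidden_activation"].map(order).sort_values(kind="stable").index
        ]
    row = tied.iloc[0]
    return {k: row[k] for k in table.columns if k not in ("mean_accuracy", "error")}


def grid_search(
    data,
    grid: Mapping[str, Sequence] | None = None,
    cv_folds: int = 5,
    seed: int = 1234,
    base_cfg: DnnConfig | None = None,
    encoder_cfg=None,
    use_pca: bool = True,
    n_components: int = 75,
) -> tuple[DnnConfig, pd.DataFrame]:
    """Exhaustive hyper-parameter search scored by mean CV accuracy.

    Every combination in the Cartesian product of ``grid`` (parameter name
    -> candidate values, fields of :class:`DnnConfig`) is evaluated by
    stratified K-fold cross-validation through the full pipeline (encode,
    PCA per fold, train, evaluate). Invalid combinations are recorded as
    failed cells, not fatal. Returns the winning config (documented
    tie-break: lower learning rate, then first-listed activation) and the
    full result table.
    """
    from .evaluation import run_cv  # deferred: evaluation imports this module

    grid = dict(grid) if grid else default_grid()
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty with non-empty candidate lists")
    base_cfg = base_cfg or DnnConfig()
    keys = list(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        row = dict(params)
        try:
            cfg = replace(base_cfg, **params)
            result = run_cv(
                data,
                encoder_cfg=encoder_cfg,
                use_pca=use_pca,
                n_components=n_components,
                model_cfg=cfg,
                folds=cv_folds,
                seed=seed,
            )
            row["mean_accuracy"] = result.mean.accuracy
            row["error"] = ""
        except (ValueError, ArithmeticError) as e:
            row["mean_accuracy"] = np.nan
            row["error"] = str(e)
            warnings.warn(f"grid cell {params} failed: {e}", stacklevel=2)
        rows.append(row)
    table = pd.DataFrame(rows)
    best_params = select_best(table, grid)
    best_cfg = replace(base_cfg, **best_params)
    return best_cfg, table
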