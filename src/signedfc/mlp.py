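"""Regularized two-hidden-layer perceptron for ASD/HC classification.

Architecture: input → 512 ReLU (L1-penalized weights, to give the network
feature-selection pressure) → dropout → 512 ReLU (L2-penalized) → dropout
→ 1 sigmoid.  Trained with minibatch Adam on binary cross-entropy, with a
validation-loss-driven learning-rate decay.  The label convention is
HC = 1, ASD = 0, so sensitivity downstream reads as the fraction of
healthy controls identified.

Implemented directly in NumPy (forward pass, backprop and Adam are a few
dense matrix products at this scale), which keeps training bitwise
reproducible for a given seed and platform.

Note the Adam moment-decay defaults ``beta1 = 0.99, beta2 = 0.01``: the
second-moment memory is deliberately short.  ``conventional_betas=True``
restores the textbook (0.9, 0.999) pair for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MlpConfig", "TrainedModel", "train", "predict_proba", "save_model", "load_model"]


@dataclass
class MlpConfig:
    """Hyperparameters of the regularized MLP."""

    hidden_units: int = 512
    l1_strength: float = 1e-3
    l2_strength: float = 1e-2
    dropout_rate: float = 0.7
    adam_beta1: float = 0.99
    adam_beta2: float = 0.01
    conventional_betas: bool = False
    learning_rate: float = 2e-4
    lr_decay_factor: float = 0.5
    validation_fraction: float = 0.10
    max_epochs: int = 200
    batch_size: int = 32
    patience: int = 5
    min_improvement: float = 1e-4
    max_decays: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        for b in (self.adam_beta1, self.adam_beta2):
            if not 0 < b < 1:
                raise ValueError("Adam betas must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l1_strength < 0 or self.l2_strength < 0:
            raise ValueError("regularization strengths must be non-negative")

    @property
    def betas(self) -> tuple[float, float]:
        if self.conventional_betas:
            return 0.9, 0.999
        return self.adam_beta1, self.adam_beta2


@dataclass
class TrainedModel:
    """Weights, biases and training history of a fitted MLP."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray
    history: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    h1 = np.maximum(x @ model.w1 + model.b1, 0.0)
    h2 = np.maximum(h1 @ model.w2 + model.b2, 0.0)
    return _sigmoid(h2 @ model.w3 + model.b3).ravel()


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified validation split; every class keeps >= 1 training row."""
    val_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        n_val = int(round(fraction * len(members)))
        n_val = min(n_val, len(members) - 1)
        val_idx.extend(members[:n_val].tolist())
    val = np.sort(np.asarray(val_idx, dtype=int))
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def train(features, labels, cfg: MlpConfig) -> TrainedModel:
    """Fit the MLP on standardized features.

    Minimizes BCE + l1·‖W1‖₁ + l2·‖W2‖₂² with dropout after each hidden
    layer.  A random class-stratified ``validation_fraction`` of the
    training subjects monitors the loss: no improvement beyond
    ``min_improvement`` for ``patience`` epochs halves the learning rate
    (``lr_decay_factor``); after ``max_decays`` decays without improvement
    training stops and the best-validation weights are restored.
    Deterministic given ``cfg.seed``.
    """
    x = np.asarray(getattr(features, "values", features), dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features and labels are misaligned")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(cfg.seed)
    d, h = x.shape[1], cfg.hidden_units
    # He initialization for the ReLU layers
    model = TrainedModel(
        w1=rng.standard_normal((d, h)) * np.sqrt(2.0 / d),
        b1=np.zeros(h),
        w2=rng.standard_normal((h, h)) * np.sqrt(2.0 / h),
        b2=np.zeros(h),
        w3=rng.standard_normal((h, 1)) * np.sqrt(2.0 / h),
        b3=np.zeros(1),
    )
    params = ["w1", "b1", "w2", "b2", "w3", "b3"]
    m = {p: np.zeros_like(getattr(model, p)) for p in params}
    v = {p: np.zeros_like(getattr(model, p)) for p in params}
    beta1, beta2 = cfg.betas

    tr_idx, val_idx = _stratified_split(y, cfg.validation_fraction, rng)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    lr = cfg.learning_rate
    keep = 1.0 - cfg.dropout_rate
    best_val = np.inf
    best_weights = {p: getattr(model, p).copy() for p in params}
    epochs_since_improve = 0
    decays_without_improve = 0
    step = 0
    history = {"train_loss": [], "val_loss": [], "lr": []}

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            nb = len(batch)

            # forward with inverted dropout
            z1 = xb @ model.w1 + model.b1
            h1 = np.maximum(z1, 0.0)
            mask1 = (rng.random(h1.shape) < keep) / keep if keep < 1 else 1.0
            h1d = h1 * mask1
            z2 = h1d @ model.w2 + model.b2
            h2 = np.maximum(z2, 0.0)
            mask2 = (rng.random(h2.shape) < keep) / keep if keep < 1 else 1.0
            h2d = h2 * mask2
            p = _sigmoid(h2d @ model.w3 + model.b3).ravel()

            epoch_loss += _bce(p, yb) * nb

            # backprop; d(BCE)/d(logit) = (p - y) / n
            dz3 = ((p - yb) / nb)[:, None]
            g = {
                "w3": h2d.T @ dz3,
                "b3": dz3.sum(axis=0),
            }
            dh2d = dz3 @ model.w3.T
            dz2 = dh2d * mask2 * (z2 > 0)
            g["w2"] = h1d.T @ dz2 + 2.0 * cfg.l2_strength * model.w2
            g["b2"] = dz2.sum(axis=0)
            dh1d = dz2 @ model.w2.T
            dz1 = dh1d * mask1 * (z1 > 0)
            g["w1"] = xb.T @ dz1 + cfg.l1_strength * np.sign(model.w1)
            g["b1"] = dz1.sum(axis=0)

            step += 1
            for pname in params:
                m[pname] = beta1 * m[pname] + (1 - beta1) * g[pname]
                v[pname] = beta2 * v[pname] + (1 - beta2) * g[pname] ** 2
                m_hat = m[pname] / (1 - beta1**step)
                v_hat = v[pname] / (1 - beta2**step)
                setattr(
                    model,
                    pname,
                    getattr(model, pname) - lr * m_hat / (np.sqrt(v_hat) + 1e-8),
                )

        val_loss = _bce(_forward(model, x_val), y_val)
        history["train_loss"].append(epoch_loss / len(x_tr))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)

        if val_loss < best_val - cfg.min_improvement:
            best_val = val_loss
            best_weights = {p: getattr(model, p).copy() for p in params}
            epochs_since_improve = 0
            decays_without_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve >= cfg.patience:
                lr *= cfg.lr_decay_factor
                epochs_since_improve = 0
                decays_without_improve += 1
                if decays_without_improve >= cfg.max_decays:
                    break

    for pname in params:
        setattr(model, pname, best_weights[pname])
    model.history = history
    return model


def predict_proba(model: TrainedModel, features) -> np.ndarray:
    """Per-subject probability of the HC (label 1) class; dropout disabled."""
    x = np.asarray(getattr(features, "values", features), dtype=float)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {x.shape[1] if x.ndim == 2 else 'n/a'} does not "
            f"match the model's input dimension {model.input_dim}"
        )
    return _forward(model, x)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a single ``.npz`` checkpoint."""
    np.savez(
        path,
        w1=model.w1, b1=model.b1, w2=model.w2, b2=model.b2,
        w3=model.w3, b3=model.b3,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as z:
        return TrainedModel(
            w1=z["w1"], b1=z["b1"], w2=z["w2"], b2=z["b2"], w3=z["w3"], b3=z["b3"]
        )
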