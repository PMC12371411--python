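"""Training loop: Adam on binary cross-entropy with the accuracy-then-loss
checkpoint rule and early stopping.

The checkpoint rule saves the model whenever validation accuracy strictly
improves; when accuracy is unchanged relative to the best checkpoint, it
saves if validation loss has decreased relative to that checkpoint. The
returned weights are the checkpointed, not final, weights. Early stopping
monitors validation loss by default with patience 40.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ..io import NEGATIVE, POSITIVE
from .model import CNN3D, CNNConfig, build_cnn


@dataclasses.dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 200
    early_stopping_patience: int = 40
    monitor: str = "val_loss"            # early-stopping monitor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")

    @staticmethod
    def desk_scale(seed: int = 0, max_epochs: int = 15) -> "TrainingConfig":
        return TrainingConfig(learning_rate=1e-3, batch_size=4,
                              max_epochs=max_epochs, seed=seed)


@dataclasses.dataclass
class TrainedModelBundle:
    weights: list[np.ndarray]
    cnn_config: CNNConfig
    training_config: TrainingConfig
    history: dict[str, list[float]]
    checkpoint_epoch: int                # 1-based; epoch whose weights are kept
    model_seed: int = 0


class CheckpointRule:
    """Accuracy-then-loss model checkpointing.

    ``update`` returns True when the model should be saved: validation
    accuracy strictly above the best so far, or equal to the best with
    validation loss strictly below the loss recorded at the best checkpoint.
    """

    def __init__(self) -> None:
        self.best_accuracy = -np.inf
        self.loss_at_best = np.inf

    def update(self, val_accuracy: float, val_loss: float) -> bool:
        if val_accuracy > self.best_accuracy:
            self.best_accuracy = val_accuracy
            self.loss_at_best = val_loss
            return True
        if val_accuracy == self.best_accuracy and val_loss < self.loss_at_best:
            self.loss_at_best = val_loss
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without strict improvement
    of the monitored quantity (mode 'min' for losses, 'max' for scores)."""

    def __init__(self, patience: int, mode: str = "min"):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.patience = patience
        self.mode = mode
        self.best = np.inf if mode == "min" else -np.inf
        self.wait = 0

    def update(self, value: float) -> bool:
        improved = value < self.best if self.mode == "min" else value > self.best
        if improved:
            self.best = value
            self.wait = 0
        else:
            self.wait += 1
        return self.wait >= self.patience


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def binary_cross_entropy(p: np.ndarray, t: np.ndarray,
                         eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean BCE loss and its gradient with respect to the probabilities."""
    p = np.clip(np.asarray(p, np.float64), eps, 1 - eps)
    t = np.asarray(t, np.float64)
    loss = float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    grad = (p - t) / (p * (1 - p)) / len(p)
    return loss, grad


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    x, y = dataset
    return np.asarray(x, np.float32), np.asarray(y, np.float64).ravel()


def train(model: CNN3D, train_set, val_set,
          tc: TrainingConfig | None = None) -> TrainedModelBundle:
    """Train a built model; returns the checkpointed weights and history.

    ``train_set``/``val_set`` are (volumes, labels) pairs with volumes of
    shape (N, D, H, W) or (N, 1, D, H, W) and labels in {0, 1}. Raises on a
    single-class training set and aborts with diagnostics if the loss goes
    non-finite.
    """
    tc = tc or TrainingConfig()
    xtr, ytr = _as_xy(train_set)
    xva, yva = _as_xy(val_set)
    if len(xtr) == 0 or len(xva) == 0:
        raise ValueError("training and validation sets must be nonempty")
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.trainable_params(), lr=tc.learning_rate)
    checkpoint = CheckpointRule()
    stopper = EarlyStopping(tc.early_stopping_patience,
                            mode="min" if "loss" in tc.monitor else "max")
    best_weights = model.get_weights()
    checkpoint_epoch = 0
    history: dict[str, list[float]] = {k: [] for k in
                                       ("loss", "accuracy", "val_loss", "val_accuracy")}
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(len(xtr))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            probs = model.forward(xtr[idx], training=True)
            loss, grad = binary_cross_entropy(probs, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(probs range [{probs.min():.3g}, {probs.max():.3g}])")
            model.backward(grad)
            opt.step(model.grads())
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum((probs >= 0.5) == (ytr[idx] == 1)))
        val_probs = model.forward(xva, training=False)
        val_loss, _ = binary_cross_entropy(val_probs, yva)
        val_acc = float(np.mean((val_probs >= 0.5) == (yva == 1)))
        history["loss"].append(ep_loss / len(xtr))
        history["accuracy"].append(ep_correct / len(xtr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if checkpoint.update(val_acc, val_loss):
            best_weights = model.get_weights()
            checkpoint_epoch = epoch
        monitored = val_loss if "loss" in tc.monitor else val_acc
        if stopper.update(monitored):
            break
    model.set_weights(best_weights)
    return TrainedModelBundle(weights=best_weights, cnn_config=model.config,
                              training_config=tc, history=history,
                              checkpoint_epoch=checkpoint_epoch)


def predict(bundle: TrainedModelBundle, volumes: np.ndarray,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and labels for a batch of volumes.

    Deterministic (dropout disabled); probability exactly at the threshold
    maps to the positive label — in a screening context ties favor
    sensitivity.
    """
    model = build_cnn(bundle.cnn_config, seed=bundle.model_seed)
    model.set_weights(bundle.weights)
    x = np.asarray(volumes, np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim == 4:
        x = x[:, None]
    if x.shape[2:] != bundle.cnn_config.input_shape:
        raise ValueError(f"volume shape {x.shape[2:]} != model input "
                         f"{bundle.cnn_config.input_shape}")
    probs = model.forward(x, training=False)
    labels = np.where(probs >= threshold, POSITIVE, NEGATIVE)
    return probs, labels


def majority_vote(label_matrix: np.ndarray | Sequence[Sequence[str]]) -> np.ndarray:
    """Ensemble label per scan from a (models x scans) label matrix; exact
    ties go to the positive class."""
    arr = np.asarray(label_matrix)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("label matrix must be 2D with >= 1 model row")
    pos = (arr == POSITIVE) if arr.dtype.kind in "SU" else (arr.astype(int) == 1)
    n_models = arr.shape[0]
    return np.where(pos.sum(axis=0) * 2 >= n_models, POSITIVE, NEGATIVE)


def save_bundle(bundle: TrainedModelBundle, model_dir: str | Path) -> None:
    """Persist weights (npz) plus a JSON sidecar of configs and history."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    np.savez(model_dir / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(bundle.weights)})
    sidecar = {
        "cnn_config": dataclasses.asdict(bundle.cnn_config),
        "training_config": dataclasses.asdict(bundle.training_config),
        "history": bundle.history,
        "checkpoint_epoch": bundle.checkpoint_epoch,
        "model_seed": bundle.model_seed,
    }
    (model_dir / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_bundle(model_dir: str | Path) -> TrainedModelBundle:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    npz = np.load(model_dir / "weights.npz")
    weights = [npz[f"w{i}"] for i in range(len(npz.files))]
    cc = sidecar["cnn_config"]
    for key in ("input_shape", "conv_filters", "kernel", "pool_size"):
        cc[key] = tuple(cc[key])
    return TrainedModelBundle(
        weights=weights,
        cnn_config=CNNConfig(**cc),
        training_config=TrainingConfig(**sidecar["training_config"]),
        history=sidecar["history"],
        checkpoint_epoch=sidecar["checkpoint_epoch"],
        model_seed=sidecar.get("model_seed", 0),
    )
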