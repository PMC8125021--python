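"""Momentum-SGD training of a stream classifier on encoded clips."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..topology import DagMatrices
from .layers import DTYPE, BatchNorm, cross_entropy
from .network import ModelConfig, TwoTowerClassifier


def recalibrate_batchnorm(
    model: TwoTowerClassifier, X: np.ndarray, batch_size: int = 32
) -> None:
    """Set batch-norm running statistics to the exact average of the batch
    statistics over ``X`` (one forward pass, no parameter updates).

    With few optimizer steps per epoch the exponentially-averaged running
    statistics lag far behind the trained parameters; recomputing them
    directly makes evaluation-mode behaviour track the current parameters.
    """
    bns = [l for l in model.layers() if isinstance(l, BatchNorm)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    for nb, start in enumerate(range(0, len(X), batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (nb + 1)  # cumulative moving average
        model.forward(X[start : start + batch_size], train=True)
    for bn, mom in zip(bns, saved):
        bn.momentum = mom


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainResult:
    model: TwoTowerClassifier
    history: list[dict]  # per-epoch: epoch, loss, train_acc, val_acc, lr
    best_state: dict | None = None


class MomentumSGD:
    """Classic momentum: ``v <- mu v - lr g``, ``p <- p + v``."""

    def __init__(self, layers, lr: float, momentum: float):
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in layers
        ]

    def step(self) -> None:
        for l, vel in zip(self.layers, self.velocity):
            for k, p in l.params.items():
                v = vel[k]
                v *= self.momentum
                v -= self.lr * l.grads[k]
                p += v


def train_stream(
    X: np.ndarray,
    y: np.ndarray,
    dag: DagMatrices,
    config: ModelConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Train one stream's classifier with momentum SGD and cross-entropy.

    ``X`` is (N, rows, 18, 3) encoded stream tensors, ``y`` integer labels.
    When a validation set is given, the parameters with the best validation
    accuracy are kept and restored at the end (epoch checkpointing).
    Batches are shuffled with a generator seeded from ``config.seed``, so a
    fixed seed reproduces the loss trace exactly on one device.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    X = np.ascontiguousarray(X, dtype=DTYPE)

    model = TwoTowerClassifier(config, dag)
    opt = MomentumSGD(model.layers(), config.learning_rate, config.momentum)
    rng = np.random.default_rng(config.seed + 1)

    history: list[dict] = []
    best_acc, best_state = -1.0, None
    n = len(X)
    for epoch in range(config.epochs):
        if epoch > 0 and config.lr_step and epoch % config.lr_step == 0:
            opt.lr *= config.lr_decay
        order = rng.permutation(n)
        total_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, gl = cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became {loss} at epoch {epoch}"
                )
            model.backward(gl)
            opt.step()
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        rec = {
            "epoch": epoch,
            "loss": total_loss / n,
            "train_acc": correct / n,
            "lr": opt.lr,
        }
        if X_val is not None:
            recalibrate_batchnorm(model, X, config.batch_size)
            val_pred = model.predict(X_val, config.batch_size)
            rec["val_acc"] = float((val_pred == y_val).mean())
            if rec["val_acc"] > best_acc:
                best_acc = rec["val_acc"]
                best_state = model.state_dict()
        history.append(rec)
        if verbose:
            print(
                "epoch {epoch}: loss {loss:.4f} train_acc {train_acc:.3f}".format(**rec)
                + (f" val_acc {rec['val_acc']:.3f}" if "val_acc" in rec else "")
            )

    if best_state is not None:
        model.load_state_dict(best_state)
    else:
        recalibrate_batchnorm(model, X, config.batch_size)
    return TrainResult(model, history, best_state)
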