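"""Training loops for the two pipeline stages.

Stage 1 (region localization) trains with Adam at 1e-3; stage 2 (boundary
prediction) with SGD-momentum at 1e-2.  Both use per-pixel cross-entropy,
shuffle the training data each epoch, optionally augment on the fly, and keep
the parameters of the epoch with the best validation accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import AugmentConfig, augment_pair
from .layers import cross_entropy, softmax
from .unet import UNet, UNetConfig, build_unet

__all__ = ["TrainConfig", "TrainedModel", "train", "predict_map", "save_model", "load_model"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # "adam" | "sgd_momentum"
    learning_rate: float = 1e-3
    momentum: float = 0.9
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd_momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")

    @classmethod
    def stage1(cls, **overrides) -> "TrainConfig":
        """Global-network recipe: Adam, lr 1e-3, 100 epochs, batch 128."""
        base = dict(optimizer="adam", learning_rate=1e-3, epochs=100, batch_size=128)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def stage2(cls, **overrides) -> "TrainConfig":
        """Local-network recipe: SGD momentum 0.9, lr 1e-2, 500 epochs, batch 128."""
        base = dict(optimizer="sgd_momentum", learning_rate=1e-2, epochs=500, batch_size=128)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainedModel:
    model: UNet
    train_config: TrainConfig
    log: list[dict] = field(default_factory=list)
    fold: int | None = None
    best_epoch: int = -1


class _Adam:
    def __init__(self, items, lr: float):
        self.items = list(items)
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in self.items]
        self.v = [np.zeros_like(p) for _, p, _ in self.items]

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for (name, p, g), m, v in zip(self.items, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class _SGDMomentum:
    def __init__(self, items, lr: float, momentum: float):
        self.items = list(items)
        self.lr = lr
        self.mu = momentum
        self.vel = [np.zeros_like(p) for _, p, _ in self.items]

    def step(self) -> None:
        for (name, p, g), v in zip(self.items, self.vel):
            v *= self.mu
            v -= self.lr * g
            p += v


def _evaluate(model: UNet, images: np.ndarray, targets: np.ndarray, batch: int) -> tuple[float, float]:
    """Mean loss and per-pixel accuracy over a dataset, in inference mode."""
    losses, correct, total = [], 0, 0
    for i in range(0, len(images), batch):
        x = images[i : i + batch][..., None].astype(np.float32)
        y = targets[i : i + batch].astype(np.int64)
        logits = model.forward(x, train=False)
        loss, _ = cross_entropy(logits, y)
        losses.append(loss * len(x))
        pred = logits.argmax(axis=-1)
        correct += int((pred == y).sum())
        total += y.size
    return float(np.sum(losses) / len(images)), correct / total


def train(
    model: UNet,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    augment: AugmentConfig | None = None,
    fold: int | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train a U-Net and return the checkpoint with the best validation accuracy.

    ``train_set`` / ``val_set`` are ``(images, targets)`` with images of shape
    (N, H, W) and integer class targets of the same shape.  Fully seeded: two
    runs with the same config and data produce identical trajectories on one
    device.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    if len(x_val) == 0:
        raise ValueError("validation set is empty: the best-validation checkpoint rule is undefined")
    if x_train.shape[1:] != y_train.shape[1:]:
        raise ValueError("images and targets must be congruent")

    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "adam":
        opt = _Adam(model.param_items(), cfg.learning_rate)
    else:
        opt = _SGDMomentum(model.param_items(), cfg.learning_rate, cfg.momentum)

    log: list[dict] = []
    # checkpoint key: highest validation accuracy, ties broken by lowest
    # validation loss (under heavy class imbalance the accuracy can plateau
    # at the majority-class baseline while the loss still improves)
    best_key, best_epoch, best_state = (-1.0, -np.inf), -1, None
    eval_batch = min(cfg.batch_size, 8)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb = x_train[sel].astype(np.float32)
            yb = y_train[sel].astype(np.int64)
            if augment is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(sel)):
                    img, msk = augment_pair(xb[j], yb[j], augment, rng=rng)
                    xb[j] = img
                    yb[j] = np.asarray(msk, np.int64)
            logits = model.forward(xb[..., None], train=True, rng=rng)
            loss, dlogits = cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
            n_seen += len(sel)
        val_loss, val_acc = _evaluate(model, x_val, y_val, eval_batch)
        row = {
            "epoch": epoch,
            "train_loss": epoch_loss / n_seen,
            "val_loss": val_loss,
            "val_acc": val_acc,
        }
        log.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d}  train_loss {row['train_loss']:.4f}  "
                f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}"
            )
        key = (val_acc, -val_loss)
        if key > best_key:
            best_key, best_epoch = key, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return TrainedModel(model=model, train_config=cfg, log=log, fold=fold, best_epoch=best_epoch)


def predict_map(model: UNet | TrainedModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel positive-class probability map in [0, 1] for one image.

    The two class scores are softmax-normalized, so they sum to one at every
    pixel; the returned map is the probability of the foreground class
    (region for stage 1, boundary for stage 2).
    """
    net = model.model if isinstance(model, TrainedModel) else model
    image = np.asarray(image, np.float32)
    if image.ndim != 2:
        raise ValueError("predict_map expects a single 2-D image")
    net.check_input_shape(image.shape)
    logits = net.forward(image[None, ..., None], train=False)
    return softmax(logits, axis=-1)[0, ..., 1].astype(np.float64)


def save_model(tm: TrainedModel, path: str | Path) -> None:
    """Persist architecture config, parameters and training log to an .npz."""
    net = tm.model
    meta = {
        "unet": vars(net.cfg) if not hasattr(net.cfg, "__dataclass_fields__") else
        {f: getattr(net.cfg, f) for f in net.cfg.__dataclass_fields__},
        "train": {f: getattr(tm.train_config, f) for f in tm.train_config.__dataclass_fields__},
        "fold": tm.fold,
        "best_epoch": tm.best_epoch,
        "log": tm.log,
    }
    arrays = dict(net.state_items())
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net = build_unet(UNetConfig(**meta["unet"]))
    net.load_state_dict(state)
    return TrainedModel(
        model=net,
        train_config=TrainConfig(**meta["train"]),
        log=meta["log"],
        fold=meta["fold"],
        best_epoch=meta["best_epoch"],
    )
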