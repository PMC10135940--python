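"""Training protocol: Huber-loss SGD with cosine annealing and 7:1:2 splits.

Defaults mirror the reference training protocol (batch 1024, initial
learning rate 0.001, 120 epochs, Huber delta = 1 on mmHg-scale labels,
SGD with cosine-annealing decay, segment-level 7:1:2 split).  Note that
with labels in mmHg and delta = 1 the Huber loss is almost everywhere in
its linear (MAE-like) regime, which bounds per-sample gradients; small
desk-scale runs therefore want a larger learning rate and smaller batch
(see :class:`ppgbp.estimator.MSAResNetRegressor`'s small-model defaults).

Targets are kept in mmHg throughout; the split can alternatively be done
at the record level so that all segments of a subject land in a single
partition (segment-level splitting leaks subjects across partitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MSAResNet
from .nn.losses import loss_and_grad, mae_loss
from .nn.optim import SGD, cosine_lr
from .preprocess import ModelInput

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "split_dataset",
    "inputs_to_arrays",
    "train",
]


@dataclass
class TrainConfig:
    delta: float = 1.0
    batch_size: int = 1024
    epochs: int = 120
    lr0: float = 0.001
    eta_min: float = 0.0
    momentum: float = 0.9
    weight_decay: float = 0.0
    loss: str = "huber"
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    split_unit: str = "segment"
    seed: int = 0

    def validate(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if any(f < 0 for f in self.split):
            raise ValueError("split fractions must be non-negative")
        if self.split_unit not in ("segment", "record"):
            raise ValueError(
                f"split_unit must be 'segment' or 'record', got {self.split_unit!r}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch training trace plus the data partition used."""

    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_mae_sbp: list[float] = field(default_factory=list)
    val_mae_dbp: list[float] = field(default_factory=list)
    best_epoch: int = -1
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.epoch)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "lr": self.lr,
                "train_loss": self.train_loss,
                "val_mae_sbp": self.val_mae_sbp,
                "val_mae_dbp": self.val_mae_dbp,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def split_dataset(
    n: int | Sequence,
    cfg: TrainConfig,
    record_ids: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index sets.

    ``n`` is the number of segments (or any sequence of that length).
    Sizes are ``floor(f_train n)`` / ``floor(f_val n)`` / remainder after a
    seeded shuffle.  With ``split_unit='record'`` (requires ``record_ids``)
    whole records are assigned to partitions by the same fractions over
    records, so no record spans two partitions.
    """
    cfg.validate()
    if not isinstance(n, (int, np.integer)):
        n = len(n)
    n = int(n)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    rng = np.random.default_rng(cfg.seed)
    f_tr, f_val, f_te = cfg.split
    if cfg.split_unit == "record":
        if record_ids is None:
            raise ValueError("record-unit split requires record_ids")
        record_ids = np.asarray(record_ids)
        if len(record_ids) != n:
            raise ValueError("record_ids length must match n")
        uniq = np.unique(record_ids)
        order = rng.permutation(len(uniq))
        shuffled = uniq[order]
        r_tr = int(np.floor(f_tr * len(uniq)))
        r_val = int(np.floor(f_val * len(uniq)))
        tr_rec = set(shuffled[:r_tr].tolist())
        val_rec = set(shuffled[r_tr : r_tr + r_val].tolist())
        idx = np.arange(n)
        train = idx[[r in tr_rec for r in record_ids]]
        val = idx[[r in val_rec for r in record_ids]]
        test = idx[
            [(r not in tr_rec and r not in val_rec) for r in record_ids]
        ]
    else:
        perm = rng.permutation(n)
        n_tr = int(np.floor(f_tr * n))
        n_val = int(np.floor(f_val * n))
        train, val, test = perm[:n_tr], perm[n_tr : n_tr + n_val], perm[n_tr + n_val :]
        if f_te == 0 and len(test):  # flooring leftovers belong to train
            train, test = np.concatenate([train, test]), test[:0]
    for name, frac, part in (("train", f_tr, train), ("val", f_val, val), ("test", f_te, test)):
        if frac > 0 and len(part) == 0:
            raise ValueError(f"{name} partition is empty for n={n}, split={cfg.split}")
    return np.sort(train) if cfg.split_unit == "record" else train, val, test


def inputs_to_arrays(inputs: Sequence[ModelInput]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a list of network inputs into (X, y, record_ids) arrays."""
    X = np.stack([m.channels for m in inputs]).astype(np.float32)
    y = np.asarray([m.labels for m in inputs], dtype=float)
    rid = np.asarray([m.record_id if m.record_id is not None else -1 for m in inputs])
    return X, y, rid


def _val_mae(model: MSAResNet, X, y, batch_size: int) -> tuple[float, float]:
    from .model import predict

    p = predict(model, X, batch_size=batch_size)
    return (
        mae_loss(p[:, 0], y[:, 0]),
        mae_loss(p[:, 1], y[:, 1]),
    )


def train(
    model: MSAResNet,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    record_ids: Sequence | None = None,
    indices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    log=None,
) -> tuple[MSAResNet, TrainHistory]:
    """Optimize a model on (X, y); returns the model and its history.

    The dataset is split per ``cfg`` (unless explicit ``indices`` are
    given); only the train partition drives gradients, the validation
    partition selects the best checkpoint (lowest mean of SBP and DBP MAE,
    restored at the end), and the test partition is untouched — its
    indices are recorded in the history for downstream evaluation.

    Raises ``RuntimeError`` if the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("empty dataset")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if indices is None:
        tr_idx, val_idx, te_idx = split_dataset(len(X), cfg, record_ids=record_ids)
    else:
        tr_idx, val_idx, te_idx = (np.asarray(i) for i in indices)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = SGD(model.params(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    hist = TrainHistory(train_idx=tr_idx, val_idx=val_idx, test_idx=te_idx)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    best_score = np.inf
    best_state = None
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.eta_min)
        opt.lr = lr
        order = rng.permutation(len(Xtr))
        losses = []
        for i in range(0, len(Xtr), cfg.batch_size):
            bi = order[i : i + cfg.batch_size]
            pred = model.forward(Xtr[bi], training=True)
            loss, g = loss_and_grad(cfg.loss, pred, ytr[bi], delta=cfg.delta)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite {cfg.loss} loss at epoch "
                    f"{epoch}, lr={lr:.3g}"
                )
            opt.zero_grad()
            model.backward(g)
            opt.step()
            losses.append(loss)
        if len(val_idx):
            v_sbp, v_dbp = _val_mae(model, X[val_idx], y[val_idx], cfg.batch_size)
            score = 0.5 * (v_sbp + v_dbp)
            if score < best_score:
                best_score = score
                best_state = model.get_state()
                hist.best_epoch = epoch
        else:
            v_sbp = v_dbp = float("nan")
        hist.epoch.append(epoch)
        hist.lr.append(lr)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_mae_sbp.append(float(v_sbp))
        hist.val_mae_dbp.append(float(v_dbp))
        if log is not None:
            log(
                f"epoch {epoch:3d}  lr {lr:.5f}  train_{cfg.loss} "
                f"{hist.train_loss[-1]:.4f}  val_mae_sbp {v_sbp:.3f}  "
                f"val_mae_dbp {v_dbp:.3f}"
            )
    if best_state is not None:
        model.set_state(best_state)
    return model, hist


def train_config_to_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)
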