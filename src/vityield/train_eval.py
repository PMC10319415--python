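"""Training loop, dataset splitting, and evaluation metrics.

Training minimizes MSE with Adam (lr 0.001), early-stops after the
validation loss fails to improve for ``patience`` epochs and restores the
best-validation weights. Targets are standardized with train-set statistics
inside the loop for numeric conditioning; predictions are always reported
in kg/ha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedMetricError
from .nn import Adam
from .yield_models import YieldModel

__all__ = [
    "TrainConfig", "MetricReport", "split_dataset", "train",
    "rmse", "r_squared", "mape", "evaluate",
]


@dataclass
class TrainConfig:
    lr: float = 0.001
    patience: int = 10
    dropout: float = 0.25
    batch_size: int = 16
    max_epochs: int = 200
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.patience < 1:
            raise InvalidArgumentError("patience must be >= 1")
        if self.lr <= 0:
            raise InvalidArgumentError("learning rate must be > 0")


@dataclass
class MetricReport:
    rmse: float
    r_squared: float
    mape: float  # percent
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r_squared,
                "mape_pct": self.mape, "n": self.n}


# ------------------------------------------------------------------ splitting

def split_dataset(n_or_items, counts, seed: int = 0, combo_indices=None):
    """Disjoint, exhaustive shuffle-split into (train, val, test) index sets.

    ``counts`` must sum to the dataset size. When ``combo_indices`` is
    given, the shuffle is stratified by seed combination: plots of each
    combo are spread across the three partitions as evenly as their group
    sizes allow.
    """
    n = n_or_items if isinstance(n_or_items, (int, np.integer)) \
        else len(n_or_items)
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise InvalidArgumentError("counts must be three non-negative ints")
    if sum(counts) != n:
        raise InvalidArgumentError(
            f"counts {counts} sum to {sum(counts)}, dataset has {n}")
    rng = np.random.default_rng([seed, 101])
    if combo_indices is None:
        order = rng.permutation(n)
    else:
        combo_indices = np.asarray(combo_indices)
        if len(combo_indices) != n:
            raise InvalidArgumentError("combo_indices length mismatch")
        # stratified round-robin: shuffle within combos, interleave groups
        order = []
        groups = [rng.permutation(np.flatnonzero(combo_indices == c))
                  for c in np.unique(combo_indices)]
        rng.shuffle(groups)
        longest = max(len(g) for g in groups)
        for i in range(longest):
            for g in groups:
                if i < len(g):
                    order.append(g[i])
        order = np.array(order)
    train_idx = np.sort(order[:counts[0]])
    val_idx = np.sort(order[counts[0]:counts[0] + counts[1]])
    test_idx = np.sort(order[counts[0] + counts[1]:])
    return train_idx, val_idx, test_idx


# ------------------------------------------------------------------- training

def train(model: YieldModel, train_records, val_records,
          config: TrainConfig | None = None,
          train_data: dict | None = None, val_data: dict | None = None):
    """Fit ``model`` in place; returns a per-epoch history DataFrame.

    ``train_data``/``val_data`` can pass pre-computed ``preprocess`` caches
    (useful when the same records feed several models).
    """
    config = config or TrainConfig()
    if train_data is None:
        if not train_records:
            raise InvalidArgumentError("empty train set")
        train_data = model.preprocess(train_records)
    if val_data is None:
        if not val_records:
            raise InvalidArgumentError("empty validation set")
        val_data = model.preprocess(val_records)

    model.set_target_scale(train_data["y"])
    y_tr = (train_data["y"] - model.y_mean) / model.y_std
    y_va = (val_data["y"] - model.y_mean) / model.y_std

    params = model.parameters()
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng([config.seed, 301])
    n = len(y_tr)

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    history = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            opt.zero_grad()
            pred = model.forward_batch(train_data, idx, training=True, rng=rng)
            err = pred - y_tr[idx]
            loss = (err * err).mean()
            pen = model.l2_penalty()
            if pen is not None:
                loss = loss + pen
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {s // config.batch_size}"
                    f" (lr={config.lr})")
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        train_loss = epoch_loss / n

        val_pred = _predict_raw(model, val_data, config.batch_size)
        val_loss = float(np.mean((val_pred - y_va) ** 2))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if config.verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break

    model.load_state_dict(best_state)
    model.is_trained = True
    return pd.DataFrame(history)


def _predict_raw(model, data, batch_size):
    n = len(data["y"])
    out = np.empty(n)
    for s in range(0, n, batch_size):
        idx = np.arange(s, min(s + batch_size, n))
        out[idx] = model.forward_batch(data, idx).numpy()
    return out


# -------------------------------------------------------------------- metrics

def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise InvalidArgumentError(
            f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise InvalidArgumentError("need at least one sample")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error, in the units of ``y``."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """R^2 = 1 - RSS/TSS with TSS about the evaluation set's own mean."""
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise InvalidArgumentError("R^2 needs at least two samples")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedMetricError("R^2 undefined for constant ground truth")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss


def mape(y, yhat) -> float:
    """Mean absolute percentage error, in percent."""
    y, yhat = _check_pair(y, yhat)
    if np.any(y == 0):
        raise UndefinedMetricError("MAPE undefined when ground truth has zeros")
    return float(100.0 * np.mean(np.abs((y - yhat) / y)))


def evaluate(y, yhat) -> MetricReport:
    y, yhat = _check_pair(y, yhat)
    return MetricReport(rmse(y, yhat), r_squared(y, yhat), mape(y, yhat),
                        n=int(y.size))
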