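"""Model/Results interface for the tau-to-Centiloid CNN regressor.

:class:`CentiloidCNN` is the model object: it holds the [0,1]-scaled input
volumes and the Centiloid targets, and ``fit`` on a train/validation split
returns a :class:`CNNResults` carrying the learned parameters, training
history, per-split RMSE/R^2 and prediction/attribution entry points.
:class:`CrossValidatedCNN` trains one instance per fold of a
:class:`~taucl.metrics.FoldPlan` and its :class:`CVResults` selects the best
instance by the mean of validation and test RMSE.

Training minimises mean squared error with RMSprop on internally
standardised targets (predictions are returned in Centiloid units), keeps
the parameters with the best validation RMSE seen over epochs, and stops
early when validation RMSE has not improved for ``patience`` epochs.  All
randomness (initialisation, shuffling) derives from ``config.seed``, so a
fixed seed reproduces predictions exactly.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import FoldPlan, r2, rmse, select_best_instance
from .nn import CNNConfig, Network, RMSprop, build_network
from .preprocess import minmax_scale
from .volume import Atlas, Volume

__all__ = ["CentiloidCNN", "CNNResults", "CrossValidatedCNN", "CVResults",
           "train_instance"]


@dataclass
class CNNResults:
    """One trained cross-validation instance of the CNN."""

    network: Network
    config: CNNConfig
    fold: int
    history: pd.DataFrame
    y_mean: float
    y_sd: float
    input_shape: tuple[int, int, int]
    rmse_train: float | None = None
    rmse_val: float | None = None
    rmse_test: float | None = None
    r2_train: float | None = None
    r2_val: float | None = None
    r2_test: float | None = None
    split_ids: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict Centiloid for a batch of scaled volumes (n, D, H, W)."""
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        if tuple(X.shape[1:]) != tuple(self.input_shape):
            raise ValueError(
                f"input grid {X.shape[1:]} != training grid {self.input_shape}")
        out = np.empty(X.shape[0])
        bs = max(1, self.config.batch_size)
        for i in range(0, X.shape[0], bs):
            out[i:i + bs] = self.network.forward(X[i:i + bs])
        return out * self.y_sd + self.y_mean

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Exact d(prediction in CL)/d(voxel) for each volume in the batch."""
        X = np.asarray(X)
        squeeze = X.ndim == 3
        if squeeze:
            X = X[None]
        if tuple(X.shape[1:]) != tuple(self.input_shape):
            raise ValueError(
                f"input grid {X.shape[1:]} != training grid {self.input_shape}")
        grads = np.empty_like(X, dtype=float)
        bs = max(1, self.config.batch_size)
        for i in range(0, X.shape[0], bs):
            grads[i:i + bs] = self.network.input_gradient(X[i:i + bs]) * self.y_sd
        return grads[0] if squeeze else grads

    def evaluate(self, X: np.ndarray, y) -> tuple[float, float]:
        """(RMSE, R^2) of this instance on an evaluation set."""
        yhat = self.predict(X)
        return rmse(y, yhat), r2(y, yhat)

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def summary(self) -> str:
        buf = io.StringIO()
        print(f"CentiloidCNN instance (fold {self.fold})", file=buf)
        print(f"  architecture : conv{self.config.channels} "
              f"k={self.config.kernel_size} stride={self.config.stride} "
              f"{self.config.activation}, head {self.config.dense_widths}", file=buf)
        print(f"  parameters   : {self.network.n_params()}", file=buf)
        print(f"  epochs run   : {self.n_epochs} "
              f"(best at {int(self.history['val_rmse'].idxmin()) + 1})", file=buf)
        print(f"  target scale : mean {self.y_mean:.2f} CL, sd {self.y_sd:.2f} CL",
              file=buf)
        print("  split        rmse (CL)       r2", file=buf)
        for split in ("train", "val", "test"):
            rm, rq = getattr(self, f"rmse_{split}"), getattr(self, f"r2_{split}")
            if rm is not None:
                print(f"  {split:<12} {rm:>9.3f} {rq:>9.3f}", file=buf)
        return buf.getvalue()


def train_instance(X: np.ndarray, y, train_idx, val_idx, config: CNNConfig,
                   test_idx=None, fold: int = 1,
                   split_ids: dict | None = None) -> CNNResults:
    """Train one CNN instance on a train/validation index split.

    X: (n, D, H, W) scaled volumes; y: (n,) Centiloid.  Keeps the epoch with
    the best validation RMSE and stops early after ``config.patience``
    epochs without improvement.  Deterministic given ``config.seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("train and validation sets must be nonempty")

    mu = float(y[train_idx].mean()) if config.standardize_targets else 0.0
    sd = float(y[train_idx].std()) if config.standardize_targets else 1.0
    if sd == 0.0:
        sd = 1.0
    ys = (y - mu) / sd

    init_rng = np.random.default_rng([int(config.seed) % 2**31, zlib.crc32(b"init")])
    shuffle_rng = np.random.default_rng([int(config.seed) % 2**31, zlib.crc32(b"shuffle")])
    net = build_network(config, init_rng, input_shape=X.shape[1:])
    opt = RMSprop(net, config.learning_rate, config.rmsprop_rho,
                  weight_decay=config.weight_decay)

    def predict_std(idx):
        out = np.empty(idx.size)
        for i in range(0, idx.size, config.batch_size):
            out[i:i + config.batch_size] = net.forward(X[idx[i:i + config.batch_size]])
        return out

    best_val, best_params, best_epoch = np.inf, net.get_params(), 0
    last_decay = 0
    history = []
    for epoch in range(config.max_epochs):
        order = train_idx[shuffle_rng.permutation(train_idx.size)]
        losses = []
        for i in range(0, order.size, config.batch_size):
            batch = order[i:i + config.batch_size]
            pred = net.forward(X[batch])
            err = pred - ys[batch]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(fold {fold}); consider lowering learning_rate "
                    f"(currently {config.learning_rate:g})")
            losses.append(loss)
            net.backward(2.0 * err / batch.size)
            opt.step()
        val_rmse = rmse(ys[val_idx] * sd + mu, predict_std(val_idx) * sd + mu)
        history.append({"epoch": epoch + 1,
                        "train_mse": float(np.mean(losses)),
                        "val_rmse": val_rmse,
                        "learning_rate": opt.lr})
        if val_rmse < best_val - 1e-12:
            best_val, best_params, best_epoch = val_rmse, net.get_params(), epoch
        elif epoch - best_epoch >= config.patience:
            break
        # decay the learning rate when validation RMSE stalls
        if (epoch - max(best_epoch, last_decay) >= config.lr_decay_patience
                and opt.lr * config.lr_decay_factor >= config.min_learning_rate):
            opt.lr *= config.lr_decay_factor
            last_decay = epoch
    net.set_params(best_params)

    res = CNNResults(network=net, config=config, fold=fold,
                     history=pd.DataFrame(history), y_mean=mu, y_sd=sd,
                     input_shape=tuple(X.shape[1:]),
                     split_ids=split_ids or {})
    res.rmse_train, res.r2_train = res.evaluate(X[train_idx], y[train_idx])
    res.rmse_val, res.r2_val = res.evaluate(X[val_idx], y[val_idx])
    if test_idx is not None and len(test_idx) > 0:
        test_idx = np.asarray(test_idx, dtype=int)
        res.rmse_test, res.r2_test = res.evaluate(X[test_idx], y[test_idx])
    return res


class CentiloidCNN:
    """CNN regression of Centiloid on 3D tau volumes (model object).

    Parameters
    ----------
    X : ndarray, shape (n, D, H, W)
        [0, 1]-scaled input volumes.
    y : array-like, shape (n,)
        Centiloid targets.
    ids : sequence of str, optional
        Subject ids aligned with rows of ``X`` (needed for id-based splits).
    config : CNNConfig, optional
    """

    def __init__(self, X, y, ids=None, config: CNNConfig | None = None) -> None:
        self.X = np.asarray(X)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 4 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (n, D, H, W) aligned with y")
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(self.y))]
        self.config = config or CNNConfig()
        self._index = {s: i for i, s in enumerate(self.ids)}

    @classmethod
    def from_dataset(cls, cohort: pd.DataFrame, volumes: list[Volume], atlas: Atlas,
                     config: CNNConfig | None = None) -> "CentiloidCNN":
        """Build the model from raw SUV volumes: scales each within the mask."""
        X = np.stack([minmax_scale(v, atlas).volume.data for v in volumes])
        return cls(X, cohort["cl"].to_numpy(), ids=cohort["id"].tolist(), config=config)

    def indices_of(self, ids) -> np.ndarray:
        missing = [s for s in ids if s not in self._index]
        if missing:
            raise KeyError(f"unknown subject ids: {missing[:5]}")
        return np.array([self._index[s] for s in ids], dtype=int)

    def fit(self, train_ids, val_ids, test_ids=None, fold: int = 1,
            config: CNNConfig | None = None) -> CNNResults:
        """Train one instance on id-based splits; returns its results object."""
        cfg = config or self.config
        return train_instance(
            self.X, self.y,
            self.indices_of(train_ids), self.indices_of(val_ids), cfg,
            test_idx=self.indices_of(test_ids) if test_ids else None,
            fold=fold,
            split_ids={"train": list(train_ids), "validation": list(val_ids),
                       "test": list(test_ids or [])})


@dataclass
class CVResults:
    """Results of K-fold cross-validation: one CNNResults per fold."""

    instances: list[CNNResults]
    plan: FoldPlan

    def best(self) -> CNNResults:
        """Best instance by mean(validation, test) RMSE; ties -> lowest fold."""
        return select_best_instance(self.instances)

    def metrics_table(self) -> pd.DataFrame:
        rows = [{"fold": r.fold, "epochs": r.n_epochs,
                 "rmse_train": r.rmse_train, "rmse_val": r.rmse_val,
                 "rmse_test": r.rmse_test, "r2_train": r.r2_train,
                 "r2_val": r.r2_val, "r2_test": r.r2_test}
                for r in self.instances]
        return pd.DataFrame(rows).set_index("fold")

    def summary(self) -> str:
        buf = io.StringIO()
        print(f"Cross-validated CentiloidCNN ({len(self.instances)} instances, "
              f"K={self.plan.K})", file=buf)
        with pd.option_context("display.width", 120):
            print(self.metrics_table().round(3), file=buf)
        print(f"best instance: fold {self.best().fold} "
              f"(mean val/test RMSE "
              f"{(self.best().rmse_val + self.best().rmse_test) / 2:.3f} CL)", file=buf)
        return buf.getvalue()


class CrossValidatedCNN:
    """Train one CNN instance per fold of a FoldPlan."""

    def __init__(self, model: CentiloidCNN, plan: FoldPlan) -> None:
        self.model = model
        self.plan = plan

    def fit(self, folds=None, progress: bool = False) -> CVResults:
        """Train the listed folds (default: all) and return CVResults.

        Each fold's instance uses a seed derived from the model seed and the
        fold id, so instances differ in initialisation as well as split.
        """
        instances = []
        for f in self.plan.folds:
            if folds is not None and f["fold"] not in folds:
                continue
            cfg = CNNConfig(**{**self.model.config.__dict__,
                               "seed": (int(self.model.config.seed) * 1009
                                        + f["fold"]) % 2**31})
            if progress:
                print(f"[taucl] training fold {f['fold']}/{self.plan.K} ...", flush=True)
            instances.append(self.model.fit(f["train"], f["validation"],
                                            test_ids=self.plan.test,
                                            fold=f["fold"], config=cfg))
        return CVResults(instances=instances, plan=self.plan)
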