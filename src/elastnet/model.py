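"""Elastance regression models.

`ElastanceRegressor` is the model object: it holds the preprocessed
channel inputs (n x C x 200) and elastance targets (mmHg/ml) for the
training and validation partitions plus an architecture and training
recipe. `fit()` trains one network per batch size in the grid with Adam
on the MSE loss, records the validation MSE after every epoch
(checkpointing the best weights, which is equivalent to tuning the epoch
count over 1..max_epochs), selects the (batch size, epoch) pair with the
lowest validation MSE, and returns an `ElastanceRegressorResults`
carrying the restored network, the selection, the loss histories and
agreement diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .architecture import CNNArchitecture, TrainingConfig
from .nn import Adam, Conv1d, Flatten, Linear, MaxPool1d, ReLU, Sequential, mse_loss

__all__ = [
    "build_cnn",
    "ElastanceRegressor",
    "ElastanceRegressorResults",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


def build_cnn(arch: CNNArchitecture, seed: int = 0) -> Sequential:
    """Instantiate an untrained network with seeded initialization."""
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = arch.in_channels
    for c_out in arch.conv_out_channels:
        layers.append(Conv1d(c_in, c_out, arch.kernel, arch.stride, arch.padding, rng))
        layers.append(ReLU())
        c_in = c_out
    layers.append(MaxPool1d(arch.pool_kernel, arch.pool_stride))
    layers.append(Flatten())
    layers.append(Linear(arch.flatten_width, 1, rng))
    return Sequential(layers)


def predict(model: Sequential, inputs: np.ndarray) -> np.ndarray:
    """Scalar elastance estimate (mmHg/ml) per subject, order-preserving."""
    x = np.asarray(inputs, dtype=float)
    expected_c = model.layers[0].W.shape[1]
    if x.ndim != 3 or x.shape[1] != expected_c:
        raise ValueError(
            f"expected inputs of shape (n, {expected_c}, L), got {x.shape}"
        )
    return model.forward(x)[:, 0]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ElastanceRegressor:
    """Model object binding data, architecture and training recipe."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    architecture: CNNArchitecture
    config: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        self.X_train = np.asarray(self.X_train, dtype=float)
        self.y_train = np.asarray(self.y_train, dtype=float)
        self.X_val = np.asarray(self.X_val, dtype=float)
        self.y_val = np.asarray(self.y_val, dtype=float)
        if self.X_train.ndim != 3 or self.X_train.shape[1] != self.architecture.in_channels:
            raise ValueError("X_train must be (n, in_channels, 200)")
        if self.X_train.shape[0] != self.y_train.shape[0]:
            raise ValueError("X_train and y_train disagree on n")
        if self.X_val.shape[0] != self.y_val.shape[0]:
            raise ValueError("X_val and y_val disagree on n")

    @classmethod
    def from_dataset(cls, X, y, split, architecture, config=None) -> "ElastanceRegressor":
        """Build from a full (n, C, 200) array and a SplitIndices."""
        config = config or TrainingConfig()
        return cls(
            X_train=X[split.train], y_train=y[split.train],
            X_val=X[split.validation], y_val=y[split.validation],
            architecture=architecture, config=config,
        )

    def _train_one(self, batch_size: int, seed: int):
        """Train one network; returns (best_weights, best_epoch, history)."""
        cfg = self.config
        model = build_cnn(self.architecture, seed)
        opt = Adam(model.params, model.grads, lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng(seed + 1)
        n = self.X_train.shape[0]
        y_tr = self.y_train[:, None]

        best_val = np.inf
        best_epoch = 0
        best_weights = model.get_weights()
        train_hist: list[float] = []
        val_hist: list[float] = []
        for epoch in range(1, cfg.max_epochs + 1):
            perm = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                pred = model.forward(self.X_train[idx])
                loss, gy = mse_loss(pred, y_tr[idx])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} (batch_size={batch_size}, "
                        f"seed={seed}, lr={cfg.learning_rate})"
                    )
                model.backward(gy)
                opt.step()
                epoch_loss += loss * idx.size
            train_hist.append(epoch_loss / n)
            val_pred = model.forward(self.X_val)[:, 0]
            val_mse = float(np.mean((val_pred - self.y_val) ** 2))
            val_hist.append(val_mse)
            if val_mse < best_val:
                best_val = val_mse
                best_epoch = epoch
                best_weights = model.get_weights()
        return best_weights, best_epoch, best_val, train_hist, val_hist

    def fit(self, seed: Optional[int] = None) -> "ElastanceRegressorResults":
        """Run the batch-size/epoch grid and return the best configuration."""
        seed = self.config.seed if seed is None else seed
        runs = {}
        best = None
        for bs in self.config.batch_size_grid:
            weights, epoch, val_mse, tr_hist, val_hist = self._train_one(bs, seed)
            runs[bs] = {"train": tr_hist, "validation": val_hist}
            if best is None or val_mse < best[2]:
                best = (bs, epoch, val_mse, weights)
        bs, epoch, val_mse, weights = best
        model = build_cnn(self.architecture, seed)
        model.set_weights(weights)
        return ElastanceRegressorResults(
            model=self, network=model, batch_size=bs, epochs=epoch,
            val_mse=val_mse, history=runs, seed=seed,
        )


@dataclass
class ElastanceRegressorResults:
    """Fitted regressor: selected hyperparameters, network and diagnostics."""

    model: ElastanceRegressor
    network: Sequential
    batch_size: int
    epochs: int
    val_mse: float
    history: dict[int, dict[str, list[float]]]
    seed: int

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return predict(self.network, inputs)

    def evaluate(self, X: np.ndarray, y: np.ndarray, label: str = "test"):
        """Agreement statistics between predictions on X and reference y."""
        from .metrics import compute_agreement

        return compute_agreement(self.predict(X), np.asarray(y, dtype=float), label=label)

    def summary(self) -> str:
        arch = self.model.architecture
        lines = [
            "Elastance CNN regression results",
            "=" * 44,
            f"channels            : {arch.in_channels} -> "
            + " -> ".join(str(c) for c in arch.conv_out_channels),
            f"flatten width       : {arch.flatten_width}",
            f"parameters          : {self.network.n_parameters()}",
            f"selected batch size : {self.batch_size}",
            f"selected epochs     : {self.epochs}",
            f"validation MSE      : {self.val_mse:.5f} (mmHg/ml)^2",
            f"training samples    : {self.model.X_train.shape[0]}",
            f"validation samples  : {self.model.X_val.shape[0]}",
            f"seed                : {self.seed}",
        ]
        return "\n".join(lines)


def train(
    model: Sequential,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    val_inputs: np.ndarray,
    val_targets: np.ndarray,
    cfg: Optional[TrainingConfig] = None,
    arch: Optional[CNNArchitecture] = None,
) -> "ElastanceRegressorResults":
    """Functional wrapper: tune over the batch-size grid and epochs.

    ``model`` supplies the architecture shape check; the returned results
    carry a freshly initialized-and-restored network.
    """
    cfg = cfg or TrainingConfig()
    if arch is None:
        c_in = model.layers[0].W.shape[1]
        arch = CNNArchitecture.cnn1() if c_in == 1 else CNNArchitecture.cnn2()
    reg = ElastanceRegressor(train_inputs, train_targets, val_inputs, val_targets, arch, cfg)
    return reg.fit()


def save_checkpoint(results: ElastanceRegressorResults, path: str) -> None:
    """Single-file checkpoint: architecture JSON + weight arrays."""
    arch = results.model.architecture
    meta = {
        "in_channels": arch.in_channels,
        "conv_out_channels": list(arch.conv_out_channels),
        "kernel": arch.kernel,
        "stride": arch.stride,
        "padding": arch.padding,
        "pool_kernel": arch.pool_kernel,
        "pool_stride": arch.pool_stride,
        "input_length": arch.input_length,
        "batch_size": results.batch_size,
        "epochs": results.epochs,
        "val_mse": results.val_mse,
        "seed": results.seed,
    }
    weights = results.network.get_weights()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_checkpoint(path: str) -> tuple[Sequential, dict]:
    """Load a checkpoint; returns (network, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    arch = CNNArchitecture(
        in_channels=meta["in_channels"],
        conv_out_channels=tuple(meta["conv_out_channels"]),
        kernel=meta["kernel"],
        stride=meta["stride"],
        padding=meta["padding"],
        pool_kernel=meta["pool_kernel"],
        pool_stride=meta["pool_stride"],
        input_length=meta["input_length"],
    )
    net = build_cnn(arch, meta.get("seed", 0))
    net.set_weights(weights)
    return net, meta
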