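"""Classifier configuration, cross-validation folds, and training.

Three model families consume the same (N, L, C) positional fold-change
arrays and emit one probability per sequence:

* ``mlp`` — flatten, two rectified hidden layers with dropout;
* ``cnn`` — two convolution/max-pool blocks over positions (channels = k-mer
  sizes), global max pooling, one dense layer;
* ``bilstm`` — a bidirectional LSTM over positions, final-state
  concatenation, one dense layer.

Training minimizes binary cross-entropy with Adam and early-stops on
validation loss.  Inputs are standardized per channel with statistics fitted
on the training set (stored in the trained model), which keeps the heavy-
tailed raw fold changes on a scale the optimizer handles without altering the
representation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nets
from .features import FeatureArray, stack

ARCHS = ("mlp", "cnn", "bilstm")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters."""

    arch: str = "mlp"
    mlp_hidden: tuple[int, int] = (256, 64)
    cnn_filters: tuple[int, int] = (32, 64)
    cnn_width: int = 7
    pool_width: int = 2
    lstm_units: int = 64
    dense_units: int = 64
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    min_delta: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}")
        sizes = (*self.mlp_hidden, *self.cnn_filters, self.cnn_width,
                 self.pool_width, self.lstm_units, self.dense_units,
                 self.batch_size, self.max_epochs, self.patience)
        if any(s <= 0 for s in sizes):
            raise ValueError("all sizes must be positive")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


@dataclass
class LabeledDataset:
    """Stacked feature arrays with binary labels (1 = positive class)."""

    X: np.ndarray  # (N, L, C)
    y: np.ndarray  # (N,) in {0, 1}
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3:
            raise ValueError("X must be (N, L, C)")
        if len(self.X) != len(self.y):
            raise ValueError("features and labels must have equal length")
        if not self.ids:
            self.ids = [str(i) for i in range(len(self.y))]

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.y, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx],
                              [self.ids[i] for i in idx])

    @classmethod
    def from_feature_arrays(
        cls,
        positives: Sequence[FeatureArray],
        negatives: Sequence[FeatureArray],
    ) -> "LabeledDataset":
        X = np.concatenate([stack(list(positives)), stack(list(negatives))])
        y = np.concatenate([np.ones(len(positives), dtype=np.int64),
                            np.zeros(len(negatives), dtype=np.int64)])
        ids = [f.segment_id for f in positives] + [f.segment_id for f in negatives]
        return cls(X, y, ids)


@dataclass
class FoldSplit:
    """Rotating stratified k-fold: fold f tests, fold f+1 (mod n) validates,
    the remaining n-2 folds train."""

    n_folds: int
    folds: list[dict[str, np.ndarray]]
    seed: int


def make_folds(dataset: LabeledDataset, n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified partition into test folds with rotating validation folds.

    Test folds partition the dataset; within each fold the train/validation/
    test index sets are disjoint.  Deterministic given ``seed``.
    """
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3 (train/validation/test roles)")
    counts = dataset.class_counts
    if len(counts) < 2 or min(counts.values()) < n_folds:
        raise ValueError(
            f"each class needs >= {n_folds} members; have {counts}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    test_folds = [test for _, test in skf.split(dataset.X[:, :1, 0], dataset.y)]
    folds = []
    for f in range(n_folds):
        test = test_folds[f]
        val = test_folds[(f + 1) % n_folds]
        train = np.concatenate(
            [test_folds[g] for g in range(n_folds) if g not in (f, (f + 1) % n_folds)])
        folds.append({"train": np.sort(train), "val": np.sort(val),
                      "test": np.sort(test)})
    return FoldSplit(n_folds=n_folds, folds=folds, seed=seed)


def build_network(config: ModelConfig, L: int, C: int,
                  rng: np.random.Generator) -> nets.Sequential:
    if config.arch == "mlp":
        h1, h2 = config.mlp_hidden
        return nets.Sequential([
            nets.Flatten(),
            nets.Dense(L * C, h1, rng), nets.ReLU(),
            nets.Dropout(config.dropout, rng),
            nets.Dense(h1, h2, rng), nets.ReLU(),
            nets.Dropout(config.dropout, rng),
            nets.Dense(h2, 1, rng),
        ])
    if config.arch == "cnn":
        f1, f2 = config.cnn_filters
        w, pw = config.cnn_width, config.pool_width
        return nets.Sequential([
            nets.Conv1D(C, f1, w, rng), nets.ReLU(), nets.MaxPool1D(pw),
            nets.Conv1D(f1, f2, w, rng), nets.ReLU(), nets.MaxPool1D(pw),
            nets.GlobalMaxPool(),
            nets.Dense(f2, config.dense_units, rng), nets.ReLU(),
            nets.Dropout(config.dropout, rng),
            nets.Dense(config.dense_units, 1, rng),
        ])
    # bilstm
    return nets.Sequential([
        nets.BiLSTM(C, config.lstm_units, rng),
        nets.Dense(2 * config.lstm_units, config.dense_units, rng), nets.ReLU(),
        nets.Dropout(config.dropout, rng),
        nets.Dense(config.dense_units, 1, rng),
    ])


@dataclass
class TrainedModel:
    """A trained scorer: sequence features -> probability of the positive class."""

    config: ModelConfig
    net: nets.Sequential
    mean: np.ndarray  # per-channel standardization, fitted on train
    std: np.ndarray
    input_shape: tuple[int, int]  # (L, C)
    history: dict

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected features of shape (N, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {X.shape}")
        return (X - self.mean) / self.std

    def predict(self, features: np.ndarray | Sequence[FeatureArray],
                batch_size: int = 256) -> np.ndarray:
        """One score in [0, 1] per input, order preserved."""
        if not isinstance(features, np.ndarray):
            if len(features) == 0:
                return np.zeros(0)
            features = stack(list(features))
        if len(features) == 0:
            return np.zeros(0)
        X = self._prep(features)
        out = []
        for lo in range(0, len(X), batch_size):
            logits = self.net.forward(X[lo:lo + batch_size], train=False)
            out.append(nets._sigmoid(logits.reshape(-1)))
        return np.concatenate(out)


def train_model(config: ModelConfig, train: LabeledDataset,
                validation: LabeledDataset) -> TrainedModel:
    """Train one classifier; deterministic given ``config.seed``.

    Raises on heterogeneous feature shapes or a single-class training set.
    """
    if train.X.shape[1:] != validation.X.shape[1:]:
        raise ValueError("train and validation feature shapes differ")
    if len(train.class_counts) < 2:
        raise ValueError("training set must contain both classes")
    L, C = train.X.shape[1:]
    rng = np.random.default_rng(config.seed)

    mean = train.X.mean(axis=(0, 1))  # per channel
    std = train.X.std(axis=(0, 1))
    std[std < 1e-12] = 1.0
    Xtr = (train.X - mean) / std
    Xval = (validation.X - mean) / std

    net = build_network(config, L, C, rng)
    history = nets.train_network(
        net, Xtr, train.y, Xval, validation.y, rng,
        lr=config.learning_rate, batch_size=config.batch_size,
        max_epochs=config.max_epochs, patience=config.patience,
        min_delta=config.min_delta,
    )
    return TrainedModel(config=config, net=net, mean=mean, std=std,
                        input_shape=(L, C), history=history)


def predict(model: TrainedModel,
            features: np.ndarray | Sequence[FeatureArray]) -> np.ndarray:
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(features)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (weights + config + normalization) as .npz."""
    import json as _json

    weights = model.net.get_weights()
    np.savez(
        path,
        config=np.array(_json.dumps(
            {**model.config.__dict__,
             "mlp_hidden": list(model.config.mlp_hidden),
             "cnn_filters": list(model.config.cnn_filters)})),
        mean=model.mean,
        std=model.std,
        input_shape=np.array(model.input_shape),
        n_weights=np.array(len(weights)),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_model(path) -> TrainedModel:
    import json as _json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = _json.loads(str(data["config"]))
        cfg_dict["mlp_hidden"] = tuple(cfg_dict["mlp_hidden"])
        cfg_dict["cnn_filters"] = tuple(cfg_dict["cnn_filters"])
        config = ModelConfig(**cfg_dict)
        L, C = (int(v) for v in data["input_shape"])
        net = build_network(config, L, C, np.random.default_rng(config.seed))
        net.set_weights([data[f"w{i}"] for i in range(int(data["n_weights"]))])
        return TrainedModel(config=config, net=net, mean=data["mean"],
                            std=data["std"], input_shape=(L, C), history={})
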