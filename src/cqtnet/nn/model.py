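"""The 5-branch CNN -> merge -> LSTM -> fully-connected chart classifier.

Each of the five physiological channels feeds its own (weight-independent)
stack of four convolution blocks — filters 70/50/30/10 with matching
kernel sizes, ReLU, max-pool 2, dropout 50/50/25/25% — so a 1792-sample
channel is compressed to 89 time steps of 10 features. The five branch
outputs are merged by feature-axis concatenation (89 x 50), run through a
single 50-unit tanh LSTM returning all steps, flattened to 4450 values and
classified by a 50-unit ReLU layer followed by a 2-way softmax. Class
index 1 is "deceptive"; the scalar probability reported everywhere is the
softmax mass of that class.

Training minimizes mean softmax cross-entropy with Adam (lr 0.0015,
batch 64), fully seeded: weight init, shuffling and dropout all derive
from explicit integer seeds, so identical calls give identical parameters.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import SEGMENT_SAMPLES, QuestionSetSegment
from .layers import (
    Adam,
    Conv1d,
    Dense,
    Dropout,
    LSTM,
    MaxPool2,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "CnnLstmClassifier",
    "build_model",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]

LABEL_TO_INDEX = {"truthful": 0, "deceptive": 1}


class ConfigurationError(ValueError):
    """Architecture hyperparameters are inconsistent."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Every structural hyperparameter of the classifier, validated."""

    n_branches: int = 5
    conv_filters: tuple[int, ...] = (70, 50, 30, 10)
    conv_kernel_sizes: tuple[int, ...] = (70, 50, 30, 10)
    conv_activation: str = "relu"
    pool_kind: str = "max"
    pool_size: int = 2
    dropout_rates: tuple[float, ...] = (0.50, 0.50, 0.25, 0.25)
    lstm_hidden: int = 50
    lstm_activation: str = "tanh"
    lstm_returns_all_steps: bool = True
    fc1_units: int = 50
    output_units: int = 2
    input_len: int = SEGMENT_SAMPLES
    #: Required number of time steps after the conv stack (None disables the
    #: check, e.g. for ablation variants with fewer conv layers).
    expected_time_steps: int | None = 89

    def __post_init__(self) -> None:
        n = len(self.conv_filters)
        if not (len(self.conv_kernel_sizes) == len(self.dropout_rates) == n):
            raise ConfigurationError(
                "conv_filters, conv_kernel_sizes and dropout_rates must have equal length"
            )
        if self.conv_activation != "relu":
            raise ConfigurationError("only ReLU conv activation is supported")
        if self.pool_kind != "max" or self.pool_size != 2:
            raise ConfigurationError("only max pooling of size 2 is supported")
        if self.lstm_activation != "tanh":
            raise ConfigurationError("only tanh LSTM activation is supported")
        if not self.lstm_returns_all_steps:
            raise ConfigurationError(
                "the LSTM must return all time steps (the head flattens them)"
            )
        self.validate_shapes()

    def shape_chain(self) -> list[int]:
        """Time lengths entering each conv block, ending with the final length.

        Valid convolution (L -> L-K+1) then floor-halving max pool per block.
        """
        lengths = [self.input_len]
        length = self.input_len
        for k in self.conv_kernel_sizes:
            if length < k:
                raise ConfigurationError(
                    f"time length {length} shorter than kernel {k}"
                )
            length = (length - k + 1) // self.pool_size
            lengths.append(length)
        return lengths

    def validate_shapes(self) -> int:
        """Return the derived flatten length; raise if the chain is inconsistent."""
        final = self.shape_chain()[-1]
        if self.expected_time_steps is not None and final != self.expected_time_steps:
            raise ConfigurationError(
                f"conv/pool arithmetic yields {final} time steps, "
                f"expected {self.expected_time_steps}"
            )
        return final * self.lstm_hidden

    @property
    def merged_features(self) -> int:
        return self.n_branches * self.conv_filters[-1]

    @property
    def flatten_len(self) -> int:
        return self.shape_chain()[-1] * self.lstm_hidden


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    optimizer: str = "adam"
    learning_rate: float = 0.0015
    batch_size: int = 64
    max_epochs: int = 100
    early_stopping_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


class CnnLstmClassifier:
    """The assembled network; see the module docstring for the wiring."""

    def __init__(self, config: ArchitectureConfig, seed: int) -> None:
        config.validate_shapes()
        self.config = config
        self.seed = seed
        self.training_log: list[dict] = []
        rng = np.random.default_rng(seed)
        self.branches: list[list] = []
        for _ in range(config.n_branches):
            blocks: list = []
            in_ch = 1
            for filters, kernel, rate in zip(
                config.conv_filters, config.conv_kernel_sizes, config.dropout_rates
            ):
                blocks += [Conv1d(in_ch, filters, kernel, rng,
                                  needs_input_grad=bool(blocks)),
                           ReLU(), MaxPool2(), Dropout(rate)]
                in_ch = filters
            self.branches.append(blocks)
        self.lstm = LSTM(config.merged_features, config.lstm_hidden, rng)
        self.fc1 = Dense(config.flatten_len, config.fc1_units, rng)
        self.fc1_act = ReLU()
        self.fc2 = Dense(config.fc1_units, config.output_units, rng)

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list:
        out = [layer for blocks in self.branches for layer in blocks]
        return out + [self.lstm, self.fc1, self.fc1_act, self.fc2]

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch ``x`` of shape (B, n_branches, input_len)."""
        if x.ndim != 3 or x.shape[1] != self.config.n_branches \
                or x.shape[2] != self.config.input_len:
            raise ValueError(
                f"expected input (B, {self.config.n_branches}, "
                f"{self.config.input_len}), got {x.shape}"
            )
        outs = []
        for b, blocks in enumerate(self.branches):
            h = x[:, b : b + 1, :]
            for layer in blocks:
                h = layer.forward(h, training=training, rng=rng)
            outs.append(h)
        merged = np.concatenate(outs, axis=1)          # (B, 50, T)
        seq = self.lstm.forward(np.ascontiguousarray(merged.transpose(0, 2, 1)),
                                training, rng)         # (B, T, H)
        flat = seq.reshape(seq.shape[0], -1)           # (B, T*H)
        self._flat_shape = seq.shape
        h = self.fc1_act.forward(self.fc1.forward(flat, training, rng), training, rng)
        return self.fc2.forward(h, training, rng)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc1.backward(self.fc1_act.backward(self.fc2.backward(dlogits)))
        d = self.lstm.backward(d.reshape(self._flat_shape))
        d = np.ascontiguousarray(d.transpose(0, 2, 1))  # (B, 50, T)
        n_f = self.config.conv_filters[-1]
        for b, blocks in enumerate(self.branches):
            db = d[:, b * n_f : (b + 1) * n_f, :]
            for layer in reversed(blocks):
                db = layer.backward(db)

    def predict_logits(self, x: np.ndarray, chunk: int = 64) -> np.ndarray:
        parts = [self.forward(x[i : i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(parts, axis=0)


def build_model(config: ArchitectureConfig | None = None, seed: int = 0) -> CnnLstmClassifier:
    """Build an untrained classifier with seeded random-noise initialization."""
    return CnnLstmClassifier(config or ArchitectureConfig(), seed)


def _as_batch(segments: list[QuestionSetSegment]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.x for s in segments]).astype(np.float32)
    labels = np.array([LABEL_TO_INDEX[s.label] for s in segments])
    return x, labels


def _epoch_loss(model: CnnLstmClassifier, x: np.ndarray, y: np.ndarray,
                chunk: int = 64) -> float:
    losses, weights = [], []
    for i in range(0, len(x), chunk):
        logits = model.forward(x[i : i + chunk])
        loss, _ = softmax_cross_entropy(logits, y[i : i + chunk])
        losses.append(loss)
        weights.append(len(logits))
    return float(np.average(losses, weights=weights))


def train(
    model: CnnLstmClassifier,
    segments: list[QuestionSetSegment],
    train_config: TrainConfig | None = None,
) -> CnnLstmClassifier:
    """Train a copy of ``model`` on labelled segments; the input is untouched.

    Seeded end to end; optional early stopping monitors the loss on a
    validation split carved from the training data (disabled when
    ``validation_fraction`` is 0), restoring the best parameters.
    """
    cfg = train_config or TrainConfig()
    for s in segments:
        if s.label not in LABEL_TO_INDEX:
            raise ValueError(f"segment with unknown label {s.label!r}")
    x, y = _as_batch(segments)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    model = copy.deepcopy(model)
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.validation_fraction * len(x)))
    use_early_stop = n_val > 0 and cfg.early_stopping_patience > 0
    perm = rng.permutation(len(x))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if use_early_stop and len(np.unique(y[tr_idx])) < 2:
        raise ValueError("validation split left a single-class training set")
    if not use_early_stop:
        tr_idx = perm
    x_tr, y_tr = x[tr_idx], y[tr_idx]

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_val, best_params, patience_left = np.inf, None, cfg.early_stopping_patience
    model.training_log = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        batch_losses, batch_sizes = [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x_tr[idx], training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step(model.gradients())
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
        entry = {"epoch": epoch,
                 "train_loss": float(np.average(batch_losses, weights=batch_sizes))}
        if use_early_stop:
            val_loss = _epoch_loss(model, x[val_idx], y[val_idx])
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = [p.copy() for p in model.parameters()]
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
        model.training_log.append(entry)
        if use_early_stop and patience_left <= 0:
            break
    if use_early_stop and best_params is not None:
        for p, bp in zip(model.parameters(), best_params):
            p[...] = bp
    return model


def predict_proba(
    model: CnnLstmClassifier,
    segments: QuestionSetSegment | list[QuestionSetSegment],
) -> float | np.ndarray:
    """Deception probability (softmax mass of class 1), dropout disabled."""
    single = isinstance(segments, QuestionSetSegment)
    seg_list = [segments] if single else segments
    x = np.stack([s.validate().x for s in seg_list]).astype(np.float32)
    probs = softmax(model.predict_logits(x).astype(np.float64))[:, 1]
    return float(probs[0]) if single else probs


# ---------------------------------------------------------------------------
# serialization (npz weights + embedded JSON configs)


def save_model(model: CnnLstmClassifier, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    meta = {
        "architecture": asdict(model.config),
        "seed": model.seed,
        "training_log": model.training_log,
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> CnnLstmClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arch = meta["architecture"]
        for key in ("conv_filters", "conv_kernel_sizes", "dropout_rates"):
            arch[key] = tuple(arch[key])
        model = CnnLstmClassifier(ArchitectureConfig(**arch), seed=meta["seed"])
        model.training_log = meta["training_log"]
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"param_{i}"]
    return model
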