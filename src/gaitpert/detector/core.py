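"""DeepConvLSTM binary perturbation detector.

Architecture: four temporal convolution layers (64 filters, kernel 5)
followed by two LSTM layers (128 units), dropout 0.5, flatten, a dense
layer of 64 ReLU units and a single sigmoid output neuron.  Training
minimizes class-weighted binary cross-entropy with Adam and early
stopping on validation loss (best weights restored).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import LSTM, Conv1D, Dense, Dropout, Flatten, Layer

__all__ = [
    "ModelConfig",
    "DeepConvLSTM",
    "TrainedDetector",
    "compute_class_weights",
    "build_model",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Detector hyperparameters; defaults match the reference architecture."""

    n_conv_layers: int = 4
    conv_filters: int = 64
    kernel_size: int = 5
    n_lstm_layers: int = 2
    lstm_units: int = 128
    dropout_rate: float = 0.50
    dropout_after_each_lstm: bool = False
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    target_val_loss: float = 0.0  # stop once val loss reaches this (0 = off)
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        for name in ("n_conv_layers", "conv_filters", "kernel_size",
                     "n_lstm_layers", "lstm_units", "dense_units",
                     "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def compute_class_weights(labels: Sequence) -> Dict:
    """Balanced class weights w_c = n_total / (2 * n_c) for binary labels."""
    labels = list(labels)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError(
            f"both classes must be present, got classes {classes!r}"
        )
    n = len(labels)
    return {c: n / (2.0 * labels.count(c)) for c in classes}


class DeepConvLSTM:
    """The sequential network; holds layers, optimizer state and history."""

    def __init__(self, cfg: ModelConfig, input_shape: Tuple[int, int]):
        c, m = input_shape
        if c < 1:
            raise ValueError("need at least one input channel")
        if m < cfg.kernel_size:
            raise ValueError(
                f"window length {m} is shorter than the kernel size "
                f"{cfg.kernel_size}"
            )
        self.cfg = cfg
        self.input_shape = (c, m)
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xD0]).generate_state(1)[0]
        )
        layers: List[Layer] = []
        ch = c
        for _ in range(cfg.n_conv_layers):
            layers.append(
                Conv1D(ch, cfg.conv_filters, cfg.kernel_size, "relu",
                       rng=rng, dtype=dtype)
            )
            ch = cfg.conv_filters
        for li in range(cfg.n_lstm_layers):
            layers.append(LSTM(ch, cfg.lstm_units, rng=rng, dtype=dtype))
            ch = cfg.lstm_units
            last = li == cfg.n_lstm_layers - 1
            if cfg.dropout_after_each_lstm or last:
                layers.append(Dropout(cfg.dropout_rate, rng=self._dropout_rng))
        layers.append(Flatten())
        layers.append(
            Dense(m * cfg.lstm_units, cfg.dense_units, "relu",
                  rng=rng, dtype=dtype)
        )
        layers.append(Dense(cfg.dense_units, 1, "sigmoid", rng=rng, dtype=dtype))
        self.layers = layers

    # -- plumbing ----------------------------------------------------------

    def architecture(self) -> List[Dict]:
        """Layer inventory for introspection tests and reports."""
        return [layer.describe() for layer in self.layers]

    def get_weights(self) -> List[Dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights: List[Dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k, v in w.items():
                layer.params[k] = v.copy()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    # -- passes ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, C, M) input -> (B,) pre-sigmoid logits."""
        h = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B, T, C)
        for layer in self.layers[:-1]:
            h = layer.forward(h, training=training)
        z = self.layers[-1].forward(h, training=training, logits=True)
        return z[:, 0]

    def backward(self, dz: np.ndarray) -> None:
        g = dz[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward_logits(x[i : i + batch_size], training=False)
            p = 0.5 * (np.tanh(0.5 * z.astype(np.float64)) + 1.0)
            out.append(np.clip(p, 1e-12, 1.0 - 1e-12))
        return np.concatenate(out) if out else np.empty(0)


@dataclass
class TrainedDetector:
    """A built (possibly trained) detector plus its training provenance."""

    network: DeepConvLSTM
    config: ModelConfig
    history: Dict[str, List[float]] = field(default_factory=dict)
    scaler = None  # windowing.WindowScaler, attached by the pipeline

    @property
    def input_shape(self) -> Tuple[int, int]:
        return self.network.input_shape

    def architecture(self) -> List[Dict]:
        return self.network.architecture()


def build_model(cfg: ModelConfig, input_shape: Tuple[int, int]) -> TrainedDetector:
    """Construct the seeded, untrained detector for (C, M) windows."""
    return TrainedDetector(network=DeepConvLSTM(cfg, input_shape), config=cfg)


class _Adam:
    def __init__(self, layers: Sequence[Layer], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]
        self.v = [copy.deepcopy(s) for s in self.m]

    def step(self, layers: Sequence[Layer]) -> None:
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _weighted_bce_from_logits(z, y, w):
    """Mean of w_i * BCE_i computed stably from logits."""
    per = np.logaddexp(0.0, z) - y * z
    return float(np.mean(w * per))


def train(
    detector: TrainedDetector,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    class_weights: Optional[Dict[int, float]] = None,
) -> TrainedDetector:
    """Fit with Adam on class-weighted BCE; early stop on validation loss.

    ``x_*`` are (N, C, M) standardized windows, ``y_*`` 0/1 labels with
    perturbation = 1.  Best-validation weights are restored at the end.
    """
    cfg = detector.config
    net = detector.network
    if x_val.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    if len(set(np.asarray(y_train).tolist())) < 2:
        raise ValueError("training set must contain both classes")
    exp_shape = net.input_shape
    if tuple(x_train.shape[1:]) != exp_shape:
        raise ValueError(
            f"training windows have shape {tuple(x_train.shape[1:])}, "
            f"model expects {exp_shape}"
        )
    dtype = np.dtype(cfg.dtype)
    x_train = np.asarray(x_train, dtype=dtype)
    x_val = np.asarray(x_val, dtype=dtype)
    y_train = np.asarray(y_train, dtype=dtype)
    y_val = np.asarray(y_val, dtype=dtype)
    if class_weights is None:
        class_weights = {0: 1.0, 1: 1.0}
    w_train = np.where(y_train == 1, class_weights[1], class_weights[0]).astype(dtype)

    opt = _Adam(net.layers, cfg.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x5F]).generate_state(1)[0]
    )
    n = x_train.shape[0]
    history = {"epoch": [], "loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = net.get_weights()
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb, wb = x_train[idx], y_train[idx], w_train[idx]
            z = net.forward_logits(xb, training=True)
            losses.append(_weighted_bce_from_logits(z, yb, wb))
            p = 0.5 * (np.tanh(0.5 * z) + 1.0)
            dz = (wb * (p - yb) / xb.shape[0]).astype(dtype)
            net.backward(dz)
            opt.step(net.layers)
        zv = []
        for i in range(0, x_val.shape[0], 256):
            zv.append(net.forward_logits(x_val[i : i + 256], training=False))
        zv = np.concatenate(zv)
        val_loss = _weighted_bce_from_logits(zv, y_val, np.ones_like(y_val))
        train_loss = float(np.mean(losses))
        history["epoch"].append(epoch)
        history["loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        logger.info(
            "epoch %d: loss=%.4f val_loss=%.4f", epoch, train_loss, val_loss
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = net.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
        if cfg.target_val_loss > 0 and val_loss <= cfg.target_val_loss:
            logger.info("validation loss converged at epoch %d", epoch)
            break
    net.set_weights(best_weights)
    detector.history = history
    return detector


def predict(
    detector: TrainedDetector,
    x: np.ndarray,
    threshold: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Probabilities and 0/1 labels (perturbation iff p >= threshold)."""
    exp_shape = detector.network.input_shape
    if tuple(x.shape[1:]) != exp_shape:
        raise ValueError(
            f"windows have shape {tuple(x.shape[1:])}, model expects {exp_shape}"
        )
    x = np.asarray(x, dtype=np.dtype(detector.config.dtype))
    proba = detector.network.predict_proba(x)
    labels = (proba >= threshold).astype(int)
    return labels, proba


def save_detector(detector: TrainedDetector, path_prefix: str) -> None:
    """Write weights (npz) plus a plain-text sidecar config/history."""
    arrays = {}
    for li, layer in enumerate(detector.network.layers):
        for k, v in layer.params.items():
            arrays[f"layer{li}:{k}"] = v
    np.savez(path_prefix + ".npz", **arrays)
    sidecar = {
        "config": asdict(detector.config),
        "input_shape": list(detector.network.input_shape),
        "architecture": detector.architecture(),
        "history": detector.history,
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_detector(path_prefix: str) -> TrainedDetector:
    with open(path_prefix + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig(**sidecar["config"])
    det = build_model(cfg, tuple(sidecar["input_shape"]))
    data = np.load(path_prefix + ".npz")
    for li, layer in enumerate(det.network.layers):
        for k in layer.params:
            layer.params[k] = data[f"layer{li}:{k}"]
    det.history = sidecar.get("history", {})
    return det
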