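"""Supervised stage: the 1-D CNN, the shared-weight assembly that prepends
the pretrained dense encoder, and joint end-to-end training.

Architecture (full-scale defaults)::

    input (input_dim) -> [shared encoder -> bottleneck 2000]
      -> conv(k=7, 16) [+BN] +ReLU -> maxpool 2
      -> conv(k=5, 32) [+BN] +ReLU -> maxpool 2
      -> conv(k=3, 64)      +ReLU
      -> conv(k=3, 128)     +ReLU -> maxpool 2
      -> conv(k=3, 256)     +ReLU
      -> conv(k=3, 512) [+BN] +ReLU
      -> conv(k=3, 1024) [+BN] +ReLU -> maxpool 2
      -> flatten -> dense(256) +ReLU -> dropout(0.3) -> dense(1) -> sigmoid

All convolutions are valid (no padding), stride 1; pooling uses window 2
with floor division.  Batch normalization is intentionally absent from the
middle three convolutions.  Joint training minimizes binary cross-entropy
with Adam and updates encoder and CNN parameters together.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .dae import EncoderWeights
from .errors import ConfigError, DimensionError, NumericalError

DEFAULT_CONV_SPECS: tuple[tuple[int, int], ...] = (
    (7, 16), (5, 32), (3, 64), (3, 128), (3, 256), (3, 512), (3, 1024))
DEFAULT_POOL_AFTER: tuple[int, ...] = (0, 1, 3, 6)
DEFAULT_BN_AT: tuple[int, ...] = (0, 1, 5, 6)


@dataclass(frozen=True)
class CnnConfig:
    conv_specs: tuple[tuple[int, int], ...] = DEFAULT_CONV_SPECS
    pool_after: tuple[int, ...] = DEFAULT_POOL_AFTER
    bn_at: tuple[int, ...] = DEFAULT_BN_AT
    pool_window: int = 2
    dropout_rate: float = 0.3
    fc_width: int = 256
    input_length: int = 2_000
    learning_rate: float = 0.0001
    max_epochs: int = 200
    early_stop_patience: int = 20
    batch_size: int = 32
    val_fraction: float = 1.0 / 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        specs = tuple((int(k), int(f)) for k, f in self.conv_specs)
        if not specs:
            raise ConfigError("need at least one convolution")
        if any(k < 1 or f < 1 for k, f in specs):
            raise ConfigError("kernel sizes and filter counts must be >= 1")
        n = len(specs)
        if any(not 0 <= i < n for i in self.pool_after):
            raise ConfigError("pool_after indices out of range")
        if any(not 0 <= i < n for i in self.bn_at):
            raise ConfigError("bn_at indices out of range")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0,1)")
        if self.fc_width < 1 or self.input_length < 1:
            raise ConfigError("fc_width and input_length must be positive")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be nonnegative")
        if self.pool_window < 2:
            raise ConfigError("pool_window must be >= 2")
        object.__setattr__(self, "conv_specs", specs)
        object.__setattr__(self, "pool_after",
                           tuple(sorted(set(int(i) for i in self.pool_after))))
        object.__setattr__(self, "bn_at",
                           tuple(sorted(set(int(i) for i in self.bn_at))))


def compute_output_shapes(config: CnnConfig) -> list[tuple[str, int, int]]:
    """(layer name, length, channels) for every stage through the head.

    Valid convolution: L_out = L_in - kernel + 1; pooling: L_out = L_in // w.
    Raises naming the first layer whose output length would be <= 0.
    """
    shapes: list[tuple[str, int, int]] = [("input", config.input_length, 1)]
    length, channels = config.input_length, 1
    pool_count = 0
    for i, (kernel, filters) in enumerate(config.conv_specs):
        length = length - kernel + 1
        channels = filters
        if length <= 0:
            raise ConfigError(f"conv{i} output length {length} <= 0 "
                              f"(kernel {kernel})")
        shapes.append((f"conv{i}", length, channels))
        if i in config.pool_after:
            length = length // config.pool_window
            if length <= 0:
                raise ConfigError(f"pool{pool_count} output length 0")
            shapes.append((f"pool{pool_count}", length, channels))
            pool_count += 1
    shapes.append(("fc", config.fc_width, 1))
    shapes.append(("sigmoid", 1, 1))
    return shapes


def conv_parameter_count(config: CnnConfig) -> int:
    """Closed-form parameter count of the conv stack (weights + biases)."""
    total = 0
    c_in = 1
    for kernel, filters in config.conv_specs:
        total += kernel * c_in * filters + filters
        c_in = filters
    return total


class _ToChannels(_nn.Layer):
    """(N, L) -> (N, 1, L) adapter between the dense encoder and the CNN."""

    def forward(self, x, *, training=False, rng=None):
        return x[:, None, :]

    def backward(self, grad):
        return grad[:, 0, :]


class SwnetModel:
    """End-to-end shared-weight model: encoder stage -> 1-D CNN -> sigmoid."""

    def __init__(self, encoder: EncoderWeights, config: CnnConfig) -> None:
        if encoder.bottleneck_dim != config.input_length:
            raise DimensionError(
                f"encoder bottleneck {encoder.bottleneck_dim} != CNN input "
                f"length {config.input_length}")
        compute_output_shapes(config)  # validates the arithmetic up front
        self.config = config
        self.encoder_activation = encoder.activation
        rng = np.random.default_rng(config.seed)

        enc_dense = _nn.Dense(encoder.input_dim, encoder.bottleneck_dim, rng)
        enc_dense.params["W"] = encoder.weight.copy()
        enc_dense.params["b"] = encoder.bias.copy()
        layers: list[_nn.Layer] = [enc_dense]
        act = {"relu": _nn.ReLU, "sigmoid": _nn.Sigmoid}.get(
            encoder.activation)
        if act is not None:
            layers.append(act())
        layers.append(_ToChannels())

        c_in = 1
        length = config.input_length
        for i, (kernel, filters) in enumerate(config.conv_specs):
            layers.append(_nn.Conv1d(c_in, filters, kernel, rng))
            length = length - kernel + 1
            if i in config.bn_at:
                layers.append(_nn.BatchNorm1d(filters))
            layers.append(_nn.ReLU())
            if i in config.pool_after:
                layers.append(_nn.MaxPool1d(config.pool_window))
                length //= config.pool_window
            c_in = filters
        layers.append(_nn.Flatten())
        layers.append(_nn.Dense(length * c_in, config.fc_width, rng))
        layers.append(_nn.ReLU())
        layers.append(_nn.Dropout(config.dropout_rate))
        head = _nn.Dense(config.fc_width, 1, rng)
        # small-scale head init keeps initial logits near zero, which avoids
        # confidently-wrong starts that early stopping can lock in
        head.params["W"] = head.params["W"] * 0.05
        layers.append(head)
        self.net = _nn.Sequential(layers)
        self._enc_dense = enc_dense
        self.training_log: list[dict] = []

    # -- introspection -----------------------------------------------------

    @property
    def input_dim(self) -> int:
        return self._enc_dense.n_in

    @property
    def encoder(self) -> EncoderWeights:
        return EncoderWeights(self._enc_dense.params["W"].copy(),
                              self._enc_dense.params["b"].copy(),
                              self.encoder_activation)

    # -- inference ---------------------------------------------------------

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.input_dim:
            raise DimensionError(f"expected {self.input_dim} features, "
                                 f"got {x.shape[1]}")
        out = self.net.forward(x, training=False).ravel()
        return out[0] if single else out

    def predict_proba(self, x: np.ndarray) -> float | np.ndarray:
        """Sigmoid probability P(patient); deterministic in eval mode."""
        logits = self.predict_logits(x)
        return (float(_nn.sigmoid(np.array([logits]))[0])
                if np.isscalar(logits) or np.ndim(logits) == 0
                else _nn.sigmoid(logits))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = self.net.state_arrays()
        meta = {"config": asdict(self.config),
                "encoder_activation": self.encoder_activation,
                "encoder_input_dim": self.input_dim}
        with open(path, "wb") as fh:
            np.savez(fh, model_kind="swnet", config_json=json.dumps(meta),
                     **state)

    @classmethod
    def load(cls, path: str | Path) -> "SwnetModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["config_json"]))
            cfg_dict = dict(meta["config"])
            cfg_dict["conv_specs"] = tuple(
                tuple(p) for p in cfg_dict["conv_specs"])
            config = CnnConfig(**cfg_dict)
            enc = EncoderWeights(
                np.zeros((meta["encoder_input_dim"], config.input_length)),
                np.zeros(config.input_length),
                meta["encoder_activation"])
            model = cls(enc, config)
            state = {k: npz[k] for k in npz.files
                     if k not in ("model_kind", "config_json")}
        model.net.load_state_arrays(state)
        return model


def build_swnet(enc: EncoderWeights, config: CnnConfig) -> SwnetModel:
    """Assemble the end-to-end model with the pretrained encoder prepended.

    The encoder stage is numerically identical to ``enc`` at build time;
    all CNN parameters are freshly initialized from ``config.seed``.
    """
    return SwnetModel(enc, config)


def train_joint(model: SwnetModel, features: np.ndarray, labels: np.ndarray,
                config: CnnConfig | None = None,
                val_data: tuple[np.ndarray, np.ndarray] | None = None,
                ) -> tuple[SwnetModel, list[dict]]:
    """Jointly train encoder + CNN with binary cross-entropy and Adam.

    An internal stratified validation split (``val_fraction``) drives early
    stopping unless ``val_data`` is given; the best-validation weights are
    restored on stop.  Returns the trained model and the per-epoch log.
    """
    cfg = config if config is not None else model.config
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise DimensionError("features and labels are inconsistent")
    if not np.isfinite(x).all():
        raise NumericalError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ConfigError("training requires both classes present")

    rng = np.random.default_rng(cfg.seed + 7)
    if val_data is not None:
        x_train, y_train = x, y
        x_val, y_val = (np.asarray(val_data[0], dtype=np.float64),
                        np.asarray(val_data[1]).astype(np.int64))
    else:
        x_train, y_train, x_val, y_val = _stratified_split(
            x, y, cfg.val_fraction, rng)

    opt = _nn.Adam(model.net.parameters(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state = None
    since_best = 0
    model.training_log = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:   # BN needs > 1 sample per batch
                continue
            logits = model.net.forward(x_train[idx], training=True, rng=rng)
            loss, grad = _nn.bce_with_logits_loss(logits, y_train[idx])
            model.net.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        if n_batches == 0:
            raise ConfigError("batch_size leaves no usable batches")
        val_logits = model.predict_logits(x_val)
        val_loss, _ = _nn.bce_with_logits_loss(
            np.atleast_1d(val_logits), y_val)
        val_acc = float(np.mean((np.atleast_1d(val_logits) >= 0.0) == y_val))
        model.training_log.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n_batches,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = {k: v.copy()
                          for k, v in model.net.state_arrays().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    if best_state is not None and cfg.learning_rate > 0:
        model.net.load_state_arrays(best_state)
    return model, model.training_log


def _stratified_split(x: np.ndarray, y: np.ndarray, fraction: float,
                      rng: np.random.Generator):
    """Carve a label-stratified validation subset of about ``fraction``."""
    val_idx: list[int] = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * len(cls_idx))))
        if n_val >= len(cls_idx):
            n_val = len(cls_idx) - 1
        picked = rng.permutation(cls_idx)[:n_val]
        val_idx.extend(picked.tolist())
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    return x[~val_mask], y[~val_mask], x[val_mask], y[val_mask]


def classify(prob: float, threshold: float = 0.5) -> int:
    """Binary decision; a tie at the threshold classifies as positive."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError(f"threshold must be in [0,1], got {threshold}")
    if not 0.0 <= prob <= 1.0:
        raise ConfigError(f"probability must be in [0,1], got {prob}")
    return int(prob >= threshold)


def miniature_config(input_length: int = 64, seed: int = 0,
                     **overrides) -> CnnConfig:
    """A desk-scale config with the same structural pattern as the default.

    The full seven-convolution stack needs input length >= 94 to keep every
    intermediate length positive, so the miniature keeps the leading
    conv/pool pattern (kernels 7, 5, 3; pooling after each; BN at the first
    and last convolutions, none in the middle) at a width where tests run
    in seconds.
    """
    if input_length >= 30:
        stack = dict(conv_specs=((7, 8), (5, 16), (3, 32)),
                     pool_after=(0, 1, 2), bn_at=(0, 2))
    else:  # very short inputs: two small convolutions, same BN-edges idea
        stack = dict(conv_specs=((3, 4), (3, 8)),
                     pool_after=(0, 1), bn_at=(0, 1))
    base = dict(
        fc_width=32,
        input_length=input_length,
        batch_size=16,
        seed=seed,
        **stack,
    )
    base.update(overrides)
    return CnnConfig(**base)
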