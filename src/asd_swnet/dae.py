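"""Denoising-autoencoder pretraining.

A single dense encoder (input -> bottleneck, nonlinear) and an untied
mirrored dense decoder (bottleneck -> input, linear) trained by SGD with
momentum to minimize the mean squared error between the CLEAN input and the
reconstruction of the input corrupted with additive Gaussian noise.  Noise
is redrawn every epoch.  A fraction of the training subjects is held out
internally to drive early stopping; the best-validation weights are
restored when training stops.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigError, DimensionError, NumericalError


@dataclass(frozen=True)
class DaeConfig:
    input_dim: int = 19_900
    bottleneck_dim: int = 2_000
    noise_sigma: float = 0.1
    learning_rate: float = 0.0001
    momentum: float = 0.9
    max_epochs: int = 200
    early_stop_patience: int = 20
    batch_size: int = 32
    activation: str = "relu"       # bottleneck nonlinearity
    val_fraction: float = 0.1      # internal early-stopping split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottleneck_dim >= self.input_dim:
            raise ConfigError("bottleneck_dim must be < input_dim")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be nonnegative")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigError("momentum must be in [0,1)")
        if self.max_epochs < 0:
            raise ConfigError("max_epochs must be nonnegative")
        if self.early_stop_patience < 1:
            raise ConfigError("early_stop_patience must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be positive")
        if self.activation not in ("relu", "sigmoid", "linear"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError("val_fraction must be in (0,1)")


@dataclass
class EncoderWeights:
    """Dense encoder parameters: weight (input_dim x bottleneck_dim) + bias."""

    weight: np.ndarray
    bias: np.ndarray
    activation: str

    def __post_init__(self) -> None:
        if self.weight.ndim != 2 or self.bias.ndim != 1:
            raise DimensionError("encoder weight must be 2-D, bias 1-D")
        if self.weight.shape[1] != self.bias.shape[0]:
            raise DimensionError("encoder weight/bias dims inconsistent")
        if not (np.isfinite(self.weight).all() and np.isfinite(self.bias).all()):
            raise NumericalError("non-finite encoder parameters")

    @property
    def input_dim(self) -> int:
        return self.weight.shape[0]

    @property
    def bottleneck_dim(self) -> int:
        return self.weight.shape[1]

    def copy(self) -> "EncoderWeights":
        return EncoderWeights(self.weight.copy(), self.bias.copy(),
                              self.activation)


def _activation_layer(name: str) -> _nn.Layer | None:
    if name == "relu":
        return _nn.ReLU()
    if name == "sigmoid":
        return _nn.Sigmoid()
    return None


def apply_activation(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return _nn.sigmoid(z)
    return z


def add_gaussian_noise(x: np.ndarray, sigma: float,
                       seed: int | np.random.Generator) -> np.ndarray:
    """x' = x + eps with eps ~ N(0, sigma^2) i.i.d. per component."""
    if sigma < 0:
        raise ConfigError("sigma must be nonnegative")
    x = np.asarray(x, dtype=np.float64)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return x + sigma * rng.standard_normal(x.shape)


def encode(x: np.ndarray, enc: EncoderWeights) -> np.ndarray:
    """Deterministic bottleneck activations for a vector or a batch."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != enc.input_dim:
        raise DimensionError(f"encode expects length {enc.input_dim}, "
                             f"got {x.shape[1]}")
    z = apply_activation(x @ enc.weight + enc.bias, enc.activation)
    return z[0] if single else z


class DenoisingAutoencoder:
    """Encoder + decoder pair with training state."""

    def __init__(self, config: DaeConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._enc_dense = _nn.Dense(config.input_dim, config.bottleneck_dim,
                                    rng)
        self._act = _activation_layer(config.activation)
        self._dec_dense = _nn.Dense(config.bottleneck_dim, config.input_dim,
                                    rng)
        layers: list[_nn.Layer] = [self._enc_dense]
        if self._act is not None:
            layers.append(self._act)
        layers.append(self._dec_dense)
        self.net = _nn.Sequential(layers)
        self.training_log: list[dict] = []

    # -- accessors ---------------------------------------------------------

    @property
    def encoder(self) -> EncoderWeights:
        return EncoderWeights(self._enc_dense.params["W"].copy(),
                              self._enc_dense.params["b"].copy(),
                              self.config.activation)

    @property
    def decoder_weights(self) -> tuple[np.ndarray, np.ndarray]:
        return (self._dec_dense.params["W"].copy(),
                self._dec_dense.params["b"].copy())

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        y = self.net.forward(x, training=False)
        return y[0] if single else y

    def reconstruction_mse(self, x: np.ndarray) -> float:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        loss, _ = _nn.mse_loss(self.net.forward(x, training=False), x)
        return loss

    # -- training ----------------------------------------------------------

    def fit(self, features: np.ndarray) -> list[dict]:
        """Train on (subjects x input_dim); returns the per-epoch log."""
        x = np.asarray(features, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise DimensionError(
                f"features must be (subjects, {self.config.input_dim})")
        if x.shape[0] < 2:
            raise ConfigError("need at least 2 subjects to train")
        cfg = self.config
        self.training_log = []
        if cfg.max_epochs == 0:
            return self.training_log

        rng = np.random.default_rng(cfg.seed + 1)
        n = x.shape[0]
        n_val = max(1, int(round(cfg.val_fraction * n)))
        if n_val >= n:
            n_val = n - 1
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        x_train, x_val = x[train_idx], x[val_idx]

        opt = _nn.SGDMomentum(self.net.parameters(), lr=cfg.learning_rate,
                              momentum=cfg.momentum)
        best_val = np.inf
        best_state = None
        since_best = 0
        for epoch in range(cfg.max_epochs):
            noisy = add_gaussian_noise(x_train, cfg.noise_sigma, rng)
            order = rng.permutation(len(x_train))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                pred = self.net.forward(noisy[idx], training=True, rng=rng)
                loss, grad = _nn.mse_loss(pred, x_train[idx])
                if not np.isfinite(loss):
                    raise NumericalError(f"non-finite loss at epoch {epoch}")
                self.net.backward(grad)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            val_loss = self.reconstruction_mse(x_val)
            self.training_log.append({
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                "val_loss": val_loss,
            })
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = {k: v.copy()
                              for k, v in self.net.state_arrays().items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
        if best_state is not None:
            self.net.load_state_arrays(best_state)
        return self.training_log

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = self.net.state_arrays()
        with open(path, "wb") as fh:  # file handle keeps the exact path
            np.savez(fh, model_kind="dae",
                     config_json=json.dumps(asdict(self.config)),
                     **state)

    @classmethod
    def load(cls, path: str | Path) -> "DenoisingAutoencoder":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with np.load(path, allow_pickle=False) as npz:
            config = DaeConfig(**json.loads(str(npz["config_json"])))
            model = cls(config)
            state = {k: npz[k] for k in npz.files
                     if k not in ("model_kind", "config_json")}
        model.net.load_state_arrays(state)
        return model


def train_dae(features: np.ndarray,
              config: DaeConfig) -> tuple[EncoderWeights,
                                          tuple[np.ndarray, np.ndarray],
                                          list[dict]]:
    """Convenience wrapper: build, fit, and return (encoder, decoder, log)."""
    model = DenoisingAutoencoder(config)
    log = model.fit(features)
    return model.encoder, model.decoder_weights, log
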