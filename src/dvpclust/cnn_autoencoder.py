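"""1-D convolutional autoencoder for pulse-shape feature learning.

The encoder compresses a 100-sample normalized pulse through three
conv(32)/halving-pool stages to a 13x32 map, flattens to 416 and projects
to an 8-dimensional latent code; the decoder mirrors it (dense 416, reshape
13x32, strided transposed convolution to 26, crop to 25, two
upsample+conv stages back to length 100, dense reconstruction head with a
sigmoid so outputs live in (0, 1) like the normalized input).  Training
minimizes the mean squared reconstruction error plus an L2 weight penalty
with Adam, early-stopping on validation loss and restoring the best
weights.  After training only the encoder is used, as a deterministic
8-feature extractor.

The implementation is a small self-contained NumPy layer stack with
explicit forward/backward passes; everything is seeded and CPU-friendly at
these input sizes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AEConfig",
    "ConvAutoencoder",
    "build_autoencoder",
    "train_autoencoder",
    "encode_pulses",
    "reconstruct_pulses",
]

INPUT_LEN = 100


@dataclass(frozen=True)
class AEConfig:
    latent_dim: int = 8
    conv_channels: int = 32
    n_encoder_convs: int = 3
    kernel_size: int = 3
    learning_rate: float = 1e-3
    l2_lambda: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if self.n_encoder_convs != 3:
            raise ValueError(
                "encoder/decoder geometry is fixed at 3 conv/pool stages "
                "(n_encoder_convs must be 3)"
            )


# --------------------------------------------------------------------------
# layers: forward caches what backward needs; backward returns dx and fills
# .grads aligned with .params (weights first, then bias where applicable)


def _act_forward(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _act_backward(dy: np.ndarray, z: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return dy * (z > 0)
    if kind == "sigmoid":
        return dy * y * (1.0 - y)
    return dy


class _Layer:
    params: list = []
    grads: list = []
    weight_mask: list = []  # True where the param is an L2-penalized weight

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, shape):
        return shape


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D(_Layer):
    """Same-padded 1-D convolution over (batch, length, channels)."""

    def __init__(self, cin: int, cout: int, k: int, activation: str, rng: np.random.Generator):
        self.k, self.cin, self.cout, self.activation = k, cin, cout, activation
        self.W = _glorot(rng, (k, cin, cout), k * cin, k * cout)
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.weight_mask = [True, False]

    def forward(self, x):
        B, L, _ = x.shape
        pad = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        z = np.zeros((B, L, self.cout))
        for t in range(self.k):
            z += xp[:, t : t + L] @ self.W[t]
        z += self.b
        y = _act_forward(z, self.activation)
        self._cache = (xp, z, y, L, pad)
        return y

    def backward(self, dy):
        xp, z, y, L, pad = self._cache
        dz = _act_backward(dy, z, y, self.activation)
        self.grads[1][:] = dz.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for t in range(self.k):
            self.grads[0][t] = np.einsum("blc,blo->co", xp[:, t : t + L], dz)
            dxp[:, t : t + L] += dz @ self.W[t].T
        return dxp[:, pad : pad + L]

    def out_shape(self, shape):
        return (shape[0], self.cout)


class MaxPool2(_Layer):
    """Halving max-pool with same-style padding (ceil length, -inf pad)."""

    def forward(self, x):
        B, L, C = x.shape
        Lp = L + (L % 2)
        if Lp != L:
            x = np.pad(x, ((0, 0), (0, 1), (0, 0)), constant_values=-np.inf)
        xr = x.reshape(B, Lp // 2, 2, C)
        self._idx = np.argmax(xr, axis=2)
        self._in_len = L
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, L2, C = dy.shape
        dxr = np.zeros((B, L2, 2, C))
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = dxr.reshape(B, 2 * L2, C)
        return dx[:, : self._in_len]

    def out_shape(self, shape):
        return ((shape[0] + 1) // 2, shape[1])


class UpSample2(_Layer):
    def forward(self, x):
        return np.repeat(x, 2, axis=1)

    def backward(self, dy):
        return dy[:, 0::2] + dy[:, 1::2]

    def out_shape(self, shape):
        return (2 * shape[0], shape[1])


class ZeroStuff2(_Layer):
    """Doubles the length by interleaving zeros (transposed-conv stride-2 core)."""

    def forward(self, x):
        B, L, C = x.shape
        z = np.zeros((B, 2 * L, C))
        z[:, 0::2] = x
        return z

    def backward(self, dy):
        return dy[:, 0::2]

    def out_shape(self, shape):
        return (2 * shape[0], shape[1])


class CropEnd(_Layer):
    def __init__(self, n: int = 1):
        self.n = n

    def forward(self, x):
        return x[:, : x.shape[1] - self.n]

    def backward(self, dy):
        return np.pad(dy, ((0, 0), (0, self.n), (0, 0)))

    def out_shape(self, shape):
        return (shape[0] - self.n, shape[1])


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, shape):
        return (shape[0] * shape[1],)


class Reshape(_Layer):
    def __init__(self, length: int, channels: int):
        self.length, self.channels = length, channels

    def forward(self, x):
        return x.reshape(x.shape[0], self.length, self.channels)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)

    def out_shape(self, shape):
        return (self.length, self.channels)


class Dense(_Layer):
    def __init__(self, nin: int, nout: int, activation: str, rng: np.random.Generator):
        self.activation = activation
        self.W = _glorot(rng, (nin, nout), nin, nout)
        self.b = np.zeros(nout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.weight_mask = [True, False]

    def forward(self, x):
        z = x @ self.W + self.b
        y = _act_forward(z, self.activation)
        self._cache = (x, z, y)
        return y

    def backward(self, dy):
        x, z, y = self._cache
        dz = _act_backward(dy, z, y, self.activation)
        self.grads[0][:] = x.T @ dz
        self.grads[1][:] = dz.sum(axis=0)
        return dz @ self.W.T

    def out_shape(self, shape):
        return (self.W.shape[1],)


class ConvAutoencoder:
    """Layer stack with an encoder prefix; see module docstring for geometry."""

    def __init__(self, config: AEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch, k = config.conv_channels, config.kernel_size

        enc: list[_Layer] = []
        cin = 1
        for _ in range(config.n_encoder_convs):
            enc.append(Conv1D(cin, ch, k, "relu", rng))
            enc.append(MaxPool2())
            cin = ch
        enc.append(Flatten())
        # trace the encoder shape to size the bottleneck dense layer
        shape: tuple = (INPUT_LEN, 1)
        for layer in enc:
            shape = layer.out_shape(shape)
        flat_width = shape[0]
        enc.append(Dense(flat_width, config.latent_dim, "linear", rng))

        pooled_len = INPUT_LEN
        for _ in range(config.n_encoder_convs):
            pooled_len = (pooled_len + 1) // 2
        if flat_width != pooled_len * ch:
            raise ValueError(
                f"encoder Flatten width {flat_width} inconsistent with "
                f"{pooled_len}x{ch} feature map"
            )

        dec: list[_Layer] = [
            Dense(config.latent_dim, flat_width, "relu", rng),
            Reshape(pooled_len, ch),
            ZeroStuff2(),
            Conv1D(ch, ch, k, "relu", rng),  # transposed conv, stride 2 -> 26
            CropEnd(2 * pooled_len - INPUT_LEN // 4),  # 26 -> 25
            UpSample2(),
            Conv1D(ch, ch, k, "relu", rng),
            UpSample2(),
            Conv1D(ch, ch, k, "relu", rng),
            Flatten(),
            Dense(INPUT_LEN * ch, INPUT_LEN, "sigmoid", rng),
        ]
        self.layers: list[_Layer] = enc + dec
        self.n_encoder_layers = len(enc)

    # -- shape audit -------------------------------------------------------
    def layer_output_shapes(self, input_len: int = INPUT_LEN) -> list[tuple]:
        shape: tuple = (input_len, 1)
        out = []
        for layer in self.layers:
            shape = layer.out_shape(shape)
            out.append(shape)
        return out

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, :, None]
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = x[:, :, None]
        for layer in self.layers[: self.n_encoder_layers]:
            h = layer.forward(h)
        return h

    def backward(self, dloss_dout: np.ndarray) -> None:
        g = dloss_dout
        for layer in reversed(self.layers):
            g = layer.backward(g)

    # -- parameters --------------------------------------------------------
    def parameters(self):
        for layer in self.layers:
            for p, g, is_w in zip(layer.params, layer.grads, layer.weight_mask):
                yield p, g, is_w

    def get_weights(self):
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights):
        for layer, saved in zip(self.layers, weights):
            for p, s in zip(layer.params, saved):
                p[:] = s

    def l2_penalty(self) -> float:
        lam = self.config.l2_lambda
        return lam * sum(float(np.sum(p**2)) for p, _, is_w in self.parameters() if is_w)


def build_autoencoder(config: AEConfig | None = None) -> ConvAutoencoder:
    """Construct the (seeded) autoencoder; raises on inconsistent geometry."""
    return ConvAutoencoder(config or AEConfig())


class _Adam:
    def __init__(self, model: ConvAutoencoder, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _, _ in model.parameters()]

    def step(self, model: ConvAutoencoder) -> None:
        self.t += 1
        lam = model.config.l2_lambda
        for i, (p, g, is_w) in enumerate(model.parameters()):
            grad = g + (2.0 * lam * p if is_w else 0.0)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batched_mse(model: ConvAutoencoder, X: np.ndarray, chunk: int = 256) -> float:
    tot = 0.0
    for i in range(0, len(X), chunk):
        xb = X[i : i + chunk]
        rec = model.forward(xb)
        tot += float(np.sum((rec - xb) ** 2))
    return tot / X.size


def train_autoencoder(
    model: ConvAutoencoder,
    train_pulses: np.ndarray,
    val_pulses: np.ndarray,
    config: AEConfig | None = None,
) -> tuple[ConvAutoencoder, dict]:
    """Adam training with early stopping on validation reconstruction MSE.

    Returns the model with the best-validation weights restored and a
    history dict (per-epoch train loss incl. L2 penalty, validation MSE,
    best epoch).  Raises ``RuntimeError`` on NaN loss.
    """
    config = config or model.config
    X = np.asarray(train_pulses, dtype=float)
    V = np.asarray(val_pulses, dtype=float)
    if X.ndim != 2 or X.shape[1] != INPUT_LEN:
        raise ValueError(f"train pulses must be (n, {INPUT_LEN})")
    if V.ndim != 2 or V.shape[1] != INPUT_LEN:
        raise ValueError(f"val pulses must be (n, {INPUT_LEN})")

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model, config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val, best_weights, best_epoch, wait = np.inf, None, -1, 0

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(X))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(X), config.batch_size):
            xb = X[perm[start : start + config.batch_size]]
            rec = model.forward(xb)
            mse = float(np.mean((rec - xb) ** 2))
            loss = mse + model.l2_penalty()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(mse={mse}); try a lower learning rate"
                )
            model.backward(2.0 * (rec - xb) / rec.size)
            opt.step(model)
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / n_batches)

        val_mse = _batched_mse(model, V)
        history["val_loss"].append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val, best_epoch, wait = val_mse, epoch, 0
            best_weights = model.get_weights()
        else:
            wait += 1
            if wait >= config.patience:
                break

    if best_weights is not None:
        model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return model, history


def encode_pulses(model: ConvAutoencoder, pulses: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Latent features (n, latent_dim) of normalized pulses; deterministic."""
    X = np.asarray(pulses, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != INPUT_LEN:
        raise ValueError(f"pulses must have length {INPUT_LEN}")
    return np.vstack([model.encode(X[i : i + chunk]) for i in range(0, len(X), chunk)])


def reconstruct_pulses(model: ConvAutoencoder, pulses: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Round-trip reconstructions of normalized pulses."""
    X = np.asarray(pulses, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != INPUT_LEN:
        raise ValueError(f"pulses must have length {INPUT_LEN}")
    return np.vstack([model.forward(X[i : i + chunk]) for i in range(0, len(X), chunk)])
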