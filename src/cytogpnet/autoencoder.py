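"""Cell-level autoencoder providing the q-dimensional latent embedding.

The encoder is a small MLP applied independently to each cell; the decoder
mirrors the encoder's layer widths in reverse (no weight tying) and ends in
a linear output layer, since the targets are real-valued arcsinh-scale
intensities.  Pretraining minimizes mean squared reconstruction error over
all cells pooled across subjects and timepoints; outcome labels are never
part of this stage, so the vast cell count can be exploited even when the
number of subjects is small.

Defaults follow the cytometry setting: one hidden layer of 16 units, latent
dimension 4, Adam with batch size 128 and learning rate 1e-6 for 1000
epochs.  The scRNA-seq variant widens the encoder to hidden layers
[256, 64, 16] and pretrains with batch size 256, learning rate 1e-3, 200
epochs.  At synthetic-benchmark scale these schedules are far longer than
needed; pass smaller ``epochs``/larger ``lr`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, tensor
from .data import ParameterError


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; try a smaller learning rate."""


@dataclass
class AEConfig:
    input_dim: int = 10
    hidden_dims: tuple[int, ...] = (16,)
    latent_dim: int = 4
    activation: str = "relu"  # {relu, tanh, linear}
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim >= self.input_dim:
            raise ParameterError("latent_dim must be < input_dim")
        if any(w < 1 for w in self.hidden_dims):
            raise ParameterError("all hidden widths must be >= 1")
        if self.activation not in {"relu", "tanh", "linear"}:
            raise ParameterError(f"unknown activation {self.activation!r}")

    @classmethod
    def for_scrnaseq(cls, input_dim: int, seed: int = 0) -> "AEConfig":
        return cls(input_dim=input_dim, hidden_dims=(256, 64, 16), latent_dim=4, seed=seed)


@dataclass
class AEParams:
    """Encoder/decoder weights; layers stored as (W, b) Tensor pairs."""

    config: AEConfig
    encoder: list[tuple[Tensor, Tensor]] = field(default_factory=list)
    decoder: list[tuple[Tensor, Tensor]] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        return [t for layer in self.encoder + self.decoder for t in layer]

    def state_arrays(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.parameters()]


def _init_layer(rng, fan_in: int, fan_out: int) -> tuple[Tensor, Tensor]:
    scale = np.sqrt(2.0 / fan_in)
    W = tensor(rng.normal(0.0, scale, size=(fan_in, fan_out)), requires_grad=True)
    b = tensor(np.zeros(fan_out), requires_grad=True)
    return W, b


def init_params(config: AEConfig) -> AEParams:
    """Seeded fan-in-scaled random initialization."""
    rng = np.random.default_rng(config.seed)
    enc_dims = [config.input_dim, *config.hidden_dims, config.latent_dim]
    dec_dims = list(reversed(enc_dims))  # symmetric: reversed widths
    params = AEParams(config=config)
    for a, b in zip(enc_dims[:-1], enc_dims[1:]):
        params.encoder.append(_init_layer(rng, a, b))
    for a, b in zip(dec_dims[:-1], dec_dims[1:]):
        params.decoder.append(_init_layer(rng, a, b))
    return params


def _act(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    return x


def encode_t(X: Tensor, params: AEParams) -> Tensor:
    """Differentiable encoder; row i of the output depends only on row i of X."""
    h = X
    layers = params.encoder
    for i, (W, b) in enumerate(layers):
        h = h @ W + b
        if i < len(layers) - 1:
            h = _act(h, params.config.activation)
    return h  # linear latent layer


def decode_t(H: Tensor, params: AEParams) -> Tensor:
    x = H
    layers = params.decoder
    for i, (W, b) in enumerate(layers):
        x = x @ W + b
        if i < len(layers) - 1:
            x = _act(x, params.config.activation)
    return x  # linear reconstruction layer


def encode(X: np.ndarray, params: AEParams) -> np.ndarray:
    """Cells x p -> cells x q latent embedding (numpy in, numpy out)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != params.config.input_dim:
        raise ParameterError(
            f"expected {params.config.input_dim} markers, got {X.shape[1]}"
        )
    if X.shape[0] == 0:
        return np.empty((0, params.config.latent_dim))
    return encode_t(tensor(X), params).data


def decode(H: np.ndarray, params: AEParams) -> np.ndarray:
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if H.shape[1] != params.config.latent_dim:
        raise ParameterError(
            f"expected latent dim {params.config.latent_dim}, got {H.shape[1]}"
        )
    if H.shape[0] == 0:
        return np.empty((0, params.config.input_dim))
    return decode_t(tensor(H), params).data


def reconstruction_mse(X: np.ndarray, params: AEParams) -> float:
    """Mean over cells of the squared reconstruction error (1/M) sum ||x - x~||^2."""
    Xr = decode(encode(X, params), params)
    return float(np.sum((X - Xr) ** 2) / X.shape[0])


def pretrain(
    X: np.ndarray,
    config: AEConfig,
    epochs: int = 1000,
    batch_size: int = 128,
    lr: float = 1e-6,
    seed: int | None = None,
) -> tuple[AEParams, list[float]]:
    """Pretrain by reconstruction on all cells pooled across samples.

    Returns the parameters and the per-epoch training loss history
    (mean squared reconstruction error over the epoch's batches).
    No outcome labels enter this function.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] < 1:
        raise ParameterError("pretraining needs at least one cell")
    if seed is not None:
        config = AEConfig(**{**config.__dict__, "seed": seed})
    params = init_params(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(params.parameters(), lr=lr)
    M = X.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(M)
        epoch_loss, nb = 0.0, 0
        for start in range(0, M, batch_size):
            idx = order[start : start + batch_size]
            xb = tensor(X[idx])
            rec = decode_t(encode_t(xb, params), params)
            loss = ((rec - xb) ** 2).sum() / float(len(idx))
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    "non-finite reconstruction loss; reduce the learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            nb += 1
        history.append(epoch_loss / nb)
    return params, history
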