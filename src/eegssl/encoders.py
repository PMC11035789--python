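"""Trainable feature extractor h_theta / g_enc and the autoregressive
context model g_ar.

The default raw-window encoder is a temporal convolution bank followed
by log-energy pooling — a learnable analogue of log band power, which
is the natural sufficient statistic for signals whose classes differ
in per-band variance:

    frames  = im2col(window; kernel, stride)          # (C*k, n_frames)
    conv    = W1 @ frames + b1                        # (F filters)
    pooled  = log(mean_t conv^2 + eps)                # per-filter log energy
    z       = tanh(W2 @ pooled + b2)                  # (D,)

Each filter acts as a learned FIR band-pass; its pooled log energy is
a differential-entropy-like feature. A small MLP variant handles
precomputed DE-feature inputs. The context model is a single-layer
GRU, causal by construction: c_t depends only on z_{<=t}.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn.autodiff import Tensor

__all__ = [
    "EncoderConfig",
    "WindowEncoder",
    "GRUContext",
    "encode",
    "contextualize",
    "save_checkpoint",
    "load_checkpoint",
]

_POOL_EPS = 1e-8


@dataclass
class EncoderConfig:
    """Architecture of the window encoder.

    ``input_mode="raw_window"`` consumes (C, T) raw windows through the
    conv/log-energy stack; ``"de_feature"`` consumes flat DE feature
    vectors through a one-hidden-layer MLP.
    """

    input_mode: str = "raw_window"
    embedding_dim: int = 32
    n_filters: int = 24
    kernel_size: int = 33
    stride: int = 8
    hidden_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in ("raw_window", "de_feature"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class WindowEncoder:
    """Maps windows (or DE feature vectors) to D-dimensional embeddings."""

    def __init__(self, config: EncoderConfig, input_shape: tuple[int, ...]):
        self.config = config
        self.input_shape = tuple(int(s) for s in input_shape)
        rng = np.random.default_rng(config.seed)
        D = config.embedding_dim
        if config.input_mode == "raw_window":
            C, T = self.input_shape
            k, s = config.kernel_size, config.stride
            if k > T:
                raise ValueError("kernel longer than window")
            self.n_frames = (T - k) // s + 1
            F = config.n_filters
            self.W1 = Tensor(_glorot(rng, F, C * k), requires_grad=True)
            self.b1 = Tensor(np.zeros((F, 1)), requires_grad=True)
            self.W2 = Tensor(_glorot(rng, D, F), requires_grad=True)
            self.b2 = Tensor(np.zeros((D, 1)), requires_grad=True)
        else:
            (F_in,) = self.input_shape
            H = config.hidden_dim
            self.W1 = Tensor(_glorot(rng, H, F_in), requires_grad=True)
            self.b1 = Tensor(np.zeros((H, 1)), requires_grad=True)
            self.W2 = Tensor(_glorot(rng, D, H), requires_grad=True)
            self.b2 = Tensor(np.zeros((D, 1)), requires_grad=True)

    @property
    def embedding_dim(self) -> int:
        return self.config.embedding_dim

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, C, T) -> (C*k, B*n_frames), strided frames stacked."""
        k, s = self.config.kernel_size, self.config.stride
        sw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        B, C, nf, _ = sw.shape
        # (B,C,nf,k) -> (C,k,B,nf) -> (C*k, B*nf)
        return np.ascontiguousarray(sw.transpose(1, 3, 0, 2)).reshape(C * k, B * nf)

    def forward(self, x: np.ndarray) -> Tensor:
        """Encode a batch; returns embeddings as a (D, B) tensor."""
        x = np.asarray(x, dtype=float)
        if x.shape[1:] != self.input_shape:
            if x.shape == self.input_shape:  # single sample
                x = x[None]
            else:
                raise ValueError(
                    f"input shape {x.shape[1:]} != expected {self.input_shape}")
        B = x.shape[0]
        if self.config.input_mode == "raw_window":
            A = self._im2col(x)                        # (C*k, B*nf)
            conv = self.W1 @ Tensor(A) + self.b1       # (F, B*nf)
            F = self.config.n_filters
            energy = conv.square().reshape(F, B, self.n_frames).mean(axis=2)
            pooled = (energy + _POOL_EPS).log()        # (F, B)
            return (self.W2 @ pooled + self.b2).tanh()
        h = (self.W1 @ Tensor(x.T) + self.b1).relu()
        return (self.W2 @ h + self.b2).tanh()

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        """Inference path: embeddings as a plain (B, D) array."""
        return self.forward(x).data.T.copy()

    # -- persistence ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.data, "b1": self.b1.data,
                "W2": self.W2.data, "b2": self.b2.data}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in ("W1", "b1", "W2", "b2"):
            param = getattr(self, name)
            if param.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            param.data = np.array(state[name], dtype=float)


class GRUContext:
    """Single-layer GRU producing causal context vectors c_t = g_ar(z_<=t)."""

    def __init__(self, input_dim: int, hidden_dim: int | None = None,
                 seed: int = 0):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim if hidden_dim is not None else input_dim
        rng = np.random.default_rng(seed + 1)
        D, H = self.input_dim, self.hidden_dim
        self.Wz = Tensor(_glorot(rng, H, D), requires_grad=True)
        self.Wr = Tensor(_glorot(rng, H, D), requires_grad=True)
        self.Wn = Tensor(_glorot(rng, H, D), requires_grad=True)
        self.Uz = Tensor(_glorot(rng, H, H), requires_grad=True)
        self.Ur = Tensor(_glorot(rng, H, H), requires_grad=True)
        self.Un = Tensor(_glorot(rng, H, H), requires_grad=True)
        self.bz = Tensor(np.zeros((H, 1)), requires_grad=True)
        self.br = Tensor(np.zeros((H, 1)), requires_grad=True)
        self.bn = Tensor(np.zeros((H, 1)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.Wz, self.Wr, self.Wn, self.Uz, self.Ur, self.Un,
                self.bz, self.br, self.bn]

    def step(self, z_t: Tensor, h: Tensor) -> Tensor:
        """One GRU update; z_t is (D, B), h is (H, B)."""
        u = (self.Wz @ z_t + self.Uz @ h + self.bz).sigmoid()
        r = (self.Wr @ z_t + self.Ur @ h + self.br).sigmoid()
        n = (self.Wn @ z_t + self.Un @ (r * h) + self.bn).tanh()
        return (Tensor(1.0) - u) * h + u * n

    def forward(self, z_steps: list[Tensor], batch_size: int) -> list[Tensor]:
        """Run over a sequence of (D, B) tensors; returns all c_t."""
        if not z_steps:
            raise ValueError("empty sequence")
        h = Tensor(np.zeros((self.hidden_dim, batch_size)))
        outputs = []
        for z_t in z_steps:
            h = self.step(z_t, h)
            outputs.append(h)
        return outputs

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ("Wz", "Wr", "Wn", "Uz", "Ur", "Un", "bz", "br", "bn")
        return {n: getattr(self, n).data for n in names}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, arr in state.items():
            getattr(self, n).data = np.array(arr, dtype=float)


def encode(x: np.ndarray, encoder: WindowEncoder) -> np.ndarray:
    """Embed one window or a batch; returns (D,) or (B, D) array."""
    x = np.asarray(x, dtype=float)
    single = x.shape == encoder.input_shape
    out = encoder.encode_array(x[None] if single else x)
    return out[0] if single else out


def contextualize(z_sequence: np.ndarray, context_model: GRUContext
                  ) -> np.ndarray:
    """Run g_ar over an (L, D) embedding sequence; returns (L, H)."""
    z_sequence = np.asarray(z_sequence, dtype=float)
    if z_sequence.ndim != 2 or z_sequence.shape[0] < 1:
        raise ValueError("z_sequence must be a non-empty (L, D) matrix")
    steps = [Tensor(z[:, None]) for z in z_sequence]
    outs = context_model.forward(steps, batch_size=1)
    return np.stack([o.data[:, 0] for o in outs], axis=0)


def save_checkpoint(path: str | Path, encoder: WindowEncoder,
                    context: GRUContext | None = None,
                    extras: dict[str, np.ndarray] | None = None) -> None:
    """Persist encoder (+ optional context model and extras) to .npz."""
    arrays: dict[str, np.ndarray] = {}
    meta = {"encoder_config": asdict(encoder.config),
            "input_shape": list(encoder.input_shape),
            "has_context": context is not None}
    for k, v in encoder.state_dict().items():
        arrays[f"enc_{k}"] = v
    if context is not None:
        meta["context"] = {"input_dim": context.input_dim,
                           "hidden_dim": context.hidden_dim}
        for k, v in context.state_dict().items():
            arrays[f"ctx_{k}"] = v
    for k, v in (extras or {}).items():
        arrays[f"extra_{k}"] = v
    arrays["_meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path
                    ) -> tuple[WindowEncoder, GRUContext | None,
                               dict[str, np.ndarray]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        encoder = WindowEncoder(EncoderConfig(**meta["encoder_config"]),
                                tuple(meta["input_shape"]))
        encoder.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("enc_")})
        context = None
        if meta["has_context"]:
            context = GRUContext(**meta["context"])
            context.load_state_dict(
                {k[4:]: data[k] for k in data.files if k.startswith("ctx_")})
        extras = {k[6:]: data[k] for k in data.files if k.startswith("extra_")}
    return encoder, context, extras
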