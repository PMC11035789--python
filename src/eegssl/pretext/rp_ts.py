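"""Relative-positioning and temporal-shuffling pretext training.

Both tasks train the shared window encoder h_theta with a linear
contrastive head on absolute-difference features:

    RP:  g_RP(h, h')      = |h - h'|                       in R^D
    TS:  g_TS(h, h', h'') = (|h - h'|, |h' - h''|)         in R^2D

and the logistic loss over pseudo-labels y in {-1, +1}:

    L(theta, w, w0) = sum_i log(1 + exp(-y_i [w^T g_i + w0]))

The models follow the package's Model/Results convention: construct
from segmented windows plus configs, call ``fit()``, get a Results
object with the loss curve, the trained encoder/head, and held-out
pretext accuracy helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..encoders import EncoderConfig, WindowEncoder
from ..nn.autodiff import Tensor, concat
from ..nn.optim import Adam
from ..preprocessing import WindowSet
from .sampling import (RPSample, RPSamplerConfig, TSTriple,
                       sample_rp_dataset, sample_ts_dataset)

__all__ = [
    "g_rp", "g_ts", "logistic_loss", "PretextTrainConfig",
    "RelativePositioningModel", "TemporalShufflingModel",
    "PretextResults",
]


def g_rp(h: np.ndarray, h_prime: np.ndarray) -> np.ndarray:
    """Elementwise |h - h'|; symmetric in its arguments."""
    h, h_prime = np.asarray(h, dtype=float), np.asarray(h_prime, dtype=float)
    if h.shape != h_prime.shape:
        raise ValueError("g_rp: embedding shapes differ")
    return np.abs(h - h_prime)


def g_ts(h: np.ndarray, h_prime: np.ndarray, h_dprime: np.ndarray
         ) -> np.ndarray:
    """Concatenated absolute differences (|h-h'|, |h'-h''|) in R^{2D}."""
    h = np.asarray(h, dtype=float)
    h_prime = np.asarray(h_prime, dtype=float)
    h_dprime = np.asarray(h_dprime, dtype=float)
    if not (h.shape == h_prime.shape == h_dprime.shape):
        raise ValueError("g_ts: embedding shapes differ")
    return np.concatenate([np.abs(h - h_prime), np.abs(h_prime - h_dprime)],
                          axis=-1)


def logistic_loss(features: np.ndarray, labels: np.ndarray,
                  w: np.ndarray, w0: float) -> float:
    """Sum_i log(1 + exp(-y_i (w.g_i + w0))) over a sample set.

    Zero score gives ln 2 per sample; the loss decreases monotonically
    in the margin y * score.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=float)
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise ValueError("labels must be in {-1, +1}")
    scores = features @ np.asarray(w, dtype=float).ravel() + w0
    return float(np.logaddexp(0.0, -labels * scores).sum())


@dataclass
class PretextTrainConfig:
    """Optimization settings shared by the RP and TS models."""

    epochs: int = 10
    batch_size: int = 64
    lr: float = 2e-3
    seed: int = 0


@dataclass
class PretextResults:
    """Outcome of RP/TS pretraining."""

    task: str
    encoder: WindowEncoder
    head_w: np.ndarray
    head_w0: float
    loss_curve: np.ndarray          # mean per-sample loss per epoch
    initial_loss: float             # mean per-sample loss before training
    final_loss: float
    n_samples: int
    sampler_config: RPSamplerConfig = None
    train_config: PretextTrainConfig = None

    def predict_scores(self, model: "_PairTripleModel",
                       samples: list) -> np.ndarray:
        feats = model._features_array(self.encoder, samples)
        return feats @ self.head_w + self.head_w0

    def pretext_accuracy(self, model: "_PairTripleModel",
                         samples: list) -> float:
        """Fraction of samples whose score sign matches the label."""
        scores = self.predict_scores(model, samples)
        y = np.array([s.y for s in samples], dtype=float)
        return float(np.mean(np.sign(scores) == y))

    def summary(self) -> str:
        lines = [
            f"{self.task} pretext training",
            "=" * 34,
            f"samples                 {self.n_samples}",
            f"epochs                  {len(self.loss_curve)}",
            f"initial loss / sample   {self.initial_loss:.4f}",
            f"final loss / sample     {self.final_loss:.4f}",
        ]
        return "\n".join(lines)


class _PairTripleModel:
    """Shared machinery for the RP and TS models."""

    task = ""

    def __init__(self, window_sets: list[WindowSet],
                 sampler_config: RPSamplerConfig | None = None,
                 encoder_config: EncoderConfig | None = None,
                 train_config: PretextTrainConfig | None = None):
        if not window_sets:
            raise ValueError("no windows supplied")
        self.window_sets = window_sets
        self.sampler_config = sampler_config or RPSamplerConfig()
        self.encoder_config = encoder_config or EncoderConfig()
        self.train_config = train_config or PretextTrainConfig()
        C, T = window_sets[0].windows.shape[1:]
        self._input_shape = (C, T)
        self._starts_per_trial = [np.arange(ws.n_windows)
                                  for ws in window_sets]

    # -- subclass hooks -------------------------------------------------

    def _draw_samples(self, config: RPSamplerConfig) -> list:
        raise NotImplementedError

    def _window_ids(self, s) -> tuple[int, ...]:
        raise NotImplementedError

    def _combine(self, hs: list[Tensor]) -> Tensor:
        raise NotImplementedError

    @property
    def _head_dim(self) -> int:
        raise NotImplementedError

    # -- shared ---------------------------------------------------------

    def _gather_windows(self, samples: list) -> np.ndarray:
        """(n_views, B, C, T) raw windows for a list of samples."""
        views = len(self._window_ids(samples[0]))
        out = np.empty((views, len(samples), *self._input_shape))
        for i, s in enumerate(samples):
            ids = self._window_ids(s)
            ws = self.window_sets[s.trial]
            for v, t in enumerate(ids):
                out[v, i] = ws.windows[t]
        return out

    def _batch_loss(self, encoder: WindowEncoder, w: Tensor, w0: Tensor,
                    samples: list) -> Tensor:
        views = self._gather_windows(samples)
        n_views, B = views.shape[0], views.shape[1]
        stacked = views.reshape(n_views * B, *self._input_shape)
        H = encoder.forward(stacked)          # (D, n_views*B)
        hs = [Tensor.take(H, np.arange(v * B, (v + 1) * B), axis=1)
              for v in range(n_views)]
        g = self._combine(hs)                 # (F, B)
        y = np.array([s.y for s in samples], dtype=float)[None, :]
        score = w @ g + w0                    # (1, B)
        margin = Tensor(-y) * score
        return margin.softplus().mean()

    def _features_array(self, encoder: WindowEncoder, samples: list
                        ) -> np.ndarray:
        views = self._gather_windows(samples)
        n_views, B = views.shape[0], views.shape[1]
        stacked = views.reshape(n_views * B, *self._input_shape)
        Hv = encoder.encode_array(stacked)    # (n_views*B, D)
        hs = [Hv[v * B:(v + 1) * B] for v in range(n_views)]
        if n_views == 2:
            return g_rp(hs[0], hs[1])
        return g_ts(hs[0], hs[1], hs[2])

    def fit(self, encoder: WindowEncoder | None = None) -> PretextResults:
        """Pretrain the encoder + linear head on a fixed sample set."""
        cfg = self.train_config
        rng = np.random.default_rng(cfg.seed)
        samples = self._draw_samples(self.sampler_config)
        encoder = encoder or WindowEncoder(self.encoder_config,
                                           self._input_shape)
        w = Tensor(np.zeros((1, self._head_dim)), requires_grad=True)
        w0 = Tensor(np.zeros((1, 1)), requires_grad=True)
        opt = Adam(encoder.parameters() + [w, w0], lr=cfg.lr)

        initial = float(self._batch_loss(encoder, w, w0, samples).data)
        curve = []
        order = np.arange(len(samples))
        for _ in range(cfg.epochs):
            rng.shuffle(order)
            losses = []
            for lo in range(0, len(order), cfg.batch_size):
                batch = [samples[i] for i in order[lo:lo + cfg.batch_size]]
                loss = self._batch_loss(encoder, w, w0, batch)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"{self.task}: non-finite loss at epoch "
                        f"{len(curve)}, sample offset {lo}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data) * len(batch))
            curve.append(sum(losses) / len(samples))
        final = float(self._batch_loss(encoder, w, w0, samples).data)
        return PretextResults(
            task=self.task, encoder=encoder, head_w=w.data.ravel().copy(),
            head_w0=float(w0.data.ravel()[0]), loss_curve=np.array(curve),
            initial_loss=initial, final_loss=final,
            n_samples=len(samples), sampler_config=self.sampler_config,
            train_config=cfg)

    def draw_eval_samples(self, n: int, seed: int) -> list:
        """Fresh sample set (e.g., for held-out pretext accuracy)."""
        cfg = RPSamplerConfig(tau_pos=self.sampler_config.tau_pos,
                              tau_neg=self.sampler_config.tau_neg,
                              n_samples=n, seed=seed)
        return self._draw_samples(cfg)


class RelativePositioningModel(_PairTripleModel):
    """RP pretext task: near-vs-far window pairs, |h-h'| head."""

    task = "RP"

    def _draw_samples(self, config):
        return sample_rp_dataset(self._starts_per_trial, config)

    def _window_ids(self, s: RPSample):
        return (s.t, s.t_prime)

    def _combine(self, hs):
        return (hs[0] - hs[1]).abs()

    @property
    def _head_dim(self):
        return self.encoder_config.embedding_dim


class TemporalShufflingModel(_PairTripleModel):
    """TS pretext task: ordered-vs-shuffled triples, (|h-h'|,|h'-h''|)."""

    task = "TS"

    def _draw_samples(self, config):
        return sample_ts_dataset(self._starts_per_trial, config)

    def _window_ids(self, s: TSTriple):
        return (s.t, s.t_prime, s.t_dprime)

    def _combine(self, hs):
        return concat([(hs[0] - hs[1]).abs(), (hs[1] - hs[2]).abs()], axis=0)

    @property
    def _head_dim(self):
        return 2 * self.encoder_config.embedding_dim
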