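"""Contrastive predictive coding over window sequences.

The encoder g_enc embeds each window as z_t; a GRU g_ar summarizes
z_{<=t} into a context c_t. For each prediction step k = 1..K a
log-bilinear scorer

    f_k(x_{t+k}, c_t) = exp(z_{t+k}^T W_k c_t)

rates candidate futures, and the InfoNCE objective

    L_N = -E[ log( f_k(x_{t+k}, c_t) / sum_{x_j in X} f_k(x_j, c_t) ) ]

is the categorical cross-entropy of picking the true future among
N candidates (1 positive + N-1 negatives drawn uniformly from the
whole dataset). All scoring is done in log space; exp(z^T W c) itself
is never materialized during training. Minimizing L_N maximizes a
lower bound on the mutual information between context and future.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as spsp

from ..encoders import EncoderConfig, GRUContext, WindowEncoder
from ..nn.autodiff import Tensor
from ..nn.optim import Adam
from ..preprocessing import WindowSet

__all__ = [
    "CPCConfig", "CPCBatch", "BilinearScorer", "score_fk",
    "infonce_loss", "make_cpc_batches", "CPCModel", "CPCResults",
]


@dataclass
class CPCConfig:
    """CPC training settings.

    ``negatives_per_positive`` + 1 is the contrast-set size N of the
    InfoNCE loss; chance level is ln N. ``context_length`` windows of
    history feed the GRU before each prediction.
    """

    prediction_steps: int = 4
    negatives_per_positive: int = 7
    context_length: int = 16
    context_dim: int | None = None     # None -> embedding_dim
    batch_size: int = 16
    epochs: int = 8
    max_batches_per_epoch: int | None = 60
    lr: float = 2e-3
    weight_decay: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prediction_steps < 1:
            raise ValueError("prediction_steps must be >= 1")
        if self.negatives_per_positive < 1:
            raise ValueError("need at least one negative per positive")

    @property
    def contrast_size(self) -> int:
        return self.negatives_per_positive + 1


@dataclass
class CPCBatch:
    """One training batch of context positions.

    ``context_ids[b]`` are the global window ids feeding the GRU;
    ``candidate_ids[b, k, 0]`` is the positive (window t+k+1) and
    ``candidate_ids[b, k, 1:]`` the negatives. Negatives never equal
    their positive's window id.
    """

    context_ids: np.ndarray      # (B, Lc)
    candidate_ids: np.ndarray    # (B, K, N)


class BilinearScorer:
    """One independent W_k (D x context_dim) per prediction step."""

    def __init__(self, embedding_dim: int, context_dim: int, n_steps: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed + 2)
        # small init: near-equal candidate scores at the start, so the
        # untrained model sits at the chance loss ln N
        scale = 1.0 / np.sqrt(embedding_dim * context_dim)
        self.W = [Tensor(rng.normal(0.0, scale, (embedding_dim, context_dim)),
                         requires_grad=True) for _ in range(n_steps)]

    def parameters(self) -> list[Tensor]:
        return list(self.W)

    def log_score(self, z: np.ndarray, c: np.ndarray, k: int) -> float:
        return float(np.asarray(z) @ self.W[k].data @ np.asarray(c))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"W{k}": w.data for k, w in enumerate(self.W)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, w in enumerate(self.W):
            w.data = np.array(state[f"W{k}"], dtype=float)


def score_fk(z: np.ndarray, c: np.ndarray, W_k: np.ndarray) -> float:
    """f_k = exp(z^T W_k c). Positive for any inputs; its log is
    bilinear in (z, c). Prefer log-space arithmetic downstream."""
    z, c, W_k = (np.asarray(a, dtype=float) for a in (z, c, W_k))
    if W_k.shape != (z.shape[-1], c.shape[-1]):
        raise ValueError(
            f"W_k shape {W_k.shape} incompatible with z {z.shape}, c {c.shape}")
    return float(np.exp(z @ W_k @ c))


def infonce_loss(log_scores: np.ndarray, positive_index: int = 0) -> float:
    """InfoNCE from a (B, N) matrix of candidate log-scores.

    Mean over the batch of ``logsumexp(row) - row[positive]``; equals
    ln N exactly when all scores in a row are equal, 0 when N == 1.
    """
    log_scores = np.atleast_2d(np.asarray(log_scores, dtype=float))
    if log_scores.shape[1] < 1:
        raise ValueError("empty candidate set")
    lse = spsp.logsumexp(log_scores, axis=1)
    return float(np.mean(lse - log_scores[:, positive_index]))


def _valid_positions(n_windows_per_trial: list[int], Lc: int, K: int,
                     window_offset: list[int]) -> np.ndarray:
    """(trial, t_end) context positions with full history and future."""
    positions = []
    for trial, n_w in enumerate(n_windows_per_trial):
        for t_end in range(Lc - 1, n_w - K):
            positions.append((trial, t_end, window_offset[trial]))
    return np.array(positions, dtype=int)


def make_cpc_batches(n_windows_per_trial: list[int], config: CPCConfig,
                     rng: np.random.Generator) -> list[CPCBatch]:
    """Enumerate one epoch of batches.

    Every context position (trial, t) with ``context_length`` windows
    of history and K future windows inside the trial is used exactly
    once per epoch, in seeded-shuffled order. Negatives are drawn
    uniformly from all windows of the dataset (any trial), excluding
    the entry's positive window.
    """
    Lc, K, N = (config.context_length, config.prediction_steps,
                config.contrast_size)
    offsets = np.concatenate([[0], np.cumsum(n_windows_per_trial)])
    total_windows = int(offsets[-1])
    positions = _valid_positions(n_windows_per_trial, Lc, K,
                                 list(offsets[:-1]))
    if positions.size == 0:
        raise ValueError(
            f"no trial is long enough for context_length={Lc} plus "
            f"{K} prediction steps")
    order = rng.permutation(len(positions))
    if config.max_batches_per_epoch is not None:
        order = order[:config.max_batches_per_epoch * config.batch_size]
    batches = []
    for lo in range(0, len(order), config.batch_size):
        chunk = positions[order[lo:lo + config.batch_size]]
        B = len(chunk)
        ctx = np.empty((B, Lc), dtype=int)
        cand = np.empty((B, K, N), dtype=int)
        for b, (_, t_end, off) in enumerate(chunk):
            ctx[b] = off + np.arange(t_end - Lc + 1, t_end + 1)
            for k in range(K):
                pos = off + t_end + 1 + k
                cand[b, k, 0] = pos
                negs = rng.integers(0, total_windows - 1,
                                    size=config.negatives_per_positive)
                negs[negs >= pos] += 1   # uniform over all windows != pos
                cand[b, k, 1:] = negs
        batches.append(CPCBatch(context_ids=ctx, candidate_ids=cand))
    return batches


@dataclass
class CPCResults:
    """Trained CPC system plus its loss trajectory."""

    encoder: WindowEncoder
    context_model: GRUContext
    scorer: BilinearScorer
    loss_curve: np.ndarray
    initial_loss: float
    final_loss: float
    config: CPCConfig
    chance_loss: float            # ln N
    val_curve: np.ndarray | None = None
    best_epoch: int | None = None

    def summary(self) -> str:
        cfg = self.config
        return "\n".join([
            "CPC pretext training",
            "=" * 34,
            f"prediction steps K      {cfg.prediction_steps}",
            f"contrast size N         {cfg.contrast_size}",
            f"chance loss ln N        {self.chance_loss:.4f}",
            f"epochs                  {len(self.loss_curve)}",
            f"initial loss            {self.initial_loss:.4f}",
            f"final loss              {self.final_loss:.4f}",
        ])


class CPCModel:
    """CPC pretraining over a segmented dataset.

    Parameters
    ----------
    window_sets : list of WindowSet
        One per trial, identical window shape.
    config : CPCConfig
    encoder_config : EncoderConfig
    """

    def __init__(self, window_sets: list[WindowSet],
                 config: CPCConfig | None = None,
                 encoder_config: EncoderConfig | None = None):
        if not window_sets:
            raise ValueError("no windows supplied")
        self.window_sets = window_sets
        self.config = config or CPCConfig()
        self.encoder_config = encoder_config or EncoderConfig()
        self._input_shape = window_sets[0].windows.shape[1:]
        self._all_windows = np.concatenate(
            [ws.windows for ws in window_sets], axis=0)
        self._n_per_trial = [ws.n_windows for ws in window_sets]

    def _batch_loss(self, batch: CPCBatch, encoder: WindowEncoder,
                    context: GRUContext, scorer: BilinearScorer) -> Tensor:
        cfg = self.config
        B, Lc = batch.context_ids.shape
        K, N = cfg.prediction_steps, cfg.contrast_size
        needed = np.unique(np.concatenate(
            [batch.context_ids.ravel(), batch.candidate_ids.ravel()]))
        local = {g: i for i, g in enumerate(needed)}
        Z = encoder.forward(self._all_windows[needed])     # (D, n_needed)
        ctx_local = np.vectorize(local.get)(batch.context_ids)
        cand_local = np.vectorize(local.get)(batch.candidate_ids)

        steps = [Z.take(ctx_local[:, t], axis=1) for t in range(Lc)]
        c = context.forward(steps, batch_size=B)[-1]        # (H, B)
        total = None
        for k in range(K):
            Ck = scorer.W[k] @ c                            # (D, B)
            Zc = Z.take(cand_local[:, k, :], axis=1)        # (D, B, N)
            D = Zc.shape[0]
            logits = (Zc * Ck.reshape(D, B, 1)).sum(axis=0)  # (B, N)
            pos = logits.take(np.array([0]), axis=1)         # (B, 1)
            lk = (logits.logsumexp(axis=1, keepdims=True) - pos).mean()
            total = lk if total is None else total + lk
        return total * (1.0 / K)

    def evaluate_loss(self, encoder: WindowEncoder, context: GRUContext,
                      scorer: BilinearScorer, seed: int = 12345,
                      max_batches: int = 20) -> float:
        """InfoNCE on freshly drawn batches, no parameter updates."""
        rng = np.random.default_rng(seed)
        batches = make_cpc_batches(self._n_per_trial, self.config, rng)
        batches = batches[:max_batches]
        losses = [float(self._batch_loss(b, encoder, context, scorer).data)
                  for b in batches]
        return float(np.mean(losses))

    def fit(self, encoder: WindowEncoder | None = None,
            val_window_sets: list[WindowSet] | None = None) -> CPCResults:
        """Train g_enc, g_ar and the scorers.

        If ``val_window_sets`` (trials never used for training) are
        given, the InfoNCE loss on them is tracked after every epoch
        and the best-validation checkpoint is returned — on data with
        no predictable structure this stops training before the model
        can only memorize its training windows.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        encoder = encoder or WindowEncoder(self.encoder_config,
                                           self._input_shape)
        D = encoder.embedding_dim
        ctx_dim = cfg.context_dim or D
        context = GRUContext(D, ctx_dim, seed=cfg.seed)
        scorer = BilinearScorer(D, ctx_dim, cfg.prediction_steps,
                                seed=cfg.seed)
        params = (encoder.parameters() + context.parameters()
                  + scorer.parameters())
        opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

        val_model = (CPCModel(val_window_sets, cfg, self.encoder_config)
                     if val_window_sets else None)

        def val_loss():
            return val_model.evaluate_loss(encoder, context, scorer,
                                           seed=cfg.seed + 999)

        initial = self.evaluate_loss(encoder, context, scorer,
                                     seed=cfg.seed + 999)
        curve: list[float] = []
        val_curve: list[float] = []
        best = None
        if val_model is not None:
            v0 = val_loss()
            val_curve.append(v0)
            best = (v0, -1, [p.data.copy() for p in params])
        for epoch in range(cfg.epochs):
            batches = make_cpc_batches(self._n_per_trial, cfg, rng)
            losses = []
            for i, batch in enumerate(batches):
                loss = self._batch_loss(batch, encoder, context, scorer)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"CPC: non-finite loss at epoch {epoch}, step {i}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            curve.append(float(np.mean(losses)))
            if val_model is not None:
                v = val_loss()
                val_curve.append(v)
                if v < best[0]:
                    best = (v, epoch, [p.data.copy() for p in params])
        best_epoch = None
        if best is not None:
            _, best_epoch, snapshot = best
            for p, d in zip(params, snapshot):
                p.data = d
            final = best[0]
        else:
            final = self.evaluate_loss(encoder, context, scorer,
                                       seed=cfg.seed + 999)
        return CPCResults(
            encoder=encoder, context_model=context, scorer=scorer,
            loss_curve=np.array(curve), initial_loss=initial,
            final_loss=final, config=cfg,
            chance_loss=float(np.log(cfg.contrast_size)),
            val_curve=np.array(val_curve) if val_curve else None,
            best_epoch=best_epoch)
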