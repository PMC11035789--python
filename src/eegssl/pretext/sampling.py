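"""Pseudo-label samplers for the RP and TS pretext tasks.

Both tasks assume signal statistics drift slowly, so windows close in
time share latent state while distant windows do not. Around an anchor
window at position t, a partner at t' is

* a positive if ``|t - t'| <= tau_pos``,
* a negative if ``|t - t'| > tau_neg``,
* never sampled if it falls in the dead zone in between.

Temporal shuffling draws two anchors from the positive context and a
third window either strictly between them (label +1, temporally
ordered) or from the negative context (label -1, shuffled).

Positions are expressed in window-start units (whatever indexing the
caller's windows use — window indices for non-overlapping 1-s windows);
``tau_pos``/``tau_neg`` are in the same units. Pairs and triples are
always drawn within a single trial: temporal adjacency across trial
boundaries is physically meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RPSamplerConfig", "RPSample", "TSTriple",
    "sample_rp", "sample_ts", "sample_rp_dataset", "sample_ts_dataset",
]


@dataclass
class RPSamplerConfig:
    """tau_pos / tau_neg in window-start units; N samples total.

    Defaults (12 / 60 windows = 12 s / 60 s at 1-s windows) follow
    common practice for temporal pretext tasks on biosignals; the
    source protocols state no values.
    """

    tau_pos: int = 12
    tau_neg: int = 60
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tau_pos <= self.tau_neg):
            raise ValueError(
                f"need 0 < tau_pos <= tau_neg, got ({self.tau_pos}, {self.tau_neg})")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass(frozen=True)
class RPSample:
    """Anchor/partner pair with pseudo-label y: +1 near, -1 far."""
    t: int
    t_prime: int
    y: int
    trial: int = 0


@dataclass(frozen=True)
class TSTriple:
    """Window triple; y=+1 iff presented order is temporal (t<t'<t'')."""
    t: int
    t_prime: int
    t_dprime: int
    y: int
    trial: int = 0


def _partner_pool(valid_starts: np.ndarray, anchor: int, tau_pos: int,
                  tau_neg: int, positive: bool) -> np.ndarray:
    d = np.abs(valid_starts - anchor)
    if positive:
        mask = (d > 0) & (d <= tau_pos)
    else:
        mask = d > tau_neg
    return valid_starts[mask]


def sample_rp(valid_starts: np.ndarray, config: RPSamplerConfig,
              rng: np.random.Generator | None = None,
              n_samples: int | None = None, trial: int = 0
              ) -> list[RPSample]:
    """Draw N balanced RP pairs from one trial's window starts.

    N/2 positives and N/2 negatives (positives get the odd one). The
    anchor is drawn uniformly among starts that admit at least one
    partner of the required sign; the partner uniformly among those
    partners. Raises if the trial geometry makes a class unrealizable.
    """
    valid_starts = np.asarray(valid_starts)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    N = n_samples if n_samples is not None else config.n_samples
    counts = {+1: (N + 1) // 2, -1: N // 2}
    samples: list[RPSample] = []
    for y, n_y in counts.items():
        anchors = np.array([
            t for t in valid_starts
            if _partner_pool(valid_starts, t, config.tau_pos,
                             config.tau_neg, y > 0).size > 0])
        if anchors.size == 0:
            kind = "positive" if y > 0 else "negative"
            raise ValueError(
                f"no {kind} RP pairs realizable: trial has "
                f"{valid_starts.size} windows, tau_pos={config.tau_pos}, "
                f"tau_neg={config.tau_neg}")
        for _ in range(n_y):
            t = int(rng.choice(anchors))
            pool = _partner_pool(valid_starts, t, config.tau_pos,
                                 config.tau_neg, y > 0)
            t_prime = int(rng.choice(pool))
            samples.append(RPSample(t=t, t_prime=t_prime, y=y, trial=trial))
    return samples


def sample_ts(valid_starts: np.ndarray, config: RPSamplerConfig,
              rng: np.random.Generator | None = None,
              n_samples: int | None = None, trial: int = 0
              ) -> list[TSTriple]:
    """Draw N balanced TS triples from one trial's window starts.

    Anchors a1 < a2 come from the positive context (a2 - a1 <= tau_pos).
    Ordered triples (+1) put t' strictly between the anchors; shuffled
    triples (-1) draw t' from the negative context of both anchors.
    """
    valid_starts = np.sort(np.asarray(valid_starts))
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    N = n_samples if n_samples is not None else config.n_samples
    counts = {+1: (N + 1) // 2, -1: N // 2}

    # anchor pairs (a1, a2) with 0 < a2-a1 <= tau_pos
    starts = valid_starts
    pos_pairs = [(int(a), int(b)) for i, a in enumerate(starts)
                 for b in starts[i + 1:] if b - a <= config.tau_pos]
    samples: list[TSTriple] = []
    for y, n_y in counts.items():
        if y > 0:
            usable = [(a, b) for a, b in pos_pairs
                      if np.any((starts > a) & (starts < b))]
            kind = "ordered (+1)"
        else:
            usable = []
            for a, b in pos_pairs:
                d = np.minimum(np.abs(starts - a), np.abs(starts - b))
                if np.any(d > config.tau_neg):
                    usable.append((a, b))
            kind = "shuffled (-1)"
        if not usable:
            raise ValueError(
                f"no {kind} TS triples realizable with tau_pos="
                f"{config.tau_pos}, tau_neg={config.tau_neg} on "
                f"{starts.size} windows")
        for _ in range(n_y):
            a, b = usable[rng.integers(len(usable))]
            if y > 0:
                pool = starts[(starts > a) & (starts < b)]
            else:
                d = np.minimum(np.abs(starts - a), np.abs(starts - b))
                pool = starts[d > config.tau_neg]
            t_prime = int(rng.choice(pool))
            samples.append(TSTriple(t=a, t_prime=t_prime, t_dprime=b,
                                    y=y, trial=trial))
    return samples


def _per_trial_counts(n_total: int, n_trials: int) -> list[int]:
    base = n_total // n_trials
    rem = n_total % n_trials
    return [base + (1 if i < rem else 0) for i in range(n_trials)]


def sample_rp_dataset(starts_per_trial: list[np.ndarray],
                      config: RPSamplerConfig) -> list[RPSample]:
    """Spread N RP pairs across trials (difference <= 1 per trial)."""
    rng = np.random.default_rng(config.seed)
    out: list[RPSample] = []
    for trial, (starts, n) in enumerate(
            zip(starts_per_trial,
                _per_trial_counts(config.n_samples, len(starts_per_trial)))):
        if n > 0:
            out.extend(sample_rp(starts, config, rng, n_samples=n, trial=trial))
    return out


def sample_ts_dataset(starts_per_trial: list[np.ndarray],
                      config: RPSamplerConfig) -> list[TSTriple]:
    """Spread N TS triples across trials (difference <= 1 per trial)."""
    rng = np.random.default_rng(config.seed)
    out: list[TSTriple] = []
    for trial, (starts, n) in enumerate(
            zip(starts_per_trial,
                _per_trial_counts(config.n_samples, len(starts_per_trial)))):
        if n > 0:
            out.extend(sample_ts(starts, config, rng, n_samples=n, trial=trial))
    return out
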