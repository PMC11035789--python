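"""Synthetic multichannel EEG with known class-dependent band structure.

Real emotion-EEG corpora (SEED-like three-class, DEAP-like four-class)
are controlled-access; this module generates stand-in datasets whose
statistical structure matches what the downstream pipeline assumes:

* each trial carries one emotion label, constant within the trial;
* emotion classes differ in per-band signal power (delta..gamma);
* per-band content is Gaussian, so the closed-form differential
  entropy ``0.5*ln(2*pi*e*sigma^2)`` is exact in expectation;
* band amplitudes drift slowly within a trial (log-normal envelopes
  with a correlation time of several seconds), so windows close in
  time are statistically more alike than distant ones — the
  temporal-continuity assumption behind the relative-positioning and
  temporal-shuffling pretext tasks holds by construction.

Not simulated: ocular/muscle artifacts, electrode geometry, volume
conduction. Channel structure is a simple linear source mixing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bands import DEFAULT_BANDS, BandDefinition

__all__ = [
    "SynthConfig",
    "Recording",
    "default_band_profiles",
    "generate_trial",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


def default_band_profiles(n_classes: int) -> np.ndarray:
    """Per-class band standard deviations (n_classes x 5).

    Classes share delta power but differ strongly in theta/alpha/beta/
    gamma, giving a linearly separable differential-entropy signature.
    Magnitudes are chosen for testability; the field has no published
    effect sizes for these corpora.
    """
    profiles = {
        3: [
            [1.0, 0.5, 1.6, 0.4, 0.3],
            [1.0, 1.6, 0.4, 0.8, 0.3],
            [1.0, 0.5, 0.6, 1.6, 0.8],
        ],
        4: [
            [1.0, 0.5, 1.6, 0.4, 0.3],
            [1.0, 1.6, 0.4, 0.8, 0.3],
            [1.0, 0.5, 0.6, 1.6, 0.8],
            [1.0, 1.2, 1.2, 0.4, 0.9],
        ],
    }
    if n_classes not in profiles:
        raise ValueError(f"default profiles exist for 3 or 4 classes, not {n_classes}")
    return np.asarray(profiles[n_classes], dtype=float)


@dataclass
class SynthConfig:
    """Configuration of the synthetic EEG generator.

    Parameters
    ----------
    n_subjects, n_trials_per_subject : int
        Dataset size. Trials are assigned labels in a balanced
        round-robin per subject (count difference per class <= 1).
    trial_duration_s : float
        Trial length in seconds. The default of 240 s mirrors the
        ~4-minute film clips of SEED-style protocols and leaves room
        for far-apart negative windows in the pretext samplers.
    n_channels : int
        Recorded channels (= sources unless ``mixing`` is given).
    sampling_rate_hz : float
        Default 200 Hz, matching common emotion-EEG preprocessing.
    n_classes : int
        3 (SEED-like) or 4 (SEED-IV / DEAP-like) by default.
    band_power_profiles : ndarray (n_classes x 5) or None
        Per-class per-band signal standard deviations; ``None`` uses
        :func:`default_band_profiles`.
    noise_sd : float
        Standard deviation of the background noise.
    noise_color : str
        "pink" (1/f, the realistic EEG background, temporally
        correlated) or "white" (i.i.d. — a structure-free control in
        which nothing is predictable across windows).
    mixing : ndarray (n_channels x n_sources) or None
        Linear channel mixing; ``None`` means identity.
    envelope_log_sd : float
        SD of the log-amplitude envelope that modulates each band
        within a trial (0 disables the slow drift).
    envelope_tau_s : float
        Correlation time of that envelope, seconds.
    seed : int
        Master seed. Identical config + seed -> bit-identical data.
    """

    n_subjects: int = 2
    n_trials_per_subject: int = 6
    trial_duration_s: float = 240.0
    n_channels: int = 8
    sampling_rate_hz: float = 200.0
    n_classes: int = 3
    band_power_profiles: np.ndarray | None = None
    noise_sd: float = 0.3
    noise_color: str = "pink"
    mixing: np.ndarray | None = None
    envelope_log_sd: float = 0.35
    envelope_tau_s: float = 20.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_power_profiles is None:
            self.band_power_profiles = default_band_profiles(self.n_classes)
        self.band_power_profiles = np.asarray(self.band_power_profiles, dtype=float)
        if self.band_power_profiles.shape != (self.n_classes, len(self.bands)):
            raise ValueError(
                "band_power_profiles must have shape "
                f"({self.n_classes}, {len(self.bands)}), "
                f"got {self.band_power_profiles.shape}"
            )
        if np.any(self.band_power_profiles < 0):
            raise ValueError("band_power_profiles entries must be >= 0")
        if self.n_trials_per_subject < 1 or self.n_subjects < 1:
            raise ValueError("need at least one subject and one trial")
        if self.sampling_rate_hz <= 0 or self.trial_duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))


@dataclass
class Recording:
    """One multichannel trial: ``signal`` is channels x samples."""

    signal: np.ndarray
    sampling_rate_hz: float
    subject_id: int = 0
    trial_id: int = 0
    label: int | None = None
    t0: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _synthesis_edges(band: BandDefinition, fs: float) -> tuple[float, float]:
    # Cap the upper edge strictly below Nyquist; the nominal gamma edge
    # (100 Hz) equals Nyquist at fs=200 and would alias if used as-is.
    nyq = fs / 2.0
    high = min(band.high_hz, 0.95 * nyq)
    if band.low_hz >= high:
        raise ValueError(f"band {band.name} lies above usable range at fs={fs}")
    return band.low_hz, high


def _smooth_log_envelope(n: int, fs: float, log_sd: float, tau_s: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Log-normal amplitude envelope with Gaussian autocorrelation.

    The log-envelope is a stationary Gaussian process with
    ``corr(lag) = exp(-lag^2 / (2 tau_s^2))``: windows a few seconds
    apart share amplitude state, windows a minute apart do not.
    Realized by shaping white noise with a Gaussian spectral kernel.
    """
    if log_sd <= 0:
        return np.ones(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # sqrt of the Gaussian power spectrum matching the target autocorr
    kernel = np.exp(-0.5 * (2.0 * np.pi * freqs * tau_s) ** 2 / 2.0)
    m = np.fft.irfft(spec * kernel, n=n)
    # normalize by the ensemble SD of the filtered process (robust for
    # trials shorter than the correlation time, where the sample SD
    # within one trial is near zero)
    k2 = kernel**2
    ens_var = (k2[0] + 2.0 * k2[1:-1].sum()
               + (k2[-1] if n % 2 == 0 else 2.0 * k2[-1])) / n
    m /= np.sqrt(ens_var)
    return np.exp(log_sd * m - 0.5 * log_sd**2)


def _band_limited_noise(shape: tuple[int, int], low: float, high: float,
                        fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with spectrum confined to [low, high) Hz.

    Synthesized by masking the DFT of white noise, so the in-band
    spectrum is flat and out-of-band power is exactly zero — an
    independent band-pass filter recovers (almost) the full variance.
    """
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[..., ~((freqs >= low) & (freqs < high))] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def generate_trial(config: SynthConfig, class_idx: int,
                   rng: np.random.Generator | None = None) -> Recording:
    """Synthesize one trial of the given class.

    Per band: Gaussian white noise, zero-phase band-pass filtered,
    rescaled to the configured band SD, modulated by a slow log-normal
    envelope. Bands are summed per source, pink background noise is
    added, and sources are linearly mixed into channels.
    """
    if not (0 <= class_idx < config.n_classes):
        raise ValueError(f"class_idx {class_idx} out of range [0, {config.n_classes})")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = config.n_samples
    n_sources = (config.mixing.shape[1] if config.mixing is not None
                 else config.n_channels)
    profile = config.band_power_profiles[class_idx]

    sources = np.zeros((n_sources, n))
    for b, band in enumerate(config.bands):
        target_sd = profile[b]
        if target_sd == 0:
            continue
        low, high = _synthesis_edges(band, fs)
        comp = _band_limited_noise((n_sources, n), low, high, fs, rng)
        sd = comp.std(axis=-1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        comp = comp / sd * target_sd
        for s in range(n_sources):
            env = _smooth_log_envelope(n, fs, config.envelope_log_sd,
                                       config.envelope_tau_s, rng)
            comp[s] *= env
        sources += comp

    if config.noise_sd > 0:
        if config.noise_color == "pink":
            noise = _pink_noise((n_sources, n), rng)
        elif config.noise_color == "white":
            noise = rng.standard_normal((n_sources, n))
        else:
            raise ValueError(f"unknown noise_color {config.noise_color!r}")
        sources += config.noise_sd * noise

    signal = (config.mixing @ sources) if config.mixing is not None else sources
    return Recording(signal=signal, sampling_rate_hz=fs, label=class_idx)


def generate_dataset(config: SynthConfig) -> list[Recording]:
    """Generate the full dataset described by ``config``.

    Labels are assigned round-robin within each subject so class
    counts per subject differ by at most one. Each (subject, trial)
    draws from its own spawned RNG stream, so the result is
    independent of generation order and bit-reproducible.
    """
    if config.n_trials_per_subject == 0:
        raise ValueError("zero trials requested")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects * config.n_trials_per_subject)
    recordings: list[Recording] = []
    i = 0
    for subj in range(config.n_subjects):
        for trial in range(config.n_trials_per_subject):
            label = trial % config.n_classes
            rng = np.random.default_rng(children[i])
            rec = generate_trial(config, label, rng)
            rec.subject_id = subj
            rec.trial_id = trial
            recordings.append(rec)
            i += 1
    return recordings


def save_dataset(recordings: list[Recording], directory: str | Path) -> Path:
    """Write per-trial float32 arrays plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        fname = f"trial_{i:04d}.npy"
        np.save(directory / fname, rec.signal.astype("<f4"))
        entries.append({
            "file": fname,
            "subject_id": rec.subject_id,
            "trial_id": rec.trial_id,
            "label": rec.label,
            "sampling_rate_hz": rec.sampling_rate_hz,
            "n_channels": int(rec.n_channels),
            "n_samples": int(rec.n_samples),
        })
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"trials": entries}, indent=2))
    return manifest


def load_dataset(directory: str | Path) -> list[Recording]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    recordings = []
    for e in manifest["trials"]:
        signal = np.load(directory / e["file"]).astype(float)
        recordings.append(Recording(
            signal=signal,
            sampling_rate_hz=e["sampling_rate_hz"],
            subject_id=e["subject_id"],
            trial_id=e["trial_id"],
            label=e["label"],
        ))
    return recordings
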