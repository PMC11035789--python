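"""Canonical EEG frequency bands.

The five bands used throughout the package follow standard EEG
nomenclature: delta (1-4 Hz), theta (4-8 Hz), alpha (8-13 Hz),
beta (13-30 Hz) and gamma (30-100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [low_hz, high_hz) with a name.

    Parameters
    ----------
    name : str
        Band label, conventionally one of ``delta``, ``theta``,
        ``alpha``, ``beta``, ``gamma``.
    low_hz, high_hz : float
        Band edges in Hz. Must satisfy ``0 < low_hz < high_hz``.
    """

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz


#: The five canonical bands. Gamma nominally extends to 100 Hz; at a
#: 200 Hz sampling rate that edge sits exactly at Nyquist and is clipped
#: by the filtering code (see :func:`eegssl.preprocessing.bandpass`).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)
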