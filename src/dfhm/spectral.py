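"""Per-segment, per-electrode band power in the workload-relevant bands.

Band power is estimated from a single Hamming-tapered periodogram over the
full segment (no Welch averaging): power spectral density bins whose
frequency lies in ``[low, high)`` are summed and multiplied by the bin width.
The taper normalization is chosen so a unit-amplitude sinusoid inside a band
contributes ~0.5 uV^2 (its variance), i.e. band powers add up to the signal
variance over a partition of the spectrum (Parseval).  The half-open bin
rule assigns the 8 Hz bin to alpha, not to both bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .preprocess import Segment

__all__ = ["BandDefinition", "THETA", "ALPHA", "BandPowerVector", "band_power"]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low_hz}, {self.high_hz})"
            )


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)


@dataclass
class BandPowerVector:
    """Theta and alpha power per electrode (uV^2) for one segment."""

    theta: np.ndarray
    alpha: np.ndarray
    channels: list[str]
    start_s: float
    task_id: str
    subject_id: str | None = None
    offset_in_block_s: float = 0.0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.theta.shape != self.alpha.shape or self.theta.ndim != 1:
            raise ValidationError("theta and alpha must be 1-D arrays of equal length")
        if len(self.channels) != self.theta.size:
            raise ValidationError("channel list does not match power vector length")
        if (self.theta < 0).any() or (self.alpha < 0).any():
            raise ValidationError("band powers must be non-negative")


def _band_sum(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    return psd[:, mask].sum(axis=1) * df


def band_power(seg: Segment, bands: tuple[BandDefinition, BandDefinition] = (THETA, ALPHA),
               ) -> BandPowerVector:
    """Compute per-electrode power in each band for one segment.

    Preconditions: the segment must span at least two cycles of every band's
    low edge, and no band may exceed the Nyquist frequency.
    """
    theta_band, alpha_band = bands
    nyq = seg.rate / 2
    for b in bands:
        if b.high_hz > nyq:
            raise ValidationError(f"band {b.name!r} exceeds Nyquist ({nyq} Hz)")
        if seg.window_s < 2.0 / b.low_hz:
            raise ValidationError(
                f"segment of {seg.window_s:.3f} s too short for band {b.name!r} "
                f"(needs >= {2.0 / b.low_hz:.3f} s)"
            )
    freqs, psd = sps.periodogram(
        seg.data, fs=seg.rate, window="hamming", scaling="density", detrend=False, axis=1
    )
    return BandPowerVector(
        theta=_band_sum(freqs, psd, theta_band),
        alpha=_band_sum(freqs, psd, alpha_band),
        channels=list(seg.channels),
        start_s=seg.start_s,
        task_id=seg.task_id,
        subject_id=seg.subject_id,
        offset_in_block_s=seg.offset_in_block_s,
    )
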