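"""Scalp-level spectral features: Welch PSD and relative band power.

The PSD of each channel is estimated per epoch with Welch's method (1-s
Hann windows, 50% overlap, per-segment mean removal) and averaged across
epochs. Segments are zero-padded to twice the sampling rate before the FFT
so the frequency grid has 0.5 Hz spacing regardless of the 1-s window.

Relative band power divides the power integrated over each of the five
canonical bands — delta [1-4), theta [4-8), alpha [8-13), beta [13-30),
gamma [30-45] Hz — by the total power over the broad 1-45 Hz band. The
half-open band edges (last band closed) make the bands a partition of the
broad band, so the five fractions sum to one per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .cohort import EpochedSignals

__all__ = [
    "BandDefinition", "DEFAULT_BAND_DEFS", "PowerSpectrum", "welch_psd",
    "relative_band_power", "map_montage", "REFERENCE_MONTAGE",
]

#: canonical 19-channel 10-20 montage (clinical reference order)
REFERENCE_MONTAGE = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz", "C4",
    "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (1.0 <= self.low < self.high <= 45.0):
            raise ValueError(
                f"band {self.name}: need 1 <= low < high <= 45, "
                f"got [{self.low}, {self.high}]")


DEFAULT_BAND_DEFS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


@dataclass
class PowerSpectrum:
    """One-sided PSD per channel on a 0.5 Hz grid (µV²/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channels: list[str]

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def welch_psd(epochs: EpochedSignals) -> PowerSpectrum:
    """Welch PSD: 1-s Hann segments, 50% overlap, averaged across epochs.

    Each 1-s segment is mean-detrended, Hann-tapered and zero-padded to
    2 * rate points, giving 0.5 Hz resolution; segment periodograms are
    averaged within each epoch and the epoch PSDs averaged per subject.
    """
    rate = epochs.rate
    nper = int(round(rate))
    if epochs.n_samples < nper:
        raise ValueError(
            f"epochs of {epochs.n_samples} samples are shorter than the "
            f"{nper}-sample window")
    f, pxx = signal.welch(
        epochs.data, fs=rate, window="hann", nperseg=nper,
        noverlap=nper // 2, nfft=2 * nper, detrend="constant",
        scaling="density", axis=-1)
    return PowerSpectrum(f, pxx.mean(axis=0), list(epochs.channels))


def relative_band_power(spectrum: PowerSpectrum,
                        bands: Sequence[BandDefinition] = DEFAULT_BAND_DEFS,
                        total_band: tuple[float, float] = (1.0, 45.0)):
    """Band power fractions per channel (rectangle-rule integration).

    Frequency bins are assigned half-open, [low, high), except that the
    final default band keeps its closing 45 Hz bin, so the default bands
    tile [1, 45] and the fractions sum to 1.
    """
    f = spectrum.frequencies
    lo, hi = total_band
    if f[0] > lo or f[-1] < hi:
        raise ValueError(f"spectrum support [{f[0]}, {f[-1]}] does not cover "
                         f"the total band {total_band}")
    total_mask = (f >= lo) & (f <= hi)
    total = spectrum.power[:, total_mask].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total power in the broad band")
    out = {}
    hi_edge = max(b.high for b in bands)
    for b in bands:
        if b.low < lo or b.high > hi:
            raise ValueError(f"band {b.name} outside the total band")
        closed = b.high == hi_edge  # last band keeps its upper edge
        mask = (f >= b.low) & ((f <= b.high) if closed else (f < b.high))
        out[b.name] = spectrum.power[:, mask].sum(axis=1) / total
    return out


class MissingChannelError(KeyError):
    pass


def map_montage(signals: EpochedSignals, channel_map: dict[str, str],
                reference: Sequence[str] = REFERENCE_MONTAGE) -> EpochedSignals:
    """Restrict/rename channels to the 19-channel reference montage.

    ``channel_map`` maps source label -> reference label. Every reference
    label must be reachable; a missing one raises MissingChannelError
    naming it (no silent interpolation).
    """
    inverse: dict[str, str] = {}
    for src, ref in channel_map.items():
        inverse.setdefault(ref, src)
    index = {lab: i for i, lab in enumerate(signals.channels)}
    rows = []
    for ref in reference:
        src = inverse.get(ref, ref if ref in index else None)
        if src is None or src not in index:
            raise MissingChannelError(
                f"no source channel maps to reference channel {ref!r}")
        rows.append(index[src])
    return EpochedSignals(signals.subject_id, signals.rate,
                          signals.data[:, rows, :], list(reference))
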