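"""Welch power spectral density and relative band power.

Relative power of a band is the sum of PSD bins inside the band divided by
the sum over the full 1-45 Hz analysis range; all band intervals are
half-open ``[f_low, f_high)`` so boundary bins are never double-counted.
With 2-s epochs at 250 Hz the frequency grid has 0.5 Hz resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet

DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

DEFAULT_BAND_PAIRS = [
    ("delta", "theta"), ("delta", "alpha"), ("delta", "beta"),
    ("theta", "alpha"), ("theta", "beta"), ("alpha", "beta"),
]

DEFAULT_COHERENCE_BANDS = {
    "delta_theta": (1.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass
class BandScheme:
    """Named frequency intervals and the band-pair / coherence-band lists.

    Defaults: delta [1,4), theta [4,8), alpha [8,13), beta [13,30) inside a
    [1,45) total range; the six unordered band pairs; and the three
    coherence bands with delta and theta merged into [1,8).
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    total: tuple[float, float] = (1.0, 45.0)
    band_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_BAND_PAIRS))
    coherence_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COHERENCE_BANDS))

    def __post_init__(self) -> None:
        lo, hi = self.total
        intervals = sorted(self.bands.values())
        for (a, b) in intervals:
            if not (lo <= a < b <= hi):
                raise ValueError(f"band [{a},{b}) outside total range {self.total}")
        for (_, b1), (a2, _) in zip(intervals, intervals[1:]):
            if a2 < b1:
                raise ValueError("bands overlap")


@dataclass
class Spectrum:
    """A one-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be nonnegative")


def _hamming_psd_epochs(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch one-sided Hamming-tapered periodograms (density scaling)."""
    L = epochs.shape[-1]
    from scipy.signal import get_window
    win = get_window("hamming", L)
    demeaned = epochs - epochs.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(demeaned * win, axis=-1)
    scale = 1.0 / (fs * (win ** 2).sum())
    psd = (spec.real ** 2 + spec.imag ** 2) * scale
    psd[..., 1:] *= 2.0
    if L % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    return freqs, psd


def welch_psd(epochs: EpochSet, channel: str) -> Spectrum:
    """Welch PSD of one channel: Hamming periodograms of the epochs, averaged."""
    x = epochs.channel(channel)
    freqs, psd = _hamming_psd_epochs(x, epochs.fs)
    return Spectrum(freqs, psd.mean(axis=0), channel=channel)


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    f1, f2 = band
    return (freqs >= f1) & (freqs < f2)


def band_power(spec: Spectrum, band: tuple[float, float]) -> float:
    """Sum of PSD bins with ``f_low <= f < f_high``."""
    mask = band_mask(spec.freqs, band)
    if not mask.any():
        warnings.warn(f"band {band} contains no frequency bins", stacklevel=2)
        return 0.0
    return float(spec.power[mask].sum())


def relative_power(spec: Spectrum, band: tuple[float, float],
                   total: tuple[float, float] = (1.0, 45.0)) -> float:
    """Band power divided by the power in the whole analysis range."""
    denom = band_power(spec, total)
    if denom <= 0:
        raise ValueError("zero total power in the analysis range")
    return band_power(spec, band) / denom


def spectral_features(segments, scheme: BandScheme | None = None,
                      epoch_s: float = 2.0, overlap_frac: float = 0.25) -> dict[str, float]:
    """Relative-power features of one subject: ``rp.<band>.<channel|global>``.

    `segments` is a list of preprocessed recordings (the subject's
    artifact-free segments). Per segment, each channel's Welch spectrum
    yields one relative power per band; segment values are averaged, and
    the global value is the mean over channels (NaN channels excluded).
    """
    from .preprocess import segment_epochs

    scheme = scheme or BandScheme()
    per_segment = []
    for rec in segments:
        epochs = segment_epochs(rec, epoch_s, overlap_frac)
        per_segment.append(segment_relative_powers(epochs, scheme))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channels
        rp = np.nanmean(np.stack(per_segment), axis=0)  # (n_channels, n_bands)
    labels = segments[0].channel_labels
    feats: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channel mean
        for j, band in enumerate(scheme.bands):
            for i, ch in enumerate(labels):
                feats[f"rp.{band}.{ch}"] = float(rp[i, j])
            feats[f"rp.{band}.global"] = float(np.nanmean(rp[:, j]))
    return feats


def segment_relative_powers(epochs: EpochSet, scheme: BandScheme) -> np.ndarray:
    """(n_channels, n_bands) relative powers of one segment, all channels.

    Vectorized equivalent of calling :func:`welch_psd` +
    :func:`relative_power` per channel; all-zero channels come back NaN.
    """
    freqs, psd = _hamming_psd_epochs(epochs.array, epochs.fs)
    mean_psd = psd.mean(axis=0)  # (n_channels, n_freqs)
    total = mean_psd[:, band_mask(freqs, scheme.total)].sum(axis=1)
    out = np.full((mean_psd.shape[0], len(scheme.bands)), np.nan)
    valid = total > 0
    for j, band in enumerate(scheme.bands.values()):
        bp = mean_psd[:, band_mask(freqs, band)].sum(axis=1)
        out[valid, j] = bp[valid] / total[valid]
    return out
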