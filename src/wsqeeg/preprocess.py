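"""Signal conditioning shared by every feature estimator.

The pipeline order is fixed: common-average re-referencing, then zero-phase
1-45 Hz band-pass filtering with a Hamming-windowed FIR, then edge
trimming, then segmentation into fixed-length overlapping epochs. The FIR
is applied as a single compensated-delay pass (the symmetric impulse
response centred by a 'same'-mode convolution), which is exactly zero-phase
for a linear-phase filter; reflect padding suppresses startup transients
and the first/last seconds are additionally excluded from epoching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signal_io import Recording

#: Transition-width heuristic for a Hamming-windowed FIR: order = 3.3 / (df/fs).
_HAMMING_TBW = 3.3


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel.

    Idempotent; preserves all pairwise channel differences exactly.
    """
    if rec.n_channels < 2:
        raise ValueError("common-average reference requires at least 2 channels")
    data = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return Recording(data, rec.fs, list(rec.channel_labels),
                     reference_state="common_average", subject_id=rec.subject_id)


def design_bandpass(fs: float, low_hz: float = 1.0, high_hz: float = 45.0,
                    transition_hz: float | None = None) -> np.ndarray:
    """Hamming-windowed linear-phase FIR band-pass taps.

    The order follows the standard transition-width heuristic
    ``3.3 / (df / fs)`` with the transition width defaulting to the lower
    band edge (1 Hz at the package defaults, giving 825 taps + 1 at
    fs=250). The tap count is forced odd (type-I filter) so the band-pass
    has a well-defined symmetric centre.
    """
    if transition_hz is None:
        transition_hz = min(low_hz, (fs / 2 - high_hz))
    numtaps = int(np.ceil(_HAMMING_TBW * fs / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sps.firwin(numtaps, [low_hz, high_hz], window="hamming",
                      pass_zero=False, fs=fs)
    taps -= taps.sum() / numtaps  # pin the DC gain to exactly zero
    return taps


def bandlimit_fir(rec: Recording, low_hz: float = 1.0, high_hz: float = 45.0) -> Recording:
    """Zero-phase 1-45 Hz band-pass with a Hamming-windowed FIR.

    Raises if the high edge reaches Nyquist or the recording is shorter
    than three filter orders (too short for the transient to die out).
    """
    if high_hz >= rec.fs / 2:
        raise ValueError("high cutoff must be below Nyquist")
    taps = design_bandpass(rec.fs, low_hz, high_hz)
    half = (len(taps) - 1) // 2
    if rec.n_samples <= 3 * (len(taps) - 1):
        raise ValueError(
            f"recording too short for the designed filter "
            f"({rec.n_samples} samples vs {len(taps) - 1}-order FIR)"
        )
    padded = np.pad(rec.samples, ((0, 0), (half, half)), mode="reflect")
    out = sps.oaconvolve(padded, taps[None, :], mode="same", axes=1)
    out = out[:, half:-half]
    return Recording(out, rec.fs, list(rec.channel_labels),
                     reference_state=rec.reference_state, subject_id=rec.subject_id)


def trim_edges(rec: Recording, seconds: float = 2.0) -> Recording:
    """Drop the first and last `seconds` (residual filter-edge transients)."""
    n = int(round(seconds * rec.fs))
    if rec.n_samples <= 2 * n:
        raise ValueError("recording shorter than twice the trim margin")
    if n == 0:
        return rec
    return replace(rec, samples=rec.samples[:, n:-n])


@dataclass
class EpochSet:
    """Fixed-length overlapping epochs cut from a recording.

    ``array`` is a (n_epochs, n_channels, L) strided view into the source
    samples — cheap to build, read-only by convention.
    """

    array: np.ndarray
    L: int
    overlap_frac: float
    step: int
    fs: float
    channel_labels: list[str]
    source: Recording | None = None

    @property
    def n_epochs(self) -> int:
        return self.array.shape[0]

    def channel(self, label: str) -> np.ndarray:
        """(n_epochs, L) view of one channel."""
        from .signal_io import canonical_label
        idx = self.channel_labels.index(canonical_label(label))
        return self.array[:, idx, :]


def segment_epochs(rec: Recording, epoch_s: float = 2.0,
                   overlap_frac: float = 0.25) -> EpochSet:
    """Cut a recording into epochs of `epoch_s` seconds with the given overlap.

    The step between epoch starts is ``round(L * (1 - overlap_frac))``
    (at least 1 sample); a trailing partial epoch is dropped.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    L = int(round(epoch_s * rec.fs))
    if L < 2:
        raise ValueError("epoch length must span at least 2 samples")
    if rec.n_samples < L:
        raise ValueError(
            f"recording ({rec.duration_s:.3g} s) shorter than one epoch ({epoch_s} s)"
        )
    step = max(1, int(round(L * (1 - overlap_frac))))
    windows = np.lib.stride_tricks.sliding_window_view(rec.samples, L, axis=1)
    view = windows[:, ::step, :].swapaxes(0, 1)
    return EpochSet(view, L, overlap_frac, step, rec.fs,
                    list(rec.channel_labels), source=rec)


def preprocess(rec: Recording, low_hz: float = 1.0, high_hz: float = 45.0,
               edge_trim_s: float = 2.0) -> Recording:
    """CAR -> FIR band-pass -> edge trim, the standard conditioning chain."""
    rec = rereference_common_average(rec)
    rec = bandlimit_fir(rec, low_hz, high_hz)
    return trim_edges(rec, edge_trim_s)
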