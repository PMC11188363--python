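"""Wavelet bicoherence: quadratic phase coupling between frequency pairs.

A constant-bandwidth complex Morlet-type filter bank (Gaussian passbands,
2 Hz spectral FWHM at every centre frequency, 1 Hz steps over 1-45 Hz)
yields analytic coefficients W(f, t). For a bifrequency pair (fp, fq) the
bicoherence of an epoch is the normalized squared magnitude of the
time-averaged triple product

    b(fp, fq) = |sum_t W(fp,t) W(fq,t) W*(fp+fq,t)|^2
                / (sum_t |W(fp,t) W(fq,t)|^2 * sum_t |W(fp+fq,t)|^2)

which the Cauchy-Schwarz inequality bounds in [0, 1]. The time sum runs
over the edge-trimmed interiors of all 2-s epochs of a segment, so the
epochs act as averaging units: b is near 1 only when the phase at fp+fq
stays locked to the sum of the phases at fp and fq *consistently across
epochs* (quadratic phase coupling), and decays toward a 1/K bias floor
over K epochs when the phases are unrelated.

The band-pair summary (FIWBIC) aggregates b^2 over a rectangular
bifrequency region (symmetrized across the pair order); the default
aggregate is the region mean so values are comparable across band pairs
of different area.
"""

from __future__ import annotations

import numpy as np

from .spectral import BandScheme

#: FWHM -> Gaussian sigma conversion.
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def cwt_frequency_bank(x: np.ndarray, fs: float,
                       freqs: np.ndarray | None = None,
                       bandwidth_hz: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Analytic constant-bandwidth wavelet coefficients of a 1-D signal.

    Implemented as an FFT filter bank: each centre frequency applies a
    one-sided Gaussian passband of spectral FWHM `bandwidth_hz`, so the
    time-domain kernel is a complex Morlet-type wavelet whose envelope
    width is the same at every frequency.

    Returns ``(freqs, W)`` with ``W`` of shape (n_freqs, n_samples),
    complex.
    """
    x = np.asarray(x, dtype=np.float64)
    if freqs is None:
        freqs = np.arange(1.0, 46.0)
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs >= fs / 2):
        raise ValueError("centre frequency at or above Nyquist")
    if x.size < 2 * fs:
        raise ValueError("signal must span at least 2 s")
    n = x.size
    X = np.fft.fft(x)
    f_grid = np.fft.fftfreq(n, d=1.0 / fs)
    sigma_f = bandwidth_hz / _FWHM
    # one-sided (analytic) Gaussian passbands; x2 restores cosine amplitude
    H = 2.0 * np.exp(-((f_grid[None, :] - freqs[:, None]) ** 2) / (2 * sigma_f ** 2))
    H[:, f_grid < 0] = 0.0
    W = np.fft.ifft(X[None, :] * H, axis=1)
    return freqs, W


def efold_samples(fs: float, bandwidth_hz: float = 2.0) -> int:
    """Samples in one e-folding time of the wavelet envelope.

    The Gaussian envelope has sigma_t = 1/(2 pi sigma_f); its amplitude
    falls to 1/e at sqrt(2) sigma_t. Coefficients within this margin of an
    epoch edge are excluded from triple-product averages.
    """
    sigma_f = bandwidth_hz / _FWHM
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    return int(np.ceil(np.sqrt(2.0) * sigma_t * fs))


def wavelet_bicoherence(W: np.ndarray, freqs: np.ndarray,
                        f_p: float, f_q: float) -> float:
    """Bicoherence of one coefficient block at bifrequency (f_p, f_q).

    `W` is a (n_freqs, n_samples) coefficient array (one epoch, already
    edge-trimmed); coefficient series must exist at f_p, f_q and f_p+f_q.
    """
    freqs = np.asarray(freqs)

    def row(f):
        idx = np.nonzero(np.isclose(freqs, f))[0]
        if idx.size == 0:
            raise ValueError(f"no coefficient series at {f} Hz")
        return W[idx[0]]

    wp, wq, ws = row(f_p), row(f_q), row(f_p + f_q)
    prod = wp * wq
    num = np.abs((prod * np.conj(ws)).sum()) ** 2
    den = (np.abs(prod) ** 2).sum() * (np.abs(ws) ** 2).sum()
    if den == 0:
        return 0.0
    return float(num / den)


class BicoherenceMatrix:
    """Bicoherence over the full bifrequency grid of one signal.

    ``b[i, j]`` holds b(freqs[i], freqs[j]); entries with
    ``f_p + f_q > grid max`` are NaN (outside the analyzed range, not
    zero coupling).
    """

    def __init__(self, b: np.ndarray, freqs: np.ndarray, channel: str = ""):
        self.b = b
        self.freqs = np.asarray(freqs)
        self.channel = channel

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.b)


def segment_bicoherence(x: np.ndarray, fs: float, *,
                        freqs: np.ndarray | None = None,
                        bandwidth_hz: float = 2.0,
                        epoch_s: float = 2.0, overlap_frac: float = 0.75,
                        channel: str = "") -> BicoherenceMatrix:
    """Epoch-accumulated bicoherence matrix of one signal segment.

    The wavelet transform is computed once over the whole segment; epochs
    of `epoch_s` seconds with the given overlap are then sliced out, each
    trimmed by one wavelet e-folding time at both edges, and the triple
    product and both normalization terms are accumulated over all epoch
    interiors before the single normalization — the estimator that gives
    uncoupled signals the 1/K bias floor.

    Per-epoch sums over time come from cumulative sums of the
    triple-product series, so the cost is linear in segment length and
    independent of the epoch overlap.
    """
    freqs, W = cwt_frequency_bank(x, fs, freqs, bandwidth_hz)
    nf = len(freqs)
    n = W.shape[1]
    L = int(round(epoch_s * fs))
    step = max(1, int(round(L * (1 - overlap_frac))))
    pad = efold_samples(fs, bandwidth_hz)
    if L - 2 * pad < 2:
        raise ValueError("epoch too short after edge exclusion")
    starts = np.arange(0, n - L + 1, step)
    lo = starts + pad          # inclusive
    hi = starts + L - pad      # exclusive

    fmax = freqs.max()
    P, Q = np.meshgrid(np.arange(nf), np.arange(nf), indexing="ij")
    fsum = freqs[P] + freqs[Q]
    valid = fsum <= fmax + 1e-9
    # indices of the sum frequency on the grid (grid is uniform)
    df = freqs[1] - freqs[0] if nf > 1 else 1.0
    S = np.rint((fsum - freqs[0]) / df).astype(int)

    pw = np.abs(W) ** 2
    c_pw = np.concatenate([np.zeros((nf, 1)), np.cumsum(pw, axis=1)], axis=1)
    sum_pw = (c_pw[:, hi] - c_pw[:, lo]).sum(axis=1)   # (nf,) over all epochs

    b_acc = np.zeros((nf, nf))
    pi, qi, si = P[valid], Q[valid], S[valid]
    n_pairs = pi.size
    chunk = max(1, int(4e6 // n))
    for start in range(0, n_pairs, chunk):
        sl = slice(start, start + chunk)
        prod = W[pi[sl]] * W[qi[sl]]
        trip = prod * np.conj(W[si[sl]])
        c_trip = np.concatenate(
            [np.zeros((trip.shape[0], 1), dtype=complex), np.cumsum(trip, axis=1)],
            axis=1)
        c_pp = np.concatenate(
            [np.zeros((prod.shape[0], 1)), np.cumsum(np.abs(prod) ** 2, axis=1)],
            axis=1)
        num = np.abs((c_trip[:, hi] - c_trip[:, lo]).sum(axis=1)) ** 2
        den = (c_pp[:, hi] - c_pp[:, lo]).sum(axis=1) * sum_pw[si[sl]]
        with np.errstate(invalid="ignore", divide="ignore"):
            b_acc[pi[sl], qi[sl]] = np.where(den > 0, num / den, 0.0)

    b = np.where(valid, b_acc, np.nan)
    return BicoherenceMatrix(b, freqs, channel=channel)


def fiwbic(bmat: BicoherenceMatrix, pair: tuple[str, str],
           scheme: BandScheme | None = None, aggregate: str = "mean") -> float:
    """Band-pair summary of squared bicoherence.

    Aggregates ``b^2`` over the symmetrized bifrequency region
    (f_p in bandA, f_q in bandB) union (f_p in bandB, f_q in bandA),
    skipping invalid grid points. ``aggregate`` is "mean" (default,
    area-invariant) or "sum" (the raw double sum).
    """
    scheme = scheme or BandScheme()
    band_a, band_b = (scheme.bands[name] for name in pair)
    f = bmat.freqs
    in_a = (f >= band_a[0]) & (f < band_a[1])
    in_b = (f >= band_b[0]) & (f < band_b[1])
    region = np.outer(in_a, in_b) | np.outer(in_b, in_a)
    sel = region & bmat.valid
    if not sel.any():
        raise ValueError(f"no valid bifrequency grid points for pair {pair}")
    vals = bmat.b[sel] ** 2
    return float(vals.sum() if aggregate == "sum" else vals.mean())


def cfc_features(segments, scheme: BandScheme | None = None, *,
                 bandwidth_hz: float = 2.0, epoch_s: float = 2.0,
                 overlap_frac: float = 0.75, aggregate: str = "mean") -> dict[str, float]:
    """FIWBIC features of one subject: ``fiwbic.<bandA>_<bandB>.<channel|global>``.

    One epoch-averaged bicoherence matrix per channel per segment; matrices
    are averaged across segments, then summarized per band pair. Global
    values are channel means.
    """
    scheme = scheme or BandScheme()
    labels = segments[0].channel_labels
    n_ch = len(labels)
    acc = None
    for rec in segments:
        for i in range(n_ch):
            bm = segment_bicoherence(
                rec.samples[i], rec.fs, bandwidth_hz=bandwidth_hz,
                epoch_s=epoch_s, overlap_frac=overlap_frac, channel=labels[i])
            if acc is None:
                acc = np.zeros((n_ch,) + bm.b.shape)
                freqs = bm.freqs
            acc[i] += bm.b
    acc /= len(segments)
    feats: dict[str, float] = {}
    for pair in scheme.band_pairs:
        name = f"{pair[0]}_{pair[1]}"
        vals = []
        for i, ch in enumerate(labels):
            v = fiwbic(BicoherenceMatrix(acc[i], freqs), pair, scheme, aggregate)
            feats[f"fiwbic.{name}.{ch}"] = v
            vals.append(v)
        feats[f"fiwbic.{name}.global"] = float(np.mean(vals))
    return feats


def epoch_averaged_bicoherence(x: np.ndarray, fs: float, f_p: float, f_q: float, *,
                               bandwidth_hz: float = 2.0, epoch_s: float = 2.0,
                               overlap_frac: float = 0.75) -> float:
    """Epoch-averaged b(f_p, f_q) of one signal, single bifrequency pair.

    Same estimator as :func:`segment_bicoherence` restricted to one grid
    point; the filter bank only evaluates f_p, f_q and f_p + f_q.
    """
    x = np.asarray(x, dtype=np.float64)
    freqs = np.array([f_p, f_q, f_p + f_q])
    _, W = cwt_frequency_bank(x, fs, np.unique(freqs), bandwidth_hz)
    uf = np.unique(freqs)
    wp = W[np.searchsorted(uf, f_p)]
    wq = W[np.searchsorted(uf, f_q)]
    ws = W[np.searchsorted(uf, f_p + f_q)]
    L = int(round(epoch_s * fs))
    step = max(1, int(round(L * (1 - overlap_frac))))
    pad = efold_samples(fs, bandwidth_hz)
    starts = np.arange(0, x.size - L + 1, step)
    num_acc = 0.0 + 0.0j
    den1 = den2 = 0.0
    for s0 in starts:
        sl = slice(s0 + pad, s0 + L - pad)
        prod = wp[sl] * wq[sl]
        num_acc += (prod * np.conj(ws[sl])).sum()
        den1 += (np.abs(prod) ** 2).sum()
        den2 += (np.abs(ws[sl]) ** 2).sum()
    den = den1 * den2
    return float(np.abs(num_acc) ** 2 / den) if den > 0 else 0.0


def surrogate_threshold(x: np.ndarray, fs: float, f_p: float, f_q: float, *,
                        n_surrogates: int = 19, quantile: float = 0.95,
                        rng: np.random.Generator | None = None,
                        epoch_s: float = 2.0, overlap_frac: float = 0.75,
                        bandwidth_hz: float = 2.0) -> float:
    """Phase-randomization significance floor for b(f_p, f_q).

    Fourier-phase surrogates destroy any phase coupling while preserving
    the power spectrum; the returned quantile of their epoch-averaged
    bicoherence is the bias floor against which an observed value is
    judged.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=np.float64)
    spec = np.abs(np.fft.rfft(x))
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        phases = rng.uniform(0, 2 * np.pi, spec.size)
        phases[0] = 0.0
        surro = np.fft.irfft(spec * np.exp(1j * phases), n=x.size)
        vals[k] = epoch_averaged_bicoherence(
            surro, fs, f_p, f_q, bandwidth_hz=bandwidth_hz,
            epoch_s=epoch_s, overlap_frac=overlap_frac)
    return float(np.quantile(vals, quantile))
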