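"""Nonlinear EEG complexity: approximate, sample, permutation and wavelet entropy.

All four estimators follow their classic definitions:

* ApEn(m, r):  Phi_m(r) - Phi_{m+1}(r) with Chebyshev distances and
  self-matches included; r is a fraction of the input's SD, recomputed per
  analysis epoch.
* SaEn(m, r):  -ln(A/B) with self-matches excluded; A and B count template
  matches at lengths m+1 and m over the same N-m templates. Undefined
  (NaN, with a warning) when no length-(m+1) match exists.
* PeEn(order, delay): Shannon entropy of the empirical distribution of
  ordinal patterns; ties rank by first occurrence. Bounded by
  log(order!).
* WaEn(levels, mother): Shannon entropy of the relative energies of a
  dyadic wavelet decomposition (levels detail sub-bands + the final
  approximation); divided by log(levels + 1) when normalized.

Scale contracts: ApEn/SaEn are invariant to linear rescaling because r
scales with the SD; PeEn is invariant to any strictly monotone amplitude
transform; WaEn is invariant to scaling because energies are normalized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import segment_epochs


@dataclass
class EntropyParams:
    """Tunable parameters of the four estimators (field-standard defaults)."""

    apen_m: int = 2
    apen_r: float = 0.2
    saen_m: int = 2
    saen_r: float = 0.2
    peen_order: int = 3
    peen_delay: int = 2
    peen_log_base: float = math.e
    waen_levels: int = 5
    waen_mother: str = "db4"
    waen_normalized: bool = True

    def __post_init__(self) -> None:
        if self.apen_m < 1 or self.saen_m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not (0 < self.apen_r < 1 and 0 < self.saen_r < 1):
            raise ValueError("tolerance fraction r must lie in (0, 1)")
        if self.peen_order < 2 or self.peen_delay < 1:
            raise ValueError("PeEn requires order >= 2 and delay >= 1")
        if self.waen_levels < 2:
            raise ValueError("WaEn requires at least 2 decomposition levels")


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    idx = np.arange(m) * delay
    return x[idx[None, :] + np.arange(n)[:, None]]


def approximate_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """ApEn with Chebyshev distance, self-matches included, r = r_frac * SD."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 10:
        raise ValueError("input too short for approximate entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        templ = _embed(x, mm)
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        c = (d <= r).mean(axis=1)
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SaEn = -ln(A/B), self-matches excluded; NaN (with warning) if A = 0."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 10:
        raise ValueError("input too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd
    n_t = x.size - m  # templates comparable at both lengths
    em = _embed(x, m)[:n_t]
    em1 = _embed(x, m + 1)
    dm = np.abs(em[:, None, :] - em[None, :, :]).max(axis=-1)
    dm1 = np.abs(em1[:, None, :] - em1[None, :, :]).max(axis=-1)
    off = ~np.eye(n_t, dtype=bool)
    B = int(((dm <= r) & off).sum())
    A = int(((dm1 <= r) & off).sum())
    if A == 0 or B == 0:
        warnings.warn("sample entropy undefined: no template matches", stacklevel=2)
        return float("nan")
    return float(-np.log(A / B))


def _ordinal_codes(x2d: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Integer pattern codes of each embedding vector, rows = sequences.

    Stable argsort implements the tie rule: equal values rank by index of
    first occurrence.
    """
    n = x2d.shape[-1] - (order - 1) * delay
    if n < 1:
        raise ValueError("input too short for the requested order/delay")
    idx = np.arange(order) * delay
    emb = x2d[..., idx[None, :] + np.arange(n)[:, None]]
    ranks = np.argsort(np.argsort(emb, axis=-1, kind="stable"), axis=-1, kind="stable")
    weights = (order ** np.arange(order)).astype(np.int64)
    return ranks @ weights


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1,
                        log_base: float = math.e) -> float:
    """Shannon entropy of the ordinal-pattern distribution of `x`."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < (order - 1) * delay + 2:
        raise ValueError("input too short for permutation entropy")
    codes = _ordinal_codes(x[None, :], order, delay)[0]
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-(p * np.log(p)).sum() / np.log(log_base)) + 0.0


def permutation_entropy_epochs(epochs: np.ndarray, order: int = 3, delay: int = 1,
                               log_base: float = math.e) -> np.ndarray:
    """Vectorized PeEn of many equal-length sequences (rows)."""
    epochs = np.asarray(epochs, dtype=np.float64)
    codes = _ordinal_codes(epochs, order, delay)
    n_codes = order ** order
    n_ep, n_pat = codes.shape
    flat = codes + n_codes * np.arange(n_ep)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n_codes * n_ep)
    counts = counts.reshape(n_ep, n_codes)
    p = counts / n_pat
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1) / np.log(log_base)


def wavelet_entropy(x: np.ndarray, levels: int = 5, mother: str = "db4",
                    normalized: bool = True) -> float:
    """Shannon entropy of relative dyadic wavelet sub-band energies."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2 ** levels:
        raise ValueError("input too short for the requested decomposition depth")
    x = x - x.mean()  # DC offset would swamp the approximation band
    coeffs = pywt.wavedec(x, mother, level=levels)
    energies = np.array([(c ** 2).sum() for c in coeffs])
    total = energies.sum()
    if total == 0:
        raise ValueError("zero total energy")
    e = energies[energies > 0] / total
    h = float(-(e * np.log(e)).sum())
    if normalized:
        h /= math.log(levels + 1)
    return h


_MEASURES = ("apen", "saen", "peen", "waen")


def complexity_features(segments, params: EntropyParams | None = None, *,
                        epoch_s: float = 2.0, overlap_frac: float = 0.25,
                        measures: tuple[str, ...] = _MEASURES) -> dict[str, float]:
    """Entropy features of one subject: ``ent.<measure>.<channel|global>``.

    Each measure is evaluated per 2-s epoch per channel and averaged over
    all epochs of all segments; r for ApEn/SaEn comes from each epoch's
    own SD. A channel is NA for a measure when more than half of its
    epochs are undefined; global values are channel means over non-NA
    channels.
    """
    params = params or EntropyParams()
    labels = segments[0].channel_labels
    n_ch = len(labels)
    sums = {m: np.zeros(n_ch) for m in measures}
    good = {m: np.zeros(n_ch, dtype=int) for m in measures}
    total = {m: np.zeros(n_ch, dtype=int) for m in measures}

    for rec in segments:
        epochs = segment_epochs(rec, epoch_s, overlap_frac)
        arr = epochs.array  # (n_ep, n_ch, L)
        for ci in range(n_ch):
            block = arr[:, ci, :]
            if "peen" in measures:
                vals = permutation_entropy_epochs(
                    block, params.peen_order, params.peen_delay, params.peen_log_base)
                sums["peen"][ci] += vals.sum()
                good["peen"][ci] += vals.size
                total["peen"][ci] += vals.size
            for name, fn in (("apen", _apen_epoch), ("saen", _saen_epoch),
                             ("waen", _waen_epoch)):
                if name not in measures:
                    continue
                for ep in block:
                    v = fn(ep, params)
                    total[name][ci] += 1
                    if np.isfinite(v):
                        sums[name][ci] += v
                        good[name][ci] += 1

    feats: dict[str, float] = {}
    for m in measures:
        with np.errstate(invalid="ignore", divide="ignore"):
            ch_vals = np.where(good[m] > 0.5 * total[m], sums[m] / good[m], np.nan)
        for ci, ch in enumerate(labels):
            feats[f"ent.{m}.{ch}"] = float(ch_vals[ci])
        finite = ch_vals[np.isfinite(ch_vals)]
        feats[f"ent.{m}.global"] = float(finite.mean()) if finite.size else float("nan")
    return feats


def _apen_epoch(ep: np.ndarray, p: EntropyParams) -> float:
    return approximate_entropy(ep, p.apen_m, p.apen_r)


def _saen_epoch(ep: np.ndarray, p: EntropyParams) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sample_entropy(ep, p.saen_m, p.saen_r)


def _waen_epoch(ep: np.ndarray, p: EntropyParams) -> float:
    if not ep.any():
        return float("nan")
    return wavelet_entropy(ep, p.waen_levels, p.waen_mother, p.waen_normalized)
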