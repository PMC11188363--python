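"""Synthetic 19-channel EEG cohorts with controllable group effects.

No public infant-EEG dataset accompanies the analysis this package
implements, so every pipeline stage is exercised on simulated cohorts
whose group contrasts point in the clinically reported directions:
WS-like subjects have higher theta and alpha relative power, lower delta
and beta, weaker quadratic phase coupling, stronger low-frequency
inter-channel coherence, and more regular (lower permutation-entropy)
signals than control-like subjects.

Per channel, a segment is built as

  pink 1/f background  (variance share ``pink_frac``, 1-45 Hz)
+ four band-limited oscillations (Gaussian spectral bumps inside each
  band; narrowband noise, hence naturally amplitude-modulated), with
  variances solved so the relative band powers of the construction hit
  the per-group targets
+ a flat 30-45 Hz residual (``gamma_frac``) and a broadband sensor-noise
  floor (``noise_frac``)
+ per-band shared sources mixed across channels
  (coherence ~ gain^2 within the band)
+ quadratic-phase-coupled cosine triplets, one per band pair, with the
  sum-frequency amplitude scaled by ``qpc_strength``
-> order-1 autoregressive smoothing with coefficient ``regularity``
   (variance-renormalized).

Everything is a pure function of (config, group, subject index): cohorts
regenerate bit-identically from the same seed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.signal import hilbert, lfilter

from .signal_io import (MONTAGE_1020, Recording, SubjectMeta,
                        write_metadata, write_recording_edf,
                        write_recording_text)

#: Group mean relative powers the generator is calibrated toward
#: (WS-like vs control-like; delta/theta/alpha/beta).
BAND_TARGETS = {
    "WS": {"delta": 0.5117, "theta": 0.2145, "alpha": 0.2516, "beta": 0.065},
    "control": {"delta": 0.5479, "theta": 0.1655, "alpha": 0.1914, "beta": 0.1328},
}

_BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

_BAND_PAIRS = [("delta", "theta"), ("delta", "alpha"), ("delta", "beta"),
               ("theta", "alpha"), ("theta", "beta"), ("alpha", "beta")]

#: Which coherence band each oscillation band's shared source belongs to.
_SHARED_BAND = {"delta": "delta_theta", "theta": "delta_theta",
                "alpha": "alpha", "beta": "beta"}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults mirror the emulated study: 31 WS-like and 20 control-like
    subjects, 250 Hz, five 3-min artifact-free segments per subject, and
    per-group effect parameters pointing in the reported directions.
    """

    n_ws: int = 31
    n_ctrl: int = 20
    fs: float = 250.0
    segment_s: float = 180.0
    n_segments_ws: int = 5
    n_segments_ctrl: int = 5
    band_targets: dict = field(default_factory=lambda: {
        g: dict(t) for g, t in BAND_TARGETS.items()})
    pink_slope: float = 1.0
    pink_frac: float = 0.20
    pink_low_hz: float = 1.5
    gamma_frac: float = 0.015
    noise_frac: float = 0.02
    qpc_strength: dict = field(default_factory=lambda: {"WS": 0.4, "control": 0.8})
    qpc_amp: float = 0.25
    regularity: dict = field(default_factory=lambda: {"WS": 0.85, "control": 0.60})
    shared_source_gain: dict = field(default_factory=lambda: {
        "WS": {"delta_theta": 0.818, "alpha": 0.777, "beta": 0.791},
        "control": {"delta_theta": 0.787, "alpha": 0.812, "beta": 0.865},
    })
    between_subject_sd: float = 0.20
    occipital_alpha_gain: float = 1.3
    amplitude_uv: float = 30.0
    structural_prevalence: float = 9 / 31
    genetic_prevalence: float = 17 / 31
    planted_genetic_theta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, targets in self.band_targets.items():
            if any(v < 0 for v in targets.values()):
                raise ValueError("band targets must be nonnegative")
        if self.n_ws < 2 or self.n_ctrl < 2:
            raise ValueError("need at least 2 subjects per group")


@lru_cache(maxsize=8)
def _measurement_gain(fs: float, n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Frequency grid and squared gain of the standard 1-45 Hz analysis FIR."""
    from scipy.signal import freqz

    from .preprocess import design_bandpass

    taps = design_bandpass(fs, 1.0, 45.0)
    f = np.linspace(0.0, fs / 2, n_grid)
    _, h = freqz(taps, worN=f, fs=fs)
    return f, np.abs(h) ** 2


def _ar_gain_sq(f: np.ndarray, a: float, fs: float) -> np.ndarray:
    """Squared magnitude response of the order-1 autoregressive smoother."""
    if a == 0:
        return np.ones_like(f)
    w = 2 * np.pi * f / fs
    return 1.0 / (1.0 + a * a - 2.0 * a * np.cos(w))


def _component_variances(cfg: GeneratorConfig, targets: dict[str, float],
                         a_reg: float = 0.0) -> dict[str, float]:
    """Solve the oscillation variance per band from the RP targets.

    The solver predicts the power the analysis pipeline will *measure*
    from each construction component — its spectral shape multiplied by
    the squared gains of the 1-45 Hz analysis FIR and the group's AR(1)
    smoother — and allocates band-oscillation variances so the measured
    relative powers equal the normalized targets despite those gains and
    despite the fixed components (pink floor, 30-45 Hz residual, sensor
    noise) spilling power into every band. Fixed-point iteration; the
    scale is pinned by keeping the fixed components' variances at their
    configured shares.
    """
    f, g2 = _measurement_gain(cfg.fs)
    g2 = g2 * _ar_gain_sq(f, a_reg, cfg.fs)
    masks = {b: (f >= e[0]) & (f < e[1]) for b, e in _BAND_EDGES.items()}
    mask_r45 = (f >= 30.0) & (f < 45.0)

    def measured(shape: np.ndarray) -> dict[str, float]:
        """Measured power per unit variance, per band and in [30,45)."""
        tot = shape.sum()
        out = {b: (shape[m] * g2[m]).sum() / tot for b, m in masks.items()}
        out["_r45"] = (shape[mask_r45] * g2[mask_r45]).sum() / tot
        return out

    pink = np.where((f >= cfg.pink_low_hz) & (f < 45.0),
                    np.maximum(f, cfg.pink_low_hz) ** (-cfg.pink_slope), 0.0)
    gamma = ((f >= 30.0) & (f < 45.0)).astype(float)
    noise = (f >= 1.0).astype(float)
    m_pink, m_gamma, m_noise = measured(pink), measured(gamma), measured(noise)
    m_bump = {b: measured(_band_bump(f, b) ** 2) for b in _BAND_EDGES}

    fixed = {key: cfg.pink_frac * m_pink[key] + cfg.gamma_frac * m_gamma[key]
             + cfg.noise_frac * m_noise[key]
             for key in list(masks) + ["_r45"]}
    tsum = sum(targets.values())
    v = {b: targets[b] / tsum for b in _BAND_EDGES}
    clipped = False
    for _ in range(100):
        r45 = fixed["_r45"] + sum(v[b] * m_bump[b]["_r45"] for b in v)
        total = r45 + sum(fixed[b] + v[b] * m_bump[b][b] for b in v)
        new = {}
        for b in v:
            want = targets[b] / tsum * (total - r45)
            nv = (want - fixed[b]) / m_bump[b][b]
            if nv < 0.005:
                nv, clipped = 0.005, True
            new[b] = nv
        if all(abs(new[b] - v[b]) < 1e-12 for b in v):
            v = new
            break
        v = new
    if clipped:
        warnings.warn("fixed spectral floor exceeds a band target; "
                      "oscillation variance clipped", stacklevel=2)
    return v


def _sum_band_background(cfg: GeneratorConfig,
                         variances: dict[str, float]) -> dict[tuple, float]:
    """Background variance inside each band pair's sum-frequency interval.

    The interval of pair (A, B) is [A_lo + B_lo, A_hi + B_hi); the
    background is everything the construction already places there (pink
    floor, 30-45 Hz residual, sensor noise, band oscillations). Used to
    scale the coupled component so the coupling-to-background ratio is set
    by ``qpc_strength * qpc_amp`` alone.
    """
    f = np.linspace(0.0, cfg.fs / 2, 4096)
    shapes = {
        "pink": (np.where((f >= cfg.pink_low_hz) & (f < 45.0),
                          np.maximum(f, cfg.pink_low_hz) ** (-cfg.pink_slope), 0.0),
                 cfg.pink_frac),
        "gamma": (((f >= 30.0) & (f < 45.0)).astype(float), cfg.gamma_frac),
        "noise": ((f >= 1.0).astype(float), cfg.noise_frac),
    }
    for b, v in variances.items():
        shapes[b] = (_band_bump(f, b) ** 2, v)
    out = {}
    for b1, b2 in _BAND_PAIRS:
        lo = _BAND_EDGES[b1][0] + _BAND_EDGES[b2][0]
        hi = _BAND_EDGES[b1][1] + _BAND_EDGES[b2][1]
        mask = (f >= lo) & (f < min(hi, cfg.fs / 2))
        total = 0.0
        for shape, var in shapes.values():
            ssum = shape.sum()
            if ssum > 0:
                total += var * shape[mask].sum() / ssum
        out[(b1, b2)] = total
    return out


def _shaped_noise(rng: np.random.Generator, amp: np.ndarray, n: int,
                  variance: float) -> np.ndarray:
    """Gaussian noise with one-sided amplitude shape `amp`, exact variance."""
    z = rng.standard_normal(amp.size) + 1j * rng.standard_normal(amp.size)
    x = np.fft.irfft(z * amp, n=n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x * (np.sqrt(variance) / sd)


def _band_bump(freqs: np.ndarray, band: str) -> np.ndarray:
    """Gaussian spectral bump confined to one band (zero outside)."""
    f1, f2 = _BAND_EDGES[band]
    centre = 0.5 * (f1 + f2)
    sigma = max((f2 - f1) / 6.0, 0.25)
    amp = np.exp(-((freqs - centre) ** 2) / (2 * sigma ** 2))
    amp[(freqs < max(f1, 1.5)) | (freqs >= f2)] = 0.0
    return amp


def _flat_shape(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    amp = np.zeros_like(freqs)
    amp[(freqs >= lo) & (freqs < hi)] = 1.0
    return amp


def _subject_rng(cfg: GeneratorConfig, group: str, index: int) -> np.random.Generator:
    tag = 1 if group == "WS" else 2
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag, index]))


def generate_subject(cfg: GeneratorConfig, group: str, index: int, *,
                     structural_flag: int = 0, genetic_flag: int = 0,
                     ) -> tuple[list[Recording], SubjectMeta]:
    """Build all segments of one synthetic subject.

    Deterministic in (cfg.seed, group, index). Returns the per-segment
    recordings (19 channels each) and the subject metadata.
    """
    if group not in ("WS", "control"):
        raise ValueError(f"invalid group: {group!r}")
    rng = _subject_rng(cfg, group, index)
    fs = cfg.fs
    n = int(round(cfg.segment_s * fs))
    n_segments = cfg.n_segments_ws if group == "WS" else cfg.n_segments_ctrl
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    labels = list(MONTAGE_1020)
    n_ch = len(labels)
    sid = f"{'ws' if group == 'WS' else 'ctrl'}{index:03d}"

    # per-subject multiplicative jitter of the band targets
    targets = dict(cfg.band_targets[group])
    jitter = np.exp(cfg.between_subject_sd * rng.standard_normal(len(targets)))
    targets = {b: t * j for (b, t), j in zip(targets.items(), jitter)}
    if genetic_flag and cfg.planted_genetic_theta != 0.0:
        targets["theta"] *= 1.0 + cfg.planted_genetic_theta
    a_reg = cfg.regularity[group]
    variances = _component_variances(cfg, targets, a_reg)
    qpc = cfg.qpc_strength[group]
    gains = cfg.shared_source_gain[group]

    bumps = {b: _band_bump(freqs, b) for b in _BAND_EDGES}
    bg_power = _sum_band_background(cfg, variances)
    pink_amp = np.zeros_like(freqs)
    sel = (freqs >= cfg.pink_low_hz) & (freqs < 45.0)
    pink_amp[sel] = freqs[sel] ** (-cfg.pink_slope / 2.0)
    gamma_amp = _flat_shape(freqs, 30.0, 45.0)
    noise_amp = _flat_shape(freqs, 1.0, fs / 2.0)

    segments = []
    for _seg in range(n_segments):
        # one unit-variance shared realisation per band; channels mix it in
        # with gain g so the within-band coherence is ~ g^2
        shared_band = {b: _shaped_noise(rng, bumps[b], n, 1.0)
                       for b in _BAND_EDGES}

        data = np.empty((n_ch, n))
        for ci, ch in enumerate(labels):
            x = _shaped_noise(rng, pink_amp, n, cfg.pink_frac)
            x += _shaped_noise(rng, gamma_amp, n, cfg.gamma_frac)
            x += _shaped_noise(rng, noise_amp, n, cfg.noise_frac)
            analytic = {}
            for b, v in variances.items():
                if ch in ("O1", "O2") and b == "alpha":
                    v = v * cfg.occipital_alpha_gain
                g = gains[_SHARED_BAND[b]]
                # alternating polarity so the shared source has a near-zero
                # channel mean and survives common-average referencing
                sign = 1.0 if ci % 2 == 0 else -1.0
                indep = _shaped_noise(rng, bumps[b], n, 1.0)
                osc = np.sqrt(max(1 - g * g, 0.0)) * indep + sign * g * shared_band[b]
                x += np.sqrt(v) * osc
                analytic[b] = hilbert(osc) * np.sqrt(v)
            # quadratic phase coupling: the coupled component is the real
            # part of the product of the two bands' analytic signals, so
            # the phase at every sum frequency is locked to the sum of the
            # band phases across the whole band-pair region; its amplitude
            # is qpc_strength * qpc_amp relative to the background already
            # present in the sum-frequency interval, making the
            # coupling-to-noise ratio group-controlled
            for b1, b2 in _BAND_PAIRS:
                prod = (analytic[b1] * analytic[b2]).real
                sd = prod.std()
                if sd == 0:
                    continue
                amp = qpc * cfg.qpc_amp * np.sqrt(bg_power[(b1, b2)])
                x += amp * prod / sd
            if a_reg > 0:
                sd0 = x.std()
                x = lfilter([1.0], [1.0, -a_reg], x)
                x *= sd0 / x.std()
            data[ci] = cfg.amplitude_uv * x
        segments.append(Recording(data, fs, labels, subject_id=sid))

    meta = SubjectMeta(sid, group, structural_flag, genetic_flag)
    return segments, meta


def generate_cohort(cfg: GeneratorConfig, out_dir=None, file_format: str = "tsv",
                    ) -> tuple[dict[str, list[Recording]], list[SubjectMeta]]:
    """Generate the full two-group cohort (and optionally write it to disk).

    Structural/genetic flags are assigned to exact per-cohort counts
    (``round(prevalence * n_ws)``) by a seeded permutation; controls carry
    zero flags. With `out_dir`, one file per segment
    (``<subject>_seg<k>.tsv|.edf``) plus ``metadata.tsv`` are written.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    n_struct = int(round(cfg.structural_prevalence * cfg.n_ws))
    n_gen = int(round(cfg.genetic_prevalence * cfg.n_ws))
    struct_flags = np.zeros(cfg.n_ws, dtype=int)
    struct_flags[rng.choice(cfg.n_ws, n_struct, replace=False)] = 1
    gen_flags = np.zeros(cfg.n_ws, dtype=int)
    gen_flags[rng.choice(cfg.n_ws, n_gen, replace=False)] = 1

    subjects: dict[str, list[Recording]] = {}
    meta: list[SubjectMeta] = []
    for i in range(cfg.n_ws):
        segs, m = generate_subject(cfg, "WS", i,
                                   structural_flag=int(struct_flags[i]),
                                   genetic_flag=int(gen_flags[i]))
        subjects[m.subject_id] = segs
        meta.append(m)
    for i in range(cfg.n_ctrl):
        segs, m = generate_subject(cfg, "control", i)
        subjects[m.subject_id] = segs
        meta.append(m)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sid, segs in subjects.items():
            for k, rec in enumerate(segs):
                base = os.path.join(out_dir, f"{sid}_seg{k}")
                if file_format == "edf":
                    write_recording_edf(rec, base + ".edf")
                elif file_format == "tsv":
                    write_recording_text(rec, base + ".tsv")
                else:
                    raise ValueError(f"unknown file format: {file_format!r}")
        write_metadata(meta, os.path.join(out_dir, "metadata.tsv"))
    return subjects, meta


def zero_effect_config(cfg: GeneratorConfig) -> GeneratorConfig:
    """A copy of `cfg` with identical parameters for both groups (null cohort)."""
    ctrl = {k: (dict(v) if isinstance(v, dict) else v)
            for k, v in cfg.band_targets.items()}
    ctrl["WS"] = dict(cfg.band_targets["control"])
    return replace(
        cfg,
        band_targets=ctrl,
        qpc_strength={"WS": cfg.qpc_strength["control"],
                      "control": cfg.qpc_strength["control"]},
        regularity={"WS": cfg.regularity["control"],
                    "control": cfg.regularity["control"]},
        shared_source_gain={"WS": dict(cfg.shared_source_gain["control"]),
                            "control": dict(cfg.shared_source_gain["control"])},
        planted_genetic_theta=0.0,
    )


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> Recording:
    """Deterministic single- or dual-channel unit-test signals.

    Kinds: ``sinusoid`` (f, amp), ``white_noise``, ``pink_noise`` (slope),
    ``qpc_triplet`` (f1, f2, strength, coupled; uncoupled mode redraws the
    sum component's phase every epoch), ``shared_source_pair`` (f, snr),
    ``chirp`` (f0, f1), ``constant`` (value). Common params: fs
    (default 250), duration_s (default 60).
    """
    p = dict(params or {})
    fs = float(p.pop("fs", 250.0))
    duration = float(p.pop("duration_s", 60.0))
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    if kind == "sinusoid":
        f = float(p.pop("f", 10.0))
        amp = float(p.pop("amp", 1.0))
        data = amp * np.sin(2 * np.pi * f * t)[None, :]
    elif kind == "white_noise":
        data = rng.standard_normal(n)[None, :]
    elif kind == "pink_noise":
        slope = float(p.pop("slope", 1.0))
        freqs = np.fft.rfftfreq(n, 1 / fs)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** (-slope / 2)
        data = _shaped_noise(rng, amp, n, 1.0)[None, :]
    elif kind == "constant":
        data = np.full((1, n), float(p.pop("value", 1.0)))
    elif kind == "chirp":
        from scipy.signal import chirp
        f0, f1 = float(p.pop("f0", 5.0)), float(p.pop("f1", 15.0))
        data = chirp(t, f0=f0, t1=t[-1], f1=f1)[None, :]
    elif kind == "qpc_triplet":
        f1 = float(p.pop("f1", 6.0))
        f2 = float(p.pop("f2", 10.0))
        strength = float(p.pop("strength", 1.0))
        coupled = bool(p.pop("coupled", True))
        noise_sd = float(p.pop("noise_sd", 0.1))
        epoch_s = float(p.pop("epoch_s", 2.0))
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        x = np.cos(2 * np.pi * f1 * t + ph1) + np.cos(2 * np.pi * f2 * t + ph2)
        if coupled:
            x += 0.5 * strength * np.cos(2 * np.pi * (f1 + f2) * t + ph1 + ph2)
        else:
            L = int(round(epoch_s * fs))
            phase = np.repeat(rng.uniform(0, 2 * np.pi, int(np.ceil(n / L))), L)[:n]
            x += 0.5 * strength * np.cos(2 * np.pi * (f1 + f2) * t + phase)
        data = (x + noise_sd * rng.standard_normal(n))[None, :]
    elif kind == "shared_source_pair":
        f = float(p.pop("f", 6.0))
        snr = float(p.pop("snr", 5.0))
        shared = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        noise = rng.standard_normal((2, n)) / snr
        data = shared[None, :] + noise
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    if p:
        raise ValueError(f"unused fixture params: {sorted(p)}")
    labels = ["Fp1", "Fp2"][: data.shape[0]]
    return Recording(data, fs, labels, subject_id=f"fixture-{kind}")
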