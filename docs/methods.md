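# Methods

`wsqeeg` implements a quantitative analysis of interictal scalp EEG aimed
at separating infants with West syndrome (WS) from healthy controls using
hypsarrhythmia-free recording segments. This note documents the models,
the estimators, the parameters that matter, and the choices made where the
design was genuinely open.

## Signal model and preprocessing

Recordings are 19-channel scalp EEG in the international 10-20 montage,
nominally sampled at 250 Hz, held in microvolts. No rescaling is applied:
every feature in the package is either scale-invariant (relative power,
coherence, bicoherence, permutation and wavelet entropy) or scale-adapted
through a tolerance expressed as a fraction of the signal's own standard
deviation (approximate and sample entropy), so amplifier units never
change a result.

Conditioning is fixed and shared by all estimators:

1. **Common-average reference (CAR).** The instantaneous mean across all
   channels is subtracted from each channel. Idempotent; preserves all
   pairwise channel differences.
2. **1–45 Hz band-pass.** A Hamming-windowed linear-phase FIR whose order
   follows the standard transition-width heuristic `3.3/(Δf/fs)` with the
   transition width set by the 1 Hz lower edge (825 taps at 250 Hz). The
   filter is applied in a single compensated-delay pass — the symmetric
   impulse response centred by a same-mode convolution — which is exactly
   zero-phase for a linear-phase filter; input edges are reflect-padded.
   The taps are adjusted by a constant (≈1e-6 relative) so the DC gain is
   exactly zero.
3. **Edge trimming.** The first and last 2 s of each conditioned segment
   are excluded from epoching to avoid residual edge transients.

Epoching cuts fixed 2-s windows; the start-to-start step is
`round(L·(1−overlap))` and a trailing partial window is dropped. Overlap
defaults per estimator: 25% for Welch spectra, coherence, and the entropy
estimators; 75% for bicoherence. Features are computed per epoch (or per
segment, below), averaged over all epochs of all segments of a subject;
the subject is the statistical unit throughout.

Missing samples are not supported: readers reject NaN, because the
analysis assumes artifact-free segments selected upstream.

## Linear features

**Relative band power (`rp`).** Welch PSD from Hamming-tapered 2-s
periodograms (per-window mean removed, density scaling; 0.5 Hz
resolution), averaged per segment. Band power is the sum of PSD bins in a
half-open interval `[f_lo, f_hi)` — delta [1,4), theta [4,8), alpha
[8,13), beta [13,30) — and relative power divides by the [1,45) total, so
boundary bins are never double-counted and the four band fractions sum to
at most 1. Per-segment values are averaged; the *global* value is the
unweighted mean of the 19 channel values (this mirrors the channel-wise
reporting structure; a pooled-spectrum alternative would weight channels
by power).

**Wavelet bicoherence and FIWBIC (`fiwbic`).** A constant-bandwidth
complex Morlet-type filter bank — one-sided Gaussian passbands of 2 Hz
spectral FWHM at centre frequencies 1–45 Hz in 1 Hz steps — yields
analytic coefficients W(f,t). The bandwidth is constant, not
proportional to frequency, because the analysis fixes a 2 Hz bandwidth at
every centre frequency. For a bifrequency pair (fp, fq):

    b(fp,fq) = |Σ_t W(fp)W(fq)W*(fp+fq)|²
               / (Σ_t |W(fp)W(fq)|² · Σ_t |W(fp+fq)|²)

with the time sums running over the edge-trimmed interiors of all 2-s
epochs of a segment (one wavelet e-folding time, ≈0.27 s, is dropped at
each epoch edge). The Cauchy–Schwarz denominator bounds b in [0,1].
Accumulating the triple product *across* epochs before normalizing is
essential: it makes b ≈ 1 only when the phase at fp+fq is locked to the
sum of the phases at fp and fq consistently across epochs, and gives
uncoupled signals the familiar 1/K bias floor over K epochs. (A
per-epoch-normalized variant is degenerate — any narrowband deterministic
signal scores ≈1 within a single short epoch regardless of coupling.)

FIWBIC summarizes a band pair as the **mean** of b² over the symmetrized
bifrequency region (fp∈A, fq∈B) ∪ (fp∈B, fq∈A), restricted to the valid
grid fp+fq ≤ 45; points outside the analyzed range are invalid, not zero.
The mean (rather than the raw double sum) makes values comparable across
band pairs whose regions differ in area; `fiwbic.aggregate=sum` restores
the raw sum. Matrices are averaged across segments per channel; global
values are channel means.

Significance of an observed b is judged against Fourier-phase surrogates:
phase randomization preserves the power spectrum while destroying phase
coupling, and the 95th percentile of the surrogate b distribution is the
bias floor. Note that an uncoupled signal exceeds a 95th percentile ~5%
of the time by construction; checks against this floor are rates over
seeds, not per-seed certainties.

**Bi-channel coherence (`coh`).** Magnitude-squared coherence
C_xy(f) = |P_xy|²/(P_x P_y) from Welch cross/auto spectra (2-s Hamming
windows, 50% window overlap, per-window mean removed) over whole
segments, averaged over the bins of three bands — delta/theta combined
[1,8), alpha [8,13), beta [13,30) — for all 171 unordered channel pairs.
Global values are unweighted pair means. With K averaged windows,
independent signals sit at the 1/K bias floor, not at zero. Coherence is
computed on CAR-referenced signals; a component common to all channels is
removed by CAR and does not inflate connectivity.

## Nonlinear features (`ent`)

All four entropies are computed per 2-s epoch on the same conditioned
signals and averaged. Defaults:

| estimator | parameters | default | rationale |
|---|---|---|---|
| ApEn | m, r | m=2, r=0.2·SD | field standard; r from each epoch's own SD |
| SaEn | m, r | m=2, r=0.2·SD | as ApEn, self-matches excluded |
| PeEn | order, delay, log | 3, 2, nats | see below |
| WaEn | levels, mother | 5, db4, normalized | value range suggests a normalized quantity |

* **ApEn(m,r)** = Φ_m − Φ_{m+1} with Chebyshev distances, self-matches
  included (the classic definition, which keeps the logarithms finite).
* **SaEn(m,r)** = −ln(A/B) with self-matches excluded, A and B counted
  over the same N−m templates. When no length-(m+1) match exists the
  value is undefined and propagates as missing; a channel is reported
  missing when more than half of its epochs are undefined, and global
  means skip missing channels.
* **PeEn(order, delay)** is the Shannon entropy of the ordinal-pattern
  distribution; ties rank by order of appearance (deterministic). Bounded
  by log(order!). The **delay default of 2 samples (8 ms at 250 Hz)** is
  a deliberate choice: for a 1–45 Hz band-limited signal at 250 Hz,
  adjacent samples are so strongly correlated that order-3 patterns at
  delay 1 cannot exceed ≈1.47 nats even for band-limited white noise,
  whereas the 1.4–1.6 nats range typical of infant EEG reported with
  these pipelines is exactly what delay 2 produces. The delay is
  configurable (`ent.peen.delay`).
* **WaEn(levels, mother)** decomposes the demeaned epoch with a dyadic
  db4 wavelet transform (5 levels), forms relative energies of the 5
  detail sub-bands plus the final approximation, and takes the Shannon
  entropy, normalized by ln 6. Because dyadic sub-bands double in width
  per level, white noise does **not** reach the normalized ceiling of 1:
  its sub-band energies are proportional to bandwidth, giving ≈0.76.
  Concentrated narrowband signals score far lower (≈0.32 for a mid-band
  tone with db4's leaky filters); the informative content of WaEn is this
  ordering, not proximity to 1.

## Group statistics

Each feature is compared between groups with a pooled-variance Student
two-sample t-test (Welch available via `stats.ttest=welch`); missing
values are dropped pairwise. Multiple testing is controlled with
Benjamini–Hochberg step-up FDR **within (family × band/measure × scope)
strata** — e.g. the 19 channel-wise theta relative-power tests form one
correction block — matching the per-band channel-wise reporting
structure; `stats.fdr.scope=global` corrects across everything at once.
Channel t-maps export t-values with non-significant entries set to zero.
Significance is flagged at q < α (α = 0.05); note the adjusted q ties α
exactly when the largest p equals the step-up boundary, where the raw
step-up rule (p_(k) ≤ kα/n, a ≤ comparison) still rejects.

The etiology analysis regresses each feature on
[intercept, structural_flag, genetic_flag] by OLS over WS subjects only,
with BH-FDR across features separately per predictor. A rank-deficient
design (constant or identical flags) marks results invalid rather than
producing spurious coefficients.

## Synthetic cohorts

No public dataset accompanies this analysis, so the generator in
`wsqeeg.synthetic` is a first-class, tested component that emulates the
study conditions: 31 WS-like and 20 control-like subjects, 250 Hz, five
3-min artifact-free segments per subject by default, with group effects
pointing in the reported directions (WS: theta↑, alpha↑, delta↓, beta↓,
cross-frequency coupling↓, low-frequency coherence↑, beta coherence↓,
regularity↑ i.e. PeEn↓).

Per channel and segment the signal is a sum of:

* a pink 1/f floor (slope 1, variance share 0.20) starting at 1.5 Hz so
  the 1 Hz analysis high-pass edge does not eat it;
* four band-limited oscillations — Gaussian spectral bumps confined to
  their band, hence narrowband noise with a natural random envelope —
  whose variances are solved numerically so that the relative powers the
  analysis pipeline will *measure* (after the FIR's and the AR
  smoother's gain curves) equal the per-group targets;
* a flat 30–45 Hz residual (0.015) and a broadband sensor-noise floor
  (0.02);
* per-band shared sources mixed across channels with alternating
  polarity (so CAR does not cancel them), gain g giving within-band
  coherence ≈ g²·(band purity)²;
* quadratic-phase-coupled components: for each band pair, the real part
  of the product of the two bands' analytic signals — locking the phase
  at every sum frequency to the sum of the band phases across the whole
  band-pair region — scaled so the coupling-to-background amplitude
  ratio in the sum-frequency interval is `qpc_strength × qpc_amp`;
* an order-1 autoregressive smoother (`regularity`; WS 0.85, control
  0.60) applied last and variance-renormalized. The variance solver
  pre-compensates its spectral tilt, so `regularity` tunes fine spectral
  shape (and hence permutation entropy) without moving the band targets.

Relative-power targets are the reported group means used as relative
weights (WS 0.5117/0.2145/0.2516/0.065, control
0.5479/0.1655/0.1914/0.1328 for delta/theta/alpha/beta); measured global
relative powers track the normalized targets within ±0.05 (self-test in
the suite). With the defaults above, measured global PeEn lands near
1.44 (WS-like) and 1.55 (control-like) and global coherence near the
0.20–0.25 range, matching the reported magnitudes. Between-subject
variation is a multiplicative log-normal jitter (SD 0.2) on the band
weights, which reproduces the reported between-subject spread of theta
relative power (≈0.03–0.04 SD). Occipital channels receive an extra
alpha gain (×1.3) for topographic realism. Structural and genetic flags
are assigned at exact per-cohort counts (9/31 and 17/31) by a seeded
permutation; an optional planted effect multiplies the theta weight of
genetic-flag carriers.

Everything is a pure function of (config, group, subject index): cohorts
regenerate bit-identically from a seed.

**What the generator does not emulate:** hypsarrhythmia waveforms (the
analyzed segments exclude them by design), age-dependent EEG maturation,
volume-conduction channel correlations beyond the shared sources, nonlinear
amplitude distributions, or artifacts. Passing tests therefore show that
the pipeline recovers planted effects of realistic size under Gaussian
band-structured signals — not that the clinical effect sizes themselves
are reproduced from real EEG, which would require the original
recordings.

## Problem sizes in tests and the acceptance script

Cohort-level simulations in the test suite and `scripts/acceptance.py`
use two 60-s segments per subject instead of the default five 3-min
segments. At 2-s epochs this still gives ≥ 114 epochs per subject, so the
per-subject estimator variance is already far below the between-subject
spread that drives the group statistics; the reduced duration changes
none of the group-level conclusions and keeps the full suite fast. The
defaults remain the full study layout.

## Numerical choices and degenerate inputs

* Half-open band intervals everywhere; the [1,45) total for relative
  power.
* Hamming tapers use the periodic (DFT-even) convention throughout,
  matching the scipy spectral estimators the coherence path cross-checks
  against.
* An all-zero channel yields missing relative power (zero total power is
  an error at the single-spectrum level, missing at the feature level);
  global means skip missing channels.
* Constant signals have ApEn = SaEn = PeEn = 0 by convention; WaEn of a
  zero-energy epoch is missing.
* Feature tables serialize floats at 17 significant digits and parse with
  round-trip precision, so write/read is value-exact and repeated runs
  are byte-identical.
* Seeds: every stochastic component derives from
  `numpy.random.SeedSequence([seed, group_tag, subject_index])`, so
  subjects are independent streams and any subject can be regenerated in
  isolation.

## Known limitations

* Gamma-band (>45 Hz) activity is outside the analysis range by design
  (250 Hz sampling).
* The bicoherence magnitude depends on the number of accumulated epochs
  through its bias floor; values are comparable only between signals
  analyzed with the same epoch count, which the pipeline guarantees
  within a cohort analysis (equal segment layouts per group).
* The etiology regression assumes homoscedastic Gaussian residuals and
  tests the two flags jointly in one OLS; with 31 subjects its power is
  limited, and no covariate adjustment (age, sex) is offered.
* The per-epoch ApEn/SaEn implementations are O(N²) in the epoch length;
  they are practical at 2-s epochs (500 samples) but not for long
  unsegmented records.
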