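# wsqeeg

Quantitative interictal-EEG biomarker analysis for West syndrome.

West syndrome (infantile epileptic spasms syndrome) is diagnosed from
interictal EEG largely by visual recognition of hypsarrhythmia, a pattern
with notoriously poor inter-rater reliability. This package implements a
reproducible, fully computational alternative for the
hypsarrhythmia-*free* portions of the record: it extracts linear and
nonlinear features from 19-channel 10–20 scalp EEG and screens them as
group-separating biomarkers. It is aimed at clinical-neurophysiology and
methods researchers who want the whole chain — preprocessing, feature
estimators, statistics, and a synthetic validation cohort — as one tested
library with a small CLI.

## What it computes

For each subject (common-average referenced, 1–45 Hz FIR-filtered, 2-s
epochs):

* **Relative band power** — Welch PSD with 2-s Hamming windows;
  RP(f₁,f₂) = P(f₁,f₂)/P(1,45) for δ [1,4), θ [4,8), α [8,13), β [13,30) Hz.
* **Cross-frequency coupling** — wavelet bicoherence from a
  constant-bandwidth (2 Hz FWHM) complex Morlet bank,
  b(f_p,f_q) = |Σ W(f_p)W(f_q)W*(f_p+f_q)|² / (Σ|W(f_p)W(f_q)|²·Σ|W(f_p+f_q)|²),
  summarized per band pair as the mean of b² (FIWBIC) over six band pairs.
* **Bi-channel connectivity** — magnitude-squared coherence
  C_xy(f) = |P_xy|²/(P_x P_y) for all 171 channel pairs in δ/θ, α and β
  bands.
* **Complexity** — approximate, sample, permutation and wavelet entropy
  per 2-s epoch, averaged.

796 features per subject (`rp.*`, `fiwbic.*`, `coh.*`, `ent.*`, each per
channel/pair plus a global mean). Group screening uses pooled-variance
t-tests with Benjamini–Hochberg FDR within feature-family strata;
structural/genetic etiology associations use per-feature OLS with BH-FDR
per predictor.

Because the clinical recordings behind this design are not public, the
package ships a seeded 19-channel cohort generator whose group contrasts
point in the clinically reported directions (WS-like: θ↑ α↑ δ↓ β↓,
coupling↓, PeEn↓, low-frequency coherence↑), calibrated so measured
values land at the reported magnitudes. See `docs/methods.md`.

## Worked example

```bash
wsqeeg simulate --n-ws 8 --n-ctrl 8 --seed 7 --segment-s 60 --n-segments 1 \
        --out cohort/
wsqeeg extract-features --in cohort/ --families rp,ent --out features.tsv
wsqeeg compare-groups --features features.tsv --meta cohort/metadata.tsv \
        --out stats/
```

which prints

```
wrote 16 subjects to cohort/
wrote 16 x 160 feature table to features.tsv
101 significant features; reports in stats/
```

`stats/comparison.tsv` then holds one row per feature; the two headline
biomarkers read

```
feature          mean_ws  mean_ctrl  t_stat    p_raw      q_value    significant
rp.theta.global  0.2097   0.1565      3.564    3.11e-03   3.11e-03   True
ent.peen.global  1.4466   1.5524    -12.424    5.98e-09   5.98e-09   True
```

i.e. in this simulated cohort theta relative power is higher and
permutation entropy lower in the WS-like group — the pair of effects the
analysis is designed to detect — with FDR-adjusted q-values well below
0.05. The same steps are available as library calls
(`generate_cohort`, `extract_features`, `compare_groups`,
`regress_etiology`).

The equivalent Python:

```python
from wsqeeg import GeneratorConfig, generate_cohort, extract_features, compare_groups

cfg = GeneratorConfig(n_ws=8, n_ctrl=8, seed=7, segment_s=60.0,
                      n_segments_ws=1, n_segments_ctrl=1)
subjects, meta = generate_cohort(cfg)
table = extract_features(subjects, families=("rp", "ent"))
for r in compare_groups(table, meta):
    if r.feature.endswith(".global") and r.significant:
        print(r.feature, round(r.mean_ws, 4), round(r.mean_ctrl, 4),
              round(r.q_value, 6))
```

## Layout

```
src/wsqeeg/
  signal_io.py     EDF/TSV recordings, montage check, feature tables
  preprocess.py    CAR, zero-phase FIR band-pass, epoching
  spectral.py      Welch PSD, band/relative power
  bicoherence.py   wavelet bank, bicoherence, FIWBIC, surrogates
  connectivity.py  magnitude-squared coherence, pair features
  complexity.py    ApEn / SaEn / PeEn / WaEn
  group_stats.py   t-tests, BH-FDR, etiology regression
  synthetic.py     seeded cohort generator and unit-test fixtures
  pipeline.py      end-to-end orchestration and reports
  config.py, cli.py
```
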