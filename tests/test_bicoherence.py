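"""Wavelet bicoherence: tuning, coupling detection, bounds, bias floor."""

import numpy as np
import pytest

from wsqeeg import (cwt_frequency_bank, epoch_averaged_bicoherence, fiwbic,
                    make_fixture, segment_bicoherence, surrogate_threshold,
                    wavelet_bicoherence)
from wsqeeg.bicoherence import BicoherenceMatrix, efold_samples


class TestFrequencyBank:
    def test_tone_peaks_at_its_frequency(self):
        rec = make_fixture("sinusoid", {"f": 10.0, "duration_s": 10})
        freqs, W = cwt_frequency_bank(rec.samples[0], 250.0)
        # steady-state mean amplitude per centre frequency
        amps = np.abs(W[:, 500:-500]).mean(axis=1)
        assert freqs[np.argmax(amps)] == 10.0

    def test_amplitude_linearity(self):
        rec = make_fixture("white_noise", {"duration_s": 4}, seed=1)
        x = rec.samples[0]
        _, W1 = cwt_frequency_bank(x, 250.0)
        _, W2 = cwt_frequency_bank(3.5 * x, 250.0)
        np.testing.assert_allclose(np.abs(W2), 3.5 * np.abs(W1), rtol=1e-9)

    def test_chirp_ridge_monotone(self):
        rec = make_fixture("chirp", {"f0": 5.0, "f1": 15.0, "duration_s": 20})
        freqs, W = cwt_frequency_bank(rec.samples[0], 250.0)
        ridge = freqs[np.argmax(np.abs(W[:, 1000:-1000:500]), axis=0)]
        assert np.all(np.diff(ridge) >= 0)
        assert ridge[-1] > ridge[0]

    def test_above_nyquist_rejected(self):
        rec = make_fixture("white_noise", {"duration_s": 4})
        with pytest.raises(ValueError, match="Nyquist"):
            cwt_frequency_bank(rec.samples[0], 250.0, np.array([130.0]))


class TestBicoherence:
    @pytest.mark.parametrize("seed", range(5))
    def test_coupled_triplet_detected(self, seed):
        rec = make_fixture("qpc_triplet",
                           {"f1": 6.0, "f2": 10.0, "duration_s": 60}, seed=seed)
        b = epoch_averaged_bicoherence(rec.samples[0], 250.0, 6.0, 10.0)
        assert b > 0.8

    def test_uncoupled_below_surrogate_floor(self):
        # a 95th-percentile threshold is exceeded ~5% of the time by an
        # uncoupled signal *by construction*, so judge the rate over seeds
        below = 0
        for seed in range(5):
            rec = make_fixture("qpc_triplet",
                               {"f1": 6.0, "f2": 10.0, "coupled": False,
                                "duration_s": 60}, seed=seed)
            x = rec.samples[0]
            b = epoch_averaged_bicoherence(x, 250.0, 6.0, 10.0)
            thr = surrogate_threshold(x, 250.0, 6.0, 10.0,
                                      rng=np.random.default_rng(seed + 100))
            below += b < thr
        assert below >= 4

    def test_bounded_unit_interval(self, rng):
        x = rng.standard_normal(5000)
        bm = segment_bicoherence(x, 250.0)
        valid = bm.b[~np.isnan(bm.b)]
        assert np.all(valid >= 0.0) and np.all(valid <= 1.0)

    def test_invalid_region_is_nan_not_zero(self, rng):
        bm = segment_bicoherence(rng.standard_normal(2500), 250.0)
        assert np.isnan(bm.b[44, 44])   # 45 + 45 > 45 Hz
        assert not np.isnan(bm.b[0, 0])

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(5000)
        b1 = epoch_averaged_bicoherence(x, 250.0, 6.0, 10.0)
        b2 = epoch_averaged_bicoherence(123.4 * x, 250.0, 6.0, 10.0)
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_bias_floor_shrinks_with_epochs(self):
        # estimator bias ~ 1/K over K accumulated epochs; average over
        # realizations so the trend is not drowned by estimator variance
        rng = np.random.default_rng(42)
        means = []
        for K in (4, 16, 64):
            n = int(K * 0.5 * 500 + 375)
            vals = [epoch_averaged_bicoherence(rng.standard_normal(n), 250.0,
                                               6.0, 10.0, overlap_frac=0.5)
                    for _ in range(10)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_matrix_matches_single_pair_path(self):
        rec = make_fixture("qpc_triplet", {"f1": 6.0, "f2": 10.0,
                                           "duration_s": 20}, seed=3)
        x = rec.samples[0]
        bm = segment_bicoherence(x, 250.0)
        direct = bm.b[5, 9]  # grid indices of 6 and 10 Hz
        pair = epoch_averaged_bicoherence(x, 250.0, 6.0, 10.0)
        assert direct == pytest.approx(pair, rel=1e-9)

    def test_single_epoch_bicoherence_via_op(self):
        rec = make_fixture("qpc_triplet", {"f1": 6.0, "f2": 10.0,
                                           "duration_s": 2}, seed=0)
        _, W = cwt_frequency_bank(rec.samples[0], 250.0)
        pad = efold_samples(250.0)
        b = wavelet_bicoherence(W[:, pad:-pad], np.arange(1.0, 46.0), 6.0, 10.0)
        assert 0.0 <= b <= 1.0

    def test_invalid_bifrequency_rejected(self):
        rec = make_fixture("white_noise", {"duration_s": 4})
        _, W = cwt_frequency_bank(rec.samples[0], 250.0)
        with pytest.raises(ValueError, match="no coefficient series"):
            wavelet_bicoherence(W, np.arange(1.0, 46.0), 30.0, 30.0)


class TestFiwbic:
    def _matrix(self, fill):
        freqs = np.arange(1.0, 46.0)
        b = np.full((45, 45), fill)
        b[np.add.outer(freqs, freqs) > 45.0] = np.nan
        return BicoherenceMatrix(b, freqs)

    def test_zero_field_gives_zero(self):
        assert fiwbic(self._matrix(0.0), ("theta", "alpha")) == 0.0

    def test_unit_field_gives_one(self):
        assert fiwbic(self._matrix(1.0), ("theta", "alpha")) == 1.0

    def test_sum_mode_scales_with_region(self):
        m = self._matrix(0.5)
        mean_v = fiwbic(m, ("delta", "theta"), aggregate="mean")
        sum_v = fiwbic(m, ("delta", "theta"), aggregate="sum")
        assert mean_v == pytest.approx(0.25)
        assert sum_v > mean_v

    def test_region_symmetrized(self):
        freqs = np.arange(1.0, 46.0)
        b = np.zeros((45, 45))
        b[5, 9] = 0.9   # (6, 10): theta x alpha orientation only
        m = BicoherenceMatrix(b, freqs)
        assert fiwbic(m, ("theta", "alpha")) == fiwbic(m, ("alpha", "theta"))
        assert fiwbic(m, ("theta", "alpha")) > 0

    def test_empty_region_rejected(self):
        freqs = np.arange(40.0, 46.0)
        b = np.full((6, 6), np.nan)
        with pytest.raises(ValueError, match="no valid"):
            fiwbic(BicoherenceMatrix(b, freqs), ("alpha", "beta"))


class TestCoupledFixtureOrdering:
    def test_fiwbic_higher_when_coupled(self):
        vals = {}
        for coupled in (True, False):
            accum = []
            for seed in range(3):
                rec = make_fixture(
                    "qpc_triplet",
                    {"f1": 6.0, "f2": 10.0, "coupled": coupled,
                     "duration_s": 30, "noise_sd": 0.3}, seed=seed)
                bm = segment_bicoherence(rec.samples[0], 250.0)
                accum.append(fiwbic(bm, ("theta", "alpha")))
            vals[coupled] = np.mean(accum)
        assert vals[True] > vals[False]
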