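"""Synthetic cohort generator: determinism, calibration, effect directions."""

import numpy as np
import pytest

from wsqeeg import (GeneratorConfig, Recording, generate_cohort,
                    generate_subject, make_fixture, preprocess,
                    spectral_features, zero_effect_config)
from wsqeeg.complexity import permutation_entropy
from wsqeeg.signal_io import read_metadata, read_recording

SMALL = dict(segment_s=30.0, n_segments_ws=1, n_segments_ctrl=1)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(seed=5, **SMALL)
        a, ma = generate_subject(cfg, "WS", 3)
        b, mb = generate_subject(cfg, "WS", 3)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        assert ma == mb

    def test_different_subjects_differ(self):
        cfg = GeneratorConfig(seed=5, **SMALL)
        a, _ = generate_subject(cfg, "WS", 0)
        b, _ = generate_subject(cfg, "WS", 1)
        assert not np.allclose(a[0].samples, b[0].samples)

    def test_cohort_regeneration_identical(self, tmp_path):
        cfg = GeneratorConfig(n_ws=2, n_ctrl=2, seed=9, **SMALL)
        s1, m1 = generate_cohort(cfg)
        s2, m2 = generate_cohort(cfg)
        assert m1 == m2
        for sid in s1:
            np.testing.assert_array_equal(s1[sid][0].samples, s2[sid][0].samples)


class TestCohortLayout:
    def test_counts_and_flags(self):
        cfg = GeneratorConfig(n_ws=31, n_ctrl=20, seed=1, **SMALL)
        subjects, meta = generate_cohort(cfg)
        assert len(meta) == 51
        ws = [m for m in meta if m.group == "WS"]
        ctrl = [m for m in meta if m.group == "control"]
        assert len(ws) == 31 and len(ctrl) == 20
        assert sum(m.structural_flag for m in ws) == 9
        assert sum(m.genetic_flag for m in ws) == 17
        assert all(m.structural_flag == 0 and m.genetic_flag == 0 for m in ctrl)

    def test_files_written_and_readable(self, tmp_path):
        cfg = GeneratorConfig(n_ws=2, n_ctrl=2, seed=2, **SMALL)
        generate_cohort(cfg, out_dir=tmp_path, file_format="tsv")
        meta = read_metadata(tmp_path / "metadata.tsv")
        assert len(meta) == 4
        rec = read_recording(tmp_path / f"{meta[0].subject_id}_seg0.tsv", fs=250.0)
        assert rec.n_channels == 19
        assert rec.duration_s == pytest.approx(30.0)

    def test_montage_is_full_1020(self):
        cfg = GeneratorConfig(seed=0, **SMALL)
        segs, _ = generate_subject(cfg, "control", 0)
        from wsqeeg import check_montage
        assert check_montage(segs[0]) == []


class TestGeneratorContracts:
    def test_theta_weight_raises_measured_theta(self):
        cfg = GeneratorConfig(seed=4, between_subject_sd=0.0, **SMALL)
        boosted = GeneratorConfig(seed=4, between_subject_sd=0.0, **SMALL)
        boosted.band_targets["control"]["theta"] *= 1.5
        lo, _ = generate_subject(cfg, "control", 0)
        hi, _ = generate_subject(boosted, "control", 0)
        f_lo = spectral_features([preprocess(lo[0])])
        f_hi = spectral_features([preprocess(hi[0])])
        assert f_hi["rp.theta.global"] > f_lo["rp.theta.global"]

    def test_ws_theta_higher_peen_lower_than_control(self):
        cfg = GeneratorConfig(seed=6, between_subject_sd=0.0, **SMALL)
        ws, _ = generate_subject(cfg, "WS", 0)
        ctrl, _ = generate_subject(cfg, "control", 0)
        f_ws = spectral_features([preprocess(ws[0])])
        f_ctrl = spectral_features([preprocess(ctrl[0])])
        assert f_ws["rp.theta.global"] > f_ctrl["rp.theta.global"]
        assert f_ws["rp.beta.global"] < f_ctrl["rp.beta.global"]
        pe_ws = np.mean([permutation_entropy(preprocess(ws[0]).samples[c], 3, 2)
                         for c in range(19)])
        pe_ctrl = np.mean([permutation_entropy(preprocess(ctrl[0]).samples[c], 3, 2)
                           for c in range(19)])
        assert pe_ws < pe_ctrl

    def test_rp_calibration_near_targets(self):
        """Measured global relative powers track the configured targets.

        Within +-0.05 of the normalized per-group target for every band
        (generator/spectral-module self-consistency).
        """
        cfg = GeneratorConfig(seed=8, between_subject_sd=0.0, segment_s=60.0,
                              n_segments_ws=1, n_segments_ctrl=1)
        for group in ("WS", "control"):
            segs, _ = generate_subject(cfg, group, 0)
            feats = spectral_features([preprocess(segs[0])])
            targets = cfg.band_targets[group]
            tsum = sum(targets.values())
            for band, t in targets.items():
                measured = feats[f"rp.{band}.global"]
                assert measured == pytest.approx(t / tsum, abs=0.05), (group, band)

    def test_zero_effect_config_equalizes_groups(self):
        cfg = zero_effect_config(GeneratorConfig(seed=3, **SMALL))
        assert cfg.band_targets["WS"] == cfg.band_targets["control"]
        assert cfg.qpc_strength["WS"] == cfg.qpc_strength["control"]
        assert cfg.regularity["WS"] == cfg.regularity["control"]

    def test_planted_genetic_effect_shifts_theta(self):
        cfg = GeneratorConfig(seed=12, between_subject_sd=0.0,
                              planted_genetic_theta=0.5, **SMALL)
        plain, _ = generate_subject(cfg, "WS", 0, genetic_flag=0)
        shifted, _ = generate_subject(cfg, "WS", 0, genetic_flag=1)
        f0 = spectral_features([preprocess(plain[0])])
        f1 = spectral_features([preprocess(shifted[0])])
        assert f1["rp.theta.global"] > f0["rp.theta.global"]

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError, match="invalid group"):
            generate_subject(GeneratorConfig(**SMALL), "patient", 0)


class TestFixtures:
    def test_sinusoid_alpha_dominant(self):
        rec = make_fixture("sinusoid", {"f": 10.0, "duration_s": 60})
        from wsqeeg import segment_epochs, welch_psd, relative_power
        two = Recording(np.vstack([rec.samples, rec.samples * 0.5]),
                        250.0, ["Fp1", "Fp2"])
        spec = welch_psd(segment_epochs(two, 2.0, 0.25), "Fp1")
        assert relative_power(spec, (8.0, 13.0)) > 0.95

    def test_constant_fixture_zero_entropy_path(self):
        rec = make_fixture("constant", {"value": 2.0, "duration_s": 4})
        from wsqeeg import approximate_entropy, permutation_entropy, sample_entropy
        x = rec.samples[0]
        assert approximate_entropy(x) == 0.0
        assert sample_entropy(x) == 0.0
        assert permutation_entropy(x, 3, 1) == 0.0

    def test_determinism(self):
        a = make_fixture("pink_noise", {"duration_s": 4}, seed=5)
        b = make_fixture("pink_noise", {"duration_s": 4}, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture kind"):
            make_fixture("brownian", {})

    def test_unused_params_rejected(self):
        with pytest.raises(ValueError, match="unused fixture params"):
            make_fixture("sinusoid", {"f": 10.0, "bogus": 1})
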