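"""Group comparison, BH-FDR, and etiology regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_reject_naive, bh_stepup_naive
from wsqeeg import (FeatureTable, bh_fdr, compare_groups, regress_etiology,
                    two_sample_ttest)
from wsqeeg.group_stats import (channel_tmap, parse_feature_name, ttest_matrix)
from wsqeeg.signal_io import SubjectMeta


class TestTTest:
    def test_identical_groups(self):
        t, p = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_worked_example_pooled(self):
        t, p = two_sample_ttest([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert t == pytest.approx(-2.0, abs=1e-12)
        assert p == pytest.approx(0.0805, abs=5e-4)

    def test_swap_flips_sign(self):
        a, b = [1.0, 2, 3, 9], [2.0, 4, 4, 5]
        t1, p1 = two_sample_ttest(a, b)
        t2, p2 = two_sample_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_sample_ttest([1.0], [1.0, 2.0])

    def test_matrix_matches_scipy(self, rng):
        a = rng.standard_normal((8, 10))
        b = rng.standard_normal((5, 10)) + 0.5
        t, p = ttest_matrix(a, b)
        for j in range(10):
            tj, pj = two_sample_ttest(a[:, j], b[:, j])
            assert t[j] == pytest.approx(tj, rel=1e-12)
            assert p[j] == pytest.approx(pj, rel=1e-12)


class TestBhFdr:
    def test_worked_example_all_rejected(self):
        # step-up rule: p_(4) = 0.05 <= 4 * 0.05 / 4, so all four reject;
        # the adjusted q ties the boundary exactly (q <= alpha, not <)
        p = [0.01, 0.02, 0.04, 0.05]
        assert all(bh_reject_naive(p, 0.05))
        assert np.all(bh_fdr(p) <= 0.05 + 1e-15)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.031])[0] == pytest.approx(0.031)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_stepup_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        np.testing.assert_allclose(bh_fdr(p), bh_stepup_naive(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equality_property(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_stepup_naive(p), atol=1e-12)

    def test_rejections_match_stepup_rule(self):
        for seed in range(20):
            p = np.random.default_rng(seed + 1000).uniform(size=15) ** 2
            by_q = bh_fdr(p) < 0.05
            np.testing.assert_array_equal(by_q, bh_reject_naive(p, 0.05))

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            bh_fdr([0.5, 1.2])


def _toy_cohort(rng, n_ws=12, n_ctrl=10, effect=0.0, n_feat=6):
    subjects = [f"ws{i:02d}" for i in range(n_ws)] + \
               [f"c{i:02d}" for i in range(n_ctrl)]
    meta = ([SubjectMeta(s, "WS", int(rng.random() < 0.3), int(rng.random() < 0.5))
             for s in subjects[:n_ws]]
            + [SubjectMeta(s, "control", 0, 0) for s in subjects[n_ws:]])
    names = [f"rp.theta.ch{i}" for i in range(n_feat - 1)] + ["rp.theta.global"]
    values = rng.standard_normal((n_ws + n_ctrl, n_feat))
    values[:n_ws] += effect
    return FeatureTable(subjects, names, values), meta


class TestCompareGroups:
    def test_null_cohort_no_significant(self, rng):
        table, meta = _toy_cohort(rng)
        results = compare_groups(table, meta)
        assert sum(r.significant for r in results) == 0

    def test_strong_effect_detected_with_direction(self, rng):
        table, meta = _toy_cohort(rng, effect=3.0)
        results = compare_groups(table, meta)
        for r in results:
            assert r.significant and r.t_stat > 0
            assert r.mean_ws > r.mean_ctrl

    def test_identical_groups_permuted_labels(self, rng):
        # copy a group onto both labels: the null is exact
        table, meta = _toy_cohort(rng, n_ws=10, n_ctrl=10)
        table.values[10:] = table.values[:10]
        results = compare_groups(table, meta)
        assert all(not r.significant for r in results)
        assert all(abs(r.t_stat) < 1e-9 for r in results)

    def test_degenerate_feature_dropped_with_warning(self, rng):
        table, meta = _toy_cohort(rng)
        table.values[:, 2] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            results = compare_groups(table, meta)
        assert len(results) == len(table.feature_names) - 1

    def test_fdr_family_vs_global_scope(self, rng):
        table, meta = _toy_cohort(rng, effect=1.0)
        fam = {r.feature: r.q_value for r in compare_groups(table, meta)}
        glob = {r.feature: r.q_value
                for r in compare_groups(table, meta, fdr_scope="global")}
        # the lone global feature is its own stratum under family scope
        r_global = "rp.theta.global"
        assert fam[r_global] <= glob[r_global] or fam[r_global] == glob[r_global]

    def test_sem_and_sd_reported(self, rng):
        table, meta = _toy_cohort(rng)
        r = compare_groups(table, meta)[0]
        ws_vals = table.values[:12, 0]
        assert r.sd_ws == pytest.approx(ws_vals.std(ddof=1))
        assert r.sem_ws == pytest.approx(ws_vals.std(ddof=1) / np.sqrt(12))


class TestFeatureNameParsing:
    @pytest.mark.parametrize("name,expected", [
        ("rp.theta.O1", ("rp", "theta", "channel")),
        ("rp.theta.global", ("rp", "theta", "global")),
        ("coh.delta_theta.F4-F8", ("coh", "delta_theta", "channel")),
        ("fiwbic.theta_alpha.global", ("fiwbic", "theta_alpha", "global")),
        ("ent.peen.Cz", ("ent", "peen", "channel")),
    ])
    def test_parse(self, name, expected):
        assert parse_feature_name(name) == expected


class TestChannelTmap:
    def test_nonsignificant_zeroed(self, rng):
        table, meta = _toy_cohort(rng, effect=3.0)
        table.values[:, 1] = rng.standard_normal(22)  # kill one channel effect
        results = compare_groups(table, meta)
        tmap = channel_tmap(results, "rp", "theta")
        row = tmap.set_index("channel")["t"]
        assert row["ch1"] == 0.0
        assert row["ch0"] != 0.0


class TestRegression:
    def _ws_table(self, rng, n=20, beta_gen=0.0, noise=1.0):
        subjects = [f"ws{i:02d}" for i in range(n)]
        struct = (rng.random(n) < 0.3).astype(int)
        gen = (rng.random(n) < 0.5).astype(int)
        struct[0], gen[0] = 1, 1   # guarantee variation
        struct[1], gen[1] = 0, 0
        meta = [SubjectMeta(s, "WS", int(st_), int(g))
                for s, st_, g in zip(subjects, struct, gen)]
        y = 3.0 + beta_gen * gen + noise * rng.standard_normal(n)
        table = FeatureTable(subjects, ["rp.theta.global"], y[:, None])
        return table, meta, gen

    def test_exact_fit_recovers_beta(self, rng):
        table, meta, gen = self._ws_table(rng, beta_gen=2.0, noise=0.0)
        r = regress_etiology(table, meta)[0]
        assert r.beta_genetic == pytest.approx(2.0, abs=1e-9)
        assert r.p_genetic < 1e-12
        assert r.valid

    def test_null_pvalues_uniform(self):
        # Kolmogorov-Smirnov of null p-values vs U(0,1) over 200 simulations
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            table, meta, _ = self._ws_table(rng)
            pvals.append(regress_etiology(table, meta)[0].p_genetic)
        from scipy.stats import kstest
        stat, _ = kstest(pvals, "uniform")
        assert stat < 1.36 / np.sqrt(200)  # 5% critical value at n=200

    def test_collinear_flags_invalid(self, rng):
        table, meta, gen = self._ws_table(rng)
        for m in meta:
            m.structural_flag = m.genetic_flag
        r = regress_etiology(table, meta)[0]
        assert not r.valid

    def test_fdr_applied_per_predictor(self, rng):
        subjects = [f"ws{i}" for i in range(20)]
        gen = (np.arange(20) % 2)
        meta = [SubjectMeta(s, "WS", int(i < 6), int(g))
                for i, (s, g) in enumerate(zip(subjects, gen))]
        values = rng.standard_normal((20, 8))
        table = FeatureTable(subjects, [f"rp.theta.ch{i}" for i in range(8)], values)
        results = regress_etiology(table, meta)
        qs = np.array([r.q_genetic for r in results])
        ps = np.array([r.p_genetic for r in results])
        np.testing.assert_allclose(qs, bh_stepup_naive(ps), atol=1e-12)
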