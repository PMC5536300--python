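"""Granger causality indices, mediated influence, order selection, and
nonparametric group comparison."""

import numpy as np
import pytest

from icahpm.cohort import simulate_var
from icahpm.gc import (
    GCIRecord,
    gci,
    gci_conditional,
    gci_via,
    gci_via_path_product,
    group_compare,
    rank_sum_test,
    select_order,
    subject_timecourse,
)
from icahpm.hpm import ReproducibleCluster
from icahpm.ica import ICMap


def _chain_series(t, c_xm=0.8, c_my=0.8, c_xy=0.0, seed=0):
    """x -> m -> y chain with optional direct x -> y link."""
    a = np.zeros((1, 3, 3))
    a[0, 1, 0] = c_xm
    a[0, 2, 1] = c_my
    a[0, 2, 0] = c_xy
    z = simulate_var(a, t, np.random.default_rng(seed))
    return z[0], z[1], z[2]


class TestGCI:
    def test_independent_white_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 2000))
        assert gci(x, y, p=1) < 0.01

    def test_planted_lag_matches_analytic_value(self):
        """y_t = 0.8 x_{t-1} + e with unit variances: the restricted model
        leaves variance 1.64, the full model 1.0, so GCI -> ln(1.64)."""
        rng = np.random.default_rng(1)
        t = 5000
        x = rng.standard_normal(t)
        e = rng.standard_normal(t)
        y = np.zeros(t)
        y[1:] = 0.8 * x[:-1] + e[1:]
        assert gci(x, y, p=1) == pytest.approx(np.log(1.64), abs=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 500))
        base = gci(x, y, p=2)
        assert gci(3.7 * x, y, p=2) == pytest.approx(base, abs=1e-10)
        assert gci(x, 0.002 * y, p=2) == pytest.approx(base, abs=1e-10)

    def test_nonnegative_under_many_draws(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x, y = rng.standard_normal((2, 60))
            assert gci(x, y, p=2) >= 0.0

    def test_short_series_and_constant_series_rejected(self):
        with pytest.raises(ValueError):
            gci(np.zeros(8) + np.arange(8), np.arange(8.0), p=1)
        with pytest.raises(ValueError):
            gci(np.ones(100), np.random.default_rng(0).normal(size=100), p=1)


class TestMediatedGCI:
    def test_chain_detected_and_conditional_small(self):
        """Pure chain x -> m -> y (one-step lags): x's influence reaches y
        after two steps, so the model order must cover two lags; the total
        index is then carried by the mediator and conditioning on m
        removes it."""
        x, m, y = _chain_series(5000, seed=3)
        assert gci_via(x, y, m, p=2) > 0.05
        assert gci_conditional(x, y, m, p=2) < 0.01

    def test_direct_link_not_attributed_to_mediator(self):
        rng = np.random.default_rng(4)
        t = 5000
        x = rng.standard_normal(t)
        e = rng.standard_normal(t)
        y = np.zeros(t)
        y[1:] = 0.8 * x[:-1] + e[1:]
        m = rng.standard_normal(t)  # independent bystander
        assert gci_via(x, y, m, p=2) < 0.01

    def test_mutually_independent_series_near_zero(self):
        rng = np.random.default_rng(5)
        x, y, m = rng.standard_normal((3, 3000))
        assert gci_via(x, y, m, p=1) < 0.01

    def test_path_product_variant_agrees_on_chain(self):
        x, m, y = _chain_series(5000, seed=6)
        assert gci_via_path_product(x, y, m, p=1) > 0.05

    def test_mediator_identity_constraints(self):
        with pytest.raises(ValueError):
            GCIRecord("s", 1, 2, 1, 1, 0.1)
        with pytest.raises(ValueError):
            GCIRecord("s", 1, 2, None, 1, -0.5)


class TestSelectOrder:
    def test_var1_data_selects_one(self):
        hits = 0
        for seed in range(20):
            a = np.array([[[0.6, 0.2], [0.0, 0.5]]])
            z = simulate_var(a, 2000, np.random.default_rng(seed))
            if select_order([z[0], z[1]], max_p=4) == 1:
                hits += 1
        assert hits >= 18

    def test_var2_data_selects_two(self):
        hits = 0
        for seed in range(20):
            a = np.zeros((2, 2, 2))
            a[0] = [[0.4, 0.0], [0.3, 0.3]]
            a[1] = [[-0.5, 0.0], [0.0, 0.35]]
            z = simulate_var(a, 2000, np.random.default_rng(seed))
            if select_order([z[0], z[1]], max_p=4) == 2:
                hits += 1
        assert hits >= 16

    def test_max_p_one_returns_one(self):
        rng = np.random.default_rng(7)
        assert select_order([rng.normal(size=200)], max_p=1) == 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_order([np.arange(6.0)], max_p=3)


class TestRankSum:
    def test_extreme_separation_exact_p(self):
        """{1..5} vs {6..10}: the exact two-sided p is 2/252."""
        z, p = rank_sum_test(np.arange(1.0, 6.0), np.arange(6.0, 11.0))
        assert p == pytest.approx(2.0 / 252.0, rel=1e-9)
        assert z < 0

    def test_sign_convention_first_group_larger_positive(self):
        z, _ = rank_sum_test(np.arange(6.0, 11.0), np.arange(1.0, 6.0))
        assert z > 0

    def test_null_calibration(self):
        """Identical distributions: |z| < 2.58 in >= 95% of 200 replicates
        and the p < 0.05 fraction sits in the binomial band around 0.05."""
        inside = 0
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a, b = rng.standard_normal((2, 20))
            z, p = rank_sum_test(a, b)
            if abs(z) < 2.58:
                inside += 1
            if p < 0.05:
                rejections += 1
        assert inside >= 190
        # 95% binomial band around 0.05 for 200 trials: [0.0198, 0.0802]
        assert 0.0198 <= rejections / 200 <= 0.0802


class TestGroupCompare:
    def _values(self, pat, con):
        vals = {}
        labels = {}
        for i, v in enumerate(pat):
            vals[f"p{i}"] = v
            labels[f"p{i}"] = "patient"
        for i, v in enumerate(con):
            vals[f"c{i}"] = v
            labels[f"c{i}"] = "control"
        return vals, labels

    def test_shifted_group_has_negative_z_and_medians(self):
        rng = np.random.default_rng(8)
        con = np.abs(rng.normal(0.2, 0.05, 20))
        pat = con * 0.3
        vals, labels = self._values(pat, con)
        cmp_ = group_compare(vals, labels, edge=(0, 1))
        assert cmp_.rank_sum_z < 0
        assert cmp_.group_medians["patient"] < cmp_.group_medians["control"]
        assert cmp_.signed_rank_p["patient"] < 0.01  # positive index vs zero
        assert cmp_.n_per_group == {"patient": 20, "control": 20}

    def test_missing_values_excluded_listwise(self):
        rng = np.random.default_rng(9)
        vals, labels = self._values(rng.normal(size=8), rng.normal(size=8))
        vals["p0"] = None
        cmp_ = group_compare(vals, labels)
        assert cmp_.n_per_group["patient"] == 7

    def test_group_with_too_few_subjects_rejected(self):
        vals, labels = self._values([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            group_compare(vals, labels)

    def test_planted_var_difference_power_and_false_rate(self):
        """Per-subject GCIs from the planted group VAR models: the
        rank-sum test flags the weakened edges with power >= 0.8 and flags
        under 10% of unplanted directed pairs (20+20 subjects per
        replicate cohort, time-course level)."""
        from icahpm.cohort import default_spec

        spec = default_spec(n_per_group=(2, 2))  # only coefficients needed
        planted = {(2, 0), (0, 3)}
        all_pairs = [(i, j) for i in range(4) for j in range(4) if i != j]
        n_rep = 10
        planted_hits = 0
        false_flags = 0
        for rep in range(n_rep):
            root = np.random.SeedSequence(1000 + rep)
            gcis = {pair: {} for pair in all_pairs}
            labels = {}
            seeds = root.spawn(40)
            for i, ss in enumerate(seeds):
                g = "patient" if i < 20 else "control"
                sid = f"s{i}"
                labels[sid] = g
                z = simulate_var(spec.var_coefficients[g], 140,
                                 np.random.default_rng(ss))
                for a, b in all_pairs:
                    gcis[(a, b)][sid] = gci(z[a], z[b], p=1)
            for pair in all_pairs:
                cmp_ = group_compare(gcis[pair], labels, edge=pair)
                if cmp_.rank_sum_p < 0.05:
                    if pair in planted:
                        planted_hits += 1
                    else:
                        false_flags += 1
        assert planted_hits / (n_rep * len(planted)) >= 0.8
        assert false_flags / (n_rep * (len(all_pairs) - len(planted))) < 0.10


class TestSubjectTimecourse:
    def _cluster(self, members):
        reps = {m.subject_id: m.spatial_z for m in members}
        return ReproducibleCluster(0, members, 0.9, np.zeros(10), reps)

    def _member(self, sid, tc):
        return ICMap(sid, 2, 0, np.zeros(10), np.asarray(tc, dtype=float))

    def test_single_member_standardized(self):
        tc = np.random.default_rng(0).normal(2.0, 3.0, 50)
        cl = self._cluster([self._member("a", tc)])
        out = subject_timecourse(cl, "a")
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)
        assert np.corrcoef(out, tc)[0, 1] == pytest.approx(1.0)

    def test_duplicate_members_give_same_course(self):
        tc = np.random.default_rng(1).normal(size=40)
        cl = self._cluster([self._member("a", tc), self._member("a", tc.copy())])
        out = subject_timecourse(cl, "a")
        assert np.corrcoef(out, tc)[0, 1] == pytest.approx(1.0)

    def test_correlated_members_pc1(self):
        """Two members correlated ~0.9: their first principal component
        correlates > 0.97 with each."""
        rng = np.random.default_rng(2)
        base = rng.standard_normal(300)
        tc1 = base + rng.normal(0, 0.33, 300)
        tc2 = base + rng.normal(0, 0.33, 300)
        assert np.corrcoef(tc1, tc2)[0, 1] > 0.85
        cl = self._cluster([self._member("a", tc1), self._member("a", tc2)])
        out = subject_timecourse(cl, "a")
        assert np.corrcoef(out, tc1)[0, 1] > 0.97
        assert np.corrcoef(out, tc2)[0, 1] > 0.97

    def test_absent_subject_returns_missing_marker(self):
        cl = self._cluster([self._member("a", np.arange(20.0))])
        assert subject_timecourse(cl, "zz") is None
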