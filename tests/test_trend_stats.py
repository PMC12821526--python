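import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nbquant import (InputError, cohort_report, fisher_exact_rxc, jonckheere_terpstra,
                     jt_statistic, kendall_tau, mann_whitney, normality_screen,
                     pairwise_fisher_bonferroni)
from oracles import (brute_force_jt_pvalue, brute_force_mw_pvalue, brute_force_tau_b,
                     brute_force_u)


class TestFisherExactRxc:
    def test_balanced_2x2_gives_p_one(self):
        assert fisher_exact_rxc([[1, 1], [1, 1]]).p_raw == pytest.approx(1.0)

    def test_matches_scipy_on_random_2x2_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, (2, 2))
            t += np.eye(2, dtype=t.dtype)  # avoid zero rows
            _, p_scipy = sps.fisher_exact(t)
            assert fisher_exact_rxc(t).p_raw == pytest.approx(p_scipy, rel=1e-9)

    def test_probabilities_over_fixed_margins_sum_to_one(self, rng):
        from nbquant.trend_stats import _enumerate_tables

        for _ in range(5):
            t = rng.integers(0, 8, (3, 2)) + 1
            rows = list(t.sum(axis=1))
            cols = list(t.sum(axis=0))
            n = int(t.sum())
            total = 0.0
            for tab in _enumerate_tables(rows, cols):
                # independent probability: product of row multinomials over
                # the column multinomial
                num = sum(math.lgamma(r + 1) for r in rows)
                num += sum(math.lgamma(c + 1) for c in cols)
                den = math.lgamma(n + 1)
                den += sum(math.lgamma(x + 1) for row in tab for x in row)
                total += math.exp(num - den)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_row_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_rxc([[0, 0], [3, 4]])


class TestPairwiseFisher:
    def test_identical_rows_all_adjusted_to_one(self):
        res = pairwise_fisher_bonferroni([[5, 10], [5, 10], [5, 10]])
        assert all(r.p_adjusted == 1.0 for r in res)

    def test_adjustment_is_three_times_raw_for_three_groups(self, rng):
        t = rng.integers(1, 10, (3, 2))
        for r in pairwise_fisher_bonferroni(t):
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_needs_three_groups(self):
        with pytest.raises(InputError):
            pairwise_fisher_bonferroni([[1, 2], [3, 4]])


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        r2 = mann_whitney([4, 5, 6], [1, 2, 3])
        assert r2.statistic == 9.0  # U + U' = n1 * n2

    def test_all_ties(self):
        r = mann_whitney([5, 5, 5], [5, 5, 5])
        assert r.statistic == 4.5
        assert r.p_raw == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1, 2])

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            x = rng.integers(0, 6, n1).astype(float)  # heavy ties
            y = rng.integers(0, 6, n2).astype(float)
            r = mann_whitney(x, y)
            assert r.statistic == brute_force_u(x, y)
            assert r.p_raw == pytest.approx(brute_force_mw_pvalue(x, y), abs=1e-12)

    def test_u_complement_identity(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(1, 9))
            y = rng.normal(size=rng.integers(1, 9))
            assert (mann_whitney(x, y).statistic + mann_whitney(y, x).statistic
                    == pytest.approx(len(x) * len(y)))

    def test_normal_approx_close_to_exact_at_moderate_n(self, rng):
        x = rng.poisson(6, 25).astype(float)
        y = rng.poisson(4, 20).astype(float)
        exact = mann_whitney(x, y, exact_limit=10_000)
        approx = mann_whitney(x, y, exact_limit=0)
        assert approx.p_raw == pytest.approx(exact.p_raw, abs=0.02)

    @given(st.integers(1, 10))
    @settings(max_examples=20, deadline=None)
    def test_bonferroni_adjustment_definition(self, m):
        r = mann_whitney([1, 2, 5, 3], [4, 2, 6, 8], adjust_m=m)
        assert r.p_adjusted == pytest.approx(min(1.0, m * r.p_raw))


class TestJonckheereTerpstra:
    def test_perfect_increase_attains_maximum(self):
        r = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == 12.0  # sum n_i n_j = 3 * 4 = 12
        assert r.z_value > 0

    def test_constant_groups_are_null(self):
        r = jonckheere_terpstra([[7, 7], [7, 7], [7, 7]])
        assert r.z_value == 0.0
        assert r.p_raw == 1.0

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(InputError):
            jonckheere_terpstra([[1, 2], [3, 4]])

    def test_reduces_to_mann_whitney_for_two_groups(self, rng):
        x = rng.integers(0, 8, 6).astype(float)
        y = rng.integers(0, 8, 5).astype(float)
        # JT over (x, y) counts second-sample wins = U of (y, x)
        assert jt_statistic([x, y]) == mann_whitney(y, x).statistic

    def test_exact_mode_matches_brute_force(self, rng):
        for _ in range(8):
            ns = rng.integers(2, 4, 3)
            groups = [rng.integers(0, 5, n).astype(float) for n in ns]
            r = jonckheere_terpstra(groups, mode="exact")
            assert r.p_raw == pytest.approx(brute_force_jt_pvalue(groups), abs=1e-12)

    def test_normal_approx_within_mc_error_of_permutation(self, rng):
        groups = [rng.poisson(5, 5).astype(float) for _ in range(3)]
        r_perm = jonckheere_terpstra(groups, mode="permutation", n_perm=20_000, seed=0)
        r_norm = jonckheere_terpstra(groups)
        assert r_norm.p_raw == pytest.approx(r_perm.p_raw, abs=0.03)

    def test_decreasing_trend_gives_negative_z(self, rng):
        groups = [rng.poisson(10, 30), rng.poisson(6, 30), rng.poisson(3, 30)]
        r = jonckheere_terpstra([g.astype(float) for g in groups])
        assert r.z_value < 0
        assert r.p_raw < 0.05

    def test_permutation_mode_is_seed_deterministic(self):
        groups = [[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]]
        a = jonckheere_terpstra(groups, mode="permutation", n_perm=500, seed=11)
        b = jonckheere_terpstra(groups, mode="permutation", n_perm=500, seed=11)
        assert a.p_raw == b.p_raw


class TestKendallTau:
    def test_perfect_concordance(self):
        r = kendall_tau([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0])
        assert r.statistic == pytest.approx(1.0)

    def test_balanced_independence_gives_zero(self):
        r = kendall_tau([0, 0, 1, 1], [1.0, 2.0, 2.0, 1.0])
        assert r.statistic == pytest.approx(0.0)

    def test_matches_scipy_and_brute_force(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 30))
            g = rng.integers(0, 3, n).astype(float)
            v = rng.integers(0, 8, n).astype(float)
            if np.unique(g).size < 2 or np.unique(v).size < 2:
                continue
            r = kendall_tau(g, v)
            tau_s, p_s = sps.kendalltau(g, v)
            assert r.statistic == pytest.approx(tau_s, abs=1e-12)
            assert r.p_raw == pytest.approx(p_s, abs=1e-9)
            assert r.statistic == pytest.approx(brute_force_tau_b(g, v), abs=1e-12)

    def test_constant_values_reported_absent(self):
        r = kendall_tau([0, 1, 2], [5.0, 5.0, 5.0])
        assert r.statistic is None and "undefined" in r.label


class TestNormalityScreen:
    def test_skewed_sample_rejected_as_normal(self):
        x = np.random.default_rng(3).exponential(1.0, 40)
        assert normality_screen(x).p_raw < 0.05

    def test_w_in_unit_interval_and_affine_invariant(self, rng):
        x = rng.normal(10, 2, 50)
        r1 = normality_screen(x)
        r2 = normality_screen(3.5 * x - 100)
        assert 0 < r1.statistic <= 1
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_sample_size_bounds(self):
        with pytest.raises(InputError):
            normality_screen([1.0, 2.0])


def _table(groups_counts, cyto=None):
    rows = []
    i = 0
    for g, counts in groups_counts.items():
        for c in counts:
            rows.append(
                {"source_id": f"s{i}", "group": g, "n_bodies": c,
                 "mean_diameter_um": 0.5 + 0.01 * (i % 7),
                 "mean_max_intensity": 100.0 + (i % 13),
                 "cytoplasmic_flag": bool(cyto[i]) if cyto is not None else False,
                 "excluded": False, "exclusion_reason": "none"})
            i += 1
    df = pd.DataFrame(rows)
    df["cytoplasmic_flag"] = df["cytoplasmic_flag"].astype("boolean")
    return df


class TestCohortReport:
    def test_median_of_even_sample(self):
        t = _table({"young": [4, 5, 6, 7], "old": [1, 2, 3, 4]})
        rep = cohort_report(t, group_order=["young", "old"])
        assert rep["summaries"]["n_bodies"]["young"]["median"] == 5.5

    def test_one_group_summary_only_with_warning(self):
        t = _table({"young": [4, 5, 6]})
        rep = cohort_report(t)
        assert rep["tests"] == {} or all("pairwise_mw" not in v for v in rep["tests"].values())
        assert any("fewer than 2" in w for w in rep["warnings"])

    def test_group_maxima_reported(self, rng):
        counts = {"young": [min(int(c), 20) for c in rng.poisson(8, 20)] + [33],
                  "middle": [min(int(c), 12) for c in rng.poisson(6, 20)] + [13],
                  "old": [min(int(c), 6) for c in rng.poisson(4, 20)] + [7]}
        rep = cohort_report(_table(counts), group_order=["young", "middle", "old"])
        s = rep["summaries"]["n_bodies"]
        assert s["young"]["max"] == 33 and s["middle"]["max"] == 13 and s["old"]["max"] == 7
        assert s["young"]["max"] / s["middle"]["max"] == pytest.approx(2.5, abs=0.05)
        assert s["young"]["max"] / s["old"]["max"] == pytest.approx(4.7, abs=0.02)

    def test_jt_gated_on_monotone_medians(self):
        non_mono = _table({"young": [1, 1, 2], "middle": [8, 9, 10], "old": [1, 2, 2]})
        rep = cohort_report(non_mono, group_order=["young", "middle", "old"])
        assert rep["tests"]["n_bodies"]["jt"] is None
        assert any("JT skipped" in w for w in rep["warnings"])
        forced = cohort_report(non_mono, group_order=["young", "middle", "old"],
                               always_run_jt=True)
        assert forced["tests"]["n_bodies"]["jt"] is not None

    def test_decreasing_cohort_runs_full_battery(self, rng):
        counts = {"young": list(rng.poisson(8, 30)),
                  "middle": list(rng.poisson(6, 30)),
                  "old": list(rng.poisson(4, 30))}
        cyto = [False] * 90
        rep = cohort_report(_table(counts, cyto), group_order=["young", "middle", "old"])
        tests = rep["tests"]["n_bodies"]
        assert len(tests["pairwise_mw"]) == 3
        if tests["jt"] is not None:
            assert tests["jt"].z_value < 0
        assert "cytoplasmic_flag" in rep["tests"]

    def test_excluded_rows_are_ignored(self):
        t = _table({"young": [4, 5, 6, 7], "old": [1, 2, 3]})
        t.loc[0, "excluded"] = True
        rep = cohort_report(t, group_order=["young", "old"])
        assert rep["n_per_group"]["young"] == 3

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            cohort_report(_table({"young": [1]}).iloc[:0])
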