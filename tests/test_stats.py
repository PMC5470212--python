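import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import cliffs_delta_bruteforce, mannwhitney_exact_bruteforce
from ribopolya.stats import (
    cliffs_delta,
    correlate,
    inducible_set,
    log2_fold_change,
    mann_whitney,
    top_fraction_by_abs_difference,
    venn_region_counts,
    welch_t,
)


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        r, _ = correlate(x, y, "pearson")
        assert r == pytest.approx(1.0)

    def test_strictly_decreasing_spearman(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 5.0, 2.0, 1.0]
        rho, _ = correlate(x, y, "spearman")
        assert rho == pytest.approx(-1.0)

    def test_spearman_hand_case(self):
        rho, _ = correlate([1, 2, 3, 4], [2, 1, 4, 3], "spearman")
        assert rho == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestWelchT:
    def test_identical_samples_t_zero(self):
        t, _ = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)

    def test_shift_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        y = x + 10
        t, _ = welch_t(x, y)
        # t = (mean_x - mean_y) / sqrt(s2/n + s2/m), s2 = 1, n = m = 3
        assert t == pytest.approx(-10 / math.sqrt(2 / 3))

    def test_antisymmetric(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(1, 2, 12)
        t1, p1 = welch_t(x, y)
        t2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestMannWhitney:
    def test_full_separation_u_zero(self):
        u, _ = mann_whitney([1.0, 2.0], [10.0, 11.0, 12.0])
        assert u == 0.0

    def test_tied_singletons(self):
        u, _ = mann_whitney([5.0], [5.0])
        assert u == 0.5

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 6)
        u, p = mann_whitney(x, y)
        u_exp, p_exp = mannwhitney_exact_bruteforce(list(x), list(y))
        assert u == pytest.approx(u_exp)
        assert p == pytest.approx(p_exp, rel=1e-9)


class TestCliffsDelta:
    def test_identical_samples_negligible(self):
        res = cliffs_delta([1, 2], [1, 2])
        assert res.delta == 0.0 and res.magnitude == "negligible"

    def test_full_dominance_large(self):
        res = cliffs_delta([10, 11], [1, 2])
        assert res.delta == 1.0 and res.magnitude == "large"
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_worked_value(self):
        res = cliffs_delta([1, 2, 3], [2, 3, 4])
        assert res.delta == pytest.approx(-5 / 9)
        assert res.magnitude == "intermediate"

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(60):
            n, m = rng.integers(1, 51, size=2)
            x = rng.normal(0, 1, n)
            y = rng.normal(rng.uniform(-1, 1), 1, m)
            res = cliffs_delta(x, y)
            assert res.delta == pytest.approx(cliffs_delta_bruteforce(x, y))

    def test_magnitude_bins_honour_cutoffs(self):
        # construct deltas straddling the printed 0.147 and 0.60 cutoffs
        def delta_of(k, n=1000):
            x = np.zeros(n)
            x[:k] = 2.0  # k values dominate, rest tie
            y = np.ones(n)
            x[k:] = 1.0
            return cliffs_delta(x, y)

        assert delta_of(146).delta == pytest.approx(0.146)
        assert delta_of(146).magnitude == "negligible"
        assert delta_of(147).magnitude == "intermediate"
        assert delta_of(599).magnitude == "intermediate"
        assert delta_of(600).magnitude == "large"

    def test_antisymmetric(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 20)
        assert cliffs_delta(x, y).delta == pytest.approx(-cliffs_delta(y, x).delta)

    @given(st.sampled_from([math.exp, lambda v: v**3, lambda v: 2 * v + 7]))
    def test_invariant_under_monotone_transform(self, f):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.4, 1, 9)
        before = cliffs_delta(x, y).delta
        after = cliffs_delta([f(v) for v in x], [f(v) for v in y]).delta
        assert before == pytest.approx(after)

    def test_ci_brackets_delta(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(2, 30)))
            y = rng.normal(0.3, 1, int(rng.integers(2, 30)))
            res = cliffs_delta(x, y)
            assert -1 <= res.ci_low <= res.delta <= res.ci_high <= 1


class TestFoldChangeAndInducible:
    def test_log2_fold_change_values(self):
        assert log2_fold_change(8, 2) == 2.0
        assert log2_fold_change(5, 5) == 0.0
        assert log2_fold_change(10, 2) == pytest.approx(math.log2(5))
        with pytest.raises(ValueError):
            log2_fold_change(0, 1)

    def test_inclusion_rules(self):
        pre = pd.Series({"in": 2.0, "low_pre": 0.5, "lfc_at_2": 2.0, "tpm_at_1": 1.0})
        post = pd.Series({"in": 10.0, "low_pre": 100.0, "lfc_at_2": 8.0, "tpm_at_1": 100.0})
        assert inducible_set(pre, post) == {"in"}

    def test_antitone_in_thresholds(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        pre = pd.Series(rng.lognormal(1, 1, 100), index=genes)
        post = pd.Series(rng.lognormal(2, 1, 100), index=genes)
        loose = inducible_set(pre, post, tpm_threshold=0.5, lfc_threshold=1.0)
        tight = inducible_set(pre, post, tpm_threshold=2.0, lfc_threshold=2.0)
        assert tight <= loose


class TestVenn:
    def test_two_disjoint_sets(self):
        comp = venn_region_counts({"S1": {"a"}, "S2": {"b"}})
        assert comp.region_counts[frozenset({"S1"})] == 1
        assert comp.region_counts[frozenset({"S2"})] == 1
        assert comp.region_counts[frozenset({"S1", "S2"})] == 0

    def test_four_identical_sets(self):
        s = set(range(5))
        comp = venn_region_counts({k: s for k in "ABCD"})
        for region, count in comp.region_counts.items():
            assert count == (5 if len(region) == 4 else 0)

    def test_matches_membership_signature_oracle(self, rng):
        names = ["A", "B", "C", "D"]
        sets = {n: set(rng.choice(100, size=rng.integers(10, 60), replace=False).tolist())
                for n in names}
        comp = venn_region_counts(sets)
        union = set().union(*sets.values())
        assert comp.union_size == len(union)
        for element in union:
            sig = frozenset(n for n in names if element in sets[n])
            assert comp.region_counts[sig] >= 1
        assert sum(comp.region_counts.values()) == len(union)

    def test_set_count_bounds(self):
        with pytest.raises(ValueError):
            venn_region_counts({"A": set()})


class TestTopFraction:
    def test_selects_largest_absolute_differences(self):
        a = pd.Series({"g1": 10.0, "g2": 1.0, "g3": 5.0, "g4": 2.0})
        b = pd.Series({"g1": 1.0, "g2": 1.1, "g3": 5.2, "g4": 2.0})
        assert top_fraction_by_abs_difference(a, b, fraction=0.25) == {"g1"}
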