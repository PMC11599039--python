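"""Association statistics: exact tests, pooling, heterogeneity, power."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import norm

import paraclone as pc
from paraclone.assoc_stats import TableError, TwoByTwoTable, heterogeneity


def fisher_oracle_exact(a, b, c, d):
    """Exhaustive rational enumeration over all tables with fixed margins."""
    N, K, n = a + b + c + d, a + b, a + c

    def comb(n_, k_):
        return Fraction(math.comb(n_, k_))

    denom = comb(N, n)
    p_obs = comb(K, a) * comb(N - K, n - a) / denom
    total = Fraction(0)
    for x in range(max(0, n - (N - K)), min(K, n) + 1):
        p_x = comb(K, x) * comb(N - K, n - x) / denom
        if p_x <= p_obs:
            total += p_x
    return float(total)


small_cells = st.integers(min_value=0, max_value=50)


class TestBuildTable:
    def test_from_published_counts(self):
        t = pc.build_table_from_counts(3, 998, 20, 17554)
        assert (t.a, t.b, t.c, t.d) == (3, 995, 20, 17534)
        assert t.case_af == pytest.approx(0.00301, abs=5e-6)

    def test_zero_alt_counts_valid(self):
        t = pc.build_table_from_counts(0, 10, 0, 10)
        assert t.case_af == 0.0 and t.control_af == 0.0

    def test_alt_exceeding_total_rejected(self):
        with pytest.raises(TableError):
            pc.build_table_from_counts(11, 10, 0, 10)


class TestFisherExact:
    @pytest.mark.parametrize("counts,expected,digits", [
        ((1, 998, 0, 17554), 0.0538, 4),    # delins row
        ((1, 998, 3, 17554), 0.198, 3),     # p.S310G row
        ((3, 998, 20, 17554), 0.124, 3),    # p.L483P current series
        ((4, 1148, 2, 1800), 0.216, 3),     # p.L483P previous series
    ])
    def test_published_allele_tables(self, counts, expected, digits):
        t = pc.build_table_from_counts(*counts)
        p = pc.fisher_exact_two_sided(t).p_two_sided
        assert round(p, digits) == expected

    def test_only_attainable_table_gives_one(self):
        t = TwoByTwoTable(0, 12, 0, 34)
        assert pc.fisher_exact_two_sided(t).p_two_sided == 1.0

    @given(a=small_cells, b=small_cells, c=small_cells, d=small_cells)
    @settings(max_examples=150, deadline=None)
    def test_matches_exact_rational_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        t = TwoByTwoTable(a, b, c, d)
        got = pc.fisher_exact_two_sided(t).p_two_sided
        want = fisher_oracle_exact(a, b, c, d)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    @given(a=small_cells, b=small_cells, c=small_cells, d=small_cells)
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_reference(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        t = TwoByTwoTable(a, b, c, d)
        got = pc.fisher_exact_two_sided(t).p_two_sided
        want = scipy_fisher([[a, b], [c, d]])[1]
        assert got == pytest.approx(want, rel=1e-7, abs=1e-12)


PAPER_TABLES = [
    pc.build_table_from_counts(3, 998, 20, 17554, "current"),
    pc.build_table_from_counts(4, 1148, 2, 1800, "previous"),
]


class TestMantelHaenszel:
    def test_published_meta_analysis(self):
        m = pc.mh_common_or(PAPER_TABLES)
        assert round(m.or_mh, 2) == 2.85
        assert round(m.ci_low, 2) == 1.05
        assert round(m.ci_high, 2) == 7.76
        assert round(m.p_z, 4) == 0.0400

    def test_single_table_equals_crude_or(self):
        t = PAPER_TABLES[0]
        m = pc.mh_common_or([t])
        assert m.or_mh == pytest.approx(t.crude_or)
        assert m.or_mh == pytest.approx(3 * 17534 / (995 * 20))

    def test_order_invariance(self):
        m1 = pc.mh_common_or(PAPER_TABLES)
        m2 = pc.mh_common_or(PAPER_TABLES[::-1])
        assert m1.or_mh == pytest.approx(m2.or_mh)
        assert m1.log_or_se == pytest.approx(m2.log_or_se)

    def test_group_swap_inverts_or(self):
        t = PAPER_TABLES[0]
        swapped = TwoByTwoTable(t.b, t.a, t.d, t.c)
        assert pc.mh_common_or([swapped]).or_mh == pytest.approx(1 / t.crude_or)

    def test_ci_contains_point_and_wald_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            tabs = [TwoByTwoTable(*(int(x) for x in rng.integers(1, 80, 4)))
                    for _ in range(int(rng.integers(1, 4)))]
            m = pc.mh_common_or(tabs)
            assert m.ci_low <= m.or_mh <= m.ci_high
            assert (m.p_z < 0.05) == not_in_ci(m)

    def test_statsmodels_agreement(self):
        """Independent oracle: statsmodels' stratified-table MH estimator."""
        from statsmodels.stats.contingency_tables import StratifiedTable
        arr = np.array([[[t.a, t.c], [t.b, t.d]] for t in PAPER_TABLES]).transpose(1, 2, 0)
        stt = StratifiedTable(arr)
        m = pc.mh_common_or(PAPER_TABLES)
        assert m.or_mh == pytest.approx(float(stt.oddsratio_pooled), rel=1e-9)
        assert m.log_or_se == pytest.approx(float(stt.logodds_pooled_se), rel=1e-9)
        lo, hi = stt.oddsratio_pooled_confint()
        assert m.ci_low == pytest.approx(float(lo), rel=1e-6)
        assert m.ci_high == pytest.approx(float(hi), rel=1e-6)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(TableError):
            pc.mh_common_or([TwoByTwoTable(5, 0, 0, 5)])


def not_in_ci(m):
    return not (m.ci_low <= 1.0 <= m.ci_high)


class TestHeterogeneity:
    def test_published_no_heterogeneity(self):
        q, df, p_q, i2, tau2 = heterogeneity(PAPER_TABLES)
        assert round(p_q, 2) == 0.87
        assert i2 == 0.0 and tau2 == 0.0 and df == 1

    def test_identical_tables_give_zero_q(self):
        t = PAPER_TABLES[0]
        q, df, p_q, i2, tau2 = heterogeneity([t, t])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0 and tau2 == 0.0

    def test_matches_direct_formula_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            tabs = [TwoByTwoTable(*(int(x) for x in rng.integers(1, 60, 4)))
                    for _ in range(k)]
            q, df, p_q, i2, tau2 = heterogeneity(tabs)
            # independent recomputation from the definition
            lors = [math.log(t.a * t.d / (t.b * t.c)) for t in tabs]
            ws = [1 / (1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d) for t in tabs]
            mu = sum(w * y for w, y in zip(ws, lors)) / sum(ws)
            q_direct = sum(w * (y - mu) ** 2 for w, y in zip(ws, lors))
            assert q == pytest.approx(q_direct, rel=1e-9)
            assert df == k - 1
            if q <= df:
                assert i2 == 0.0 and tau2 == 0.0

    def test_single_table_rejected(self):
        with pytest.raises(TableError):
            heterogeneity([PAPER_TABLES[0]])


class TestSampleSize:
    def test_uncorrected_matches_closed_form(self):
        # independent evaluation of the textbook expression
        za, zb = norm.ppf(0.975), norm.ppf(0.8)
        p1, p2 = 0.0030, 0.0011
        pbar = (p1 + p2) / 2
        expect = (za * math.sqrt(2 * pbar * (1 - pbar))
                  + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2 / (p1 - p2) ** 2
        n = pc.sample_size_two_proportions(pc.PowerSpec(p1, p2))
        assert n == math.ceil(expect)
        assert 8.8e3 < n < 9.0e3

    def test_continuity_corrected_near_reported_requirement(self):
        n = pc.sample_size_two_proportions(
            pc.PowerSpec(0.0030, 0.0011, correction="continuity")
        )
        assert abs(n - 9948) / 9948 < 0.01

    def test_larger_difference_needs_fewer_samples(self):
        n1 = pc.sample_size_two_proportions(pc.PowerSpec(0.0030, 0.0011))
        n2 = pc.sample_size_two_proportions(pc.PowerSpec(0.0049, 0.0011))
        assert n2 < n1

    def test_invalid_proportions_rejected(self):
        with pytest.raises(TableError):
            pc.PowerSpec(0.001, 0.003)


class TestForestTable:
    def test_structure_matches_meta(self):
        m = pc.mh_common_or(PAPER_TABLES)
        df = pc.forest_table(m)
        assert list(df["study"])[:2] == ["current", "previous"]
        assert df.iloc[-1]["or"] == pytest.approx(m.or_mh)
        assert df.iloc[:2]["weight_pct"].sum() == pytest.approx(100.0)
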