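"""Statistical tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pulsesong.stats_compare import (
    ContingencyTable2x2,
    anova_bonferroni,
    fisher_exact,
    fisher_from_summaries,
    kruskal_steel,
    kruskal_steel_dwass,
    mann_whitney_u,
    stars,
)


def fisher_oracle_p(a, b, c, d):
    """Independent two-sided Fisher p via scipy's hypergeometric pmf."""
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(a)
    return float(pmf[pmf <= observed * (1 + 1e-12)].sum())


class TestFisherExact:
    def test_homogeneous_table_p_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)).p_value == 1.0

    def test_perfect_separation(self):
        p = fisher_exact(ContingencyTable2x2(10, 0, 0, 10)).p_value
        assert p == pytest.approx(1.082508822e-5, rel=1e-8)

    def test_seven_three_table_matches_enumeration(self):
        p = fisher_exact(ContingencyTable2x2(7, 3, 3, 7)).p_value
        assert p == pytest.approx(fisher_oracle_p(7, 3, 3, 7), rel=1e-10)

    def test_all_tables_total_at_most_20_match_oracle(self):
        for n in range(1, 21):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        mine = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
                        ref = fisher_oracle_p(a, b, c, d)
                        assert mine == pytest.approx(ref, rel=1e-9), (a, b, c, d)

    def test_symmetric_under_transpose_and_row_swap(self):
        a, b, c, d = 9, 4, 2, 11
        p = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
        assert fisher_exact(ContingencyTable2x2(a, c, b, d)).p_value == pytest.approx(p)
        assert fisher_exact(ContingencyTable2x2(c, d, a, b)).p_value == pytest.approx(p)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact(ContingencyTable2x2(0, 0, 3, 4))

    def test_from_summaries(self):
        a = {"n_pulses": 100, "n_polycyclic": 2}
        b = {"n_pulses": 100, "n_polycyclic": 40}
        report = fisher_from_summaries(a, b)
        assert report.p_value < 1e-9 and report.stars == "***"


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        report = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert report.statistic == 0.0

    def test_identical_multisets_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_exact_p_matches_labeling_enumeration_5v5(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 5), rng.normal(0.8, 1, 5)
        mine = mann_whitney_u(x, y).p_value
        # independent oracle: enumerate all C(10,5) labelings directly
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = 5 * 5 / 2.0
        obs = abs(ranks[:5].sum() - 15 - mu)
        hits = total = 0
        for comb in itertools.combinations(range(10), 5):
            u = ranks[list(comb)].sum() - 15
            total += 1
            hits += abs(u - mu) >= obs - 1e-9
        assert mine == pytest.approx(hits / total, rel=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            sps.mannwhitneyu(x, y, method="exact").pvalue, rel=1e-12
        )

    def test_asymptotic_close_to_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1, 35)
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            sps.mannwhitneyu(x, y, method="asymptotic").pvalue, rel=1e-9
        )


class TestAnovaBonferroni:
    def test_identical_groups_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        report = anova_bonferroni([g, list(g), list(g)])
        assert report.statistic == pytest.approx(0.0, abs=1e-12)
        assert report.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        report = anova_bonferroni([g1, g2])
        t = sps.ttest_ind(g1, g2, equal_var=True).statistic
        assert report.statistic == pytest.approx(t**2, rel=1e-10)

    def test_hand_computed_three_by_three(self):
        # groups [1,2,3], [2,3,4], [6,7,8]: SSB=42 (df 2), SSW=6 (df 6) -> F=21
        report = anova_bonferroni([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert report.statistic == pytest.approx(21.0, rel=1e-12)
        assert report.p_value == pytest.approx(sps.f.sf(21.0, 2, 6), rel=1e-9)

    def test_bonferroni_adjustment_and_ordering(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 15) for m in (0, 0.2, 3)]
        report = anova_bonferroni(groups)
        for c in report.pairwise:
            assert c.p_adjusted >= c.p_raw - 1e-15
            assert 0 <= c.p_adjusted <= 1


class TestKruskalSteelDwass:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        report = kruskal_steel_dwass([g, list(g), list(g)])
        assert report.statistic == pytest.approx(0.0, abs=1e-9)
        assert all(c.p_adjusted > 0.9 for c in report.pairwise)

    def test_hand_rankable_h_statistic(self):
        # ranks are the values themselves: rank sums 12, 15, 18 -> H = 0.8
        report = kruskal_steel_dwass([[1, 4, 7], [2, 5, 8], [3, 6, 9]])
        assert report.statistic == pytest.approx(0.8, rel=1e-12)

    def test_pairwise_statistic_matches_direct_formula(self):
        groups = [[1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]]
        report = kruskal_steel_dwass(groups)
        # direct evaluation for the first pair (n=3 vs 3, no ties)
        gi, gj = np.array(groups[0]), np.array(groups[1])
        ranks = sps.rankdata(np.concatenate([gi, gj]))
        w = ranks[3:].sum()
        mean = 3 * 7 / 2.0
        var = 3 * 3 / 12.0 * 7
        expected_q = math.sqrt(2.0) * abs(w - mean) / math.sqrt(var)
        assert report.pairwise[0].statistic == pytest.approx(expected_q, rel=1e-12)

    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(6)
        groups = [list(rng.normal(m, 0.5, 12)) for m in (0, 10, 20)]
        report = kruskal_steel_dwass(groups)
        assert all(c.p_adjusted < 0.01 for c in report.pairwise)

    def test_permutation_invariance_of_pairwise_p_set(self):
        rng = np.random.default_rng(7)
        groups = [list(rng.normal(m, 1, 10)) for m in (0, 1, 2)]
        p1 = sorted(c.p_adjusted for c in kruskal_steel_dwass(groups).pairwise)
        shuffled = [groups[2], groups[0], groups[1]]
        p2 = sorted(c.p_adjusted for c in kruskal_steel_dwass(shuffled).pairwise)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_exact_small_sample_variant(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        report = kruskal_steel_dwass(groups, method="exact")
        assert all(0 < c.p_adjusted <= 1 for c in report.pairwise)


class TestKruskalSteel:
    def test_identical_groups_all_ns(self):
        g = [1.0, 2.0, 3.0, 4.0]
        report = kruskal_steel([g, list(g), list(g)], control_index=0)
        assert all(c.p_adjusted > 0.9 for c in report.pairwise)

    def test_strongly_shifted_treatments_significant(self):
        rng = np.random.default_rng(10)
        control = list(rng.normal(0, 1, 10))
        treats = [list(rng.normal(8, 1, 10)), list(rng.normal(8, 1, 10))]
        report = kruskal_steel([control] + treats, control_index=0)
        assert all(c.p_adjusted < 0.05 for c in report.pairwise)

    def test_only_shifted_treatment_flagged(self):
        rng = np.random.default_rng(11)
        control = list(rng.normal(0, 1, 12))
        shifted = list(rng.normal(6, 1, 12))
        null = list(rng.normal(0, 1, 12))
        report = kruskal_steel([control, shifted, null], control_index=0)
        by_label = {c.label: c.p_adjusted for c in report.pairwise}
        assert by_label["group1 vs group0 (control)"] < 0.05
        assert by_label["group2 vs group0 (control)"] > 0.05

    def test_steel_p_matches_monte_carlo_reference(self):
        """Joint max-|Z| tail from the integral matches a seeded MC estimate."""
        rng = np.random.default_rng(12)
        control = list(rng.normal(0, 1, 10))
        treats = [list(rng.normal(1.2, 1, 10)), list(rng.normal(0.3, 1, 10))]
        report = kruskal_steel([control] + treats, control_index=0)
        # MC of the equicorrelated (rho=0.5) max-|Z| reference
        mc_rng = np.random.default_rng(99)
        shared = mc_rng.normal(size=200_000)
        eps = mc_rng.normal(size=(200_000, 2))
        z = (shared[:, None] + eps) / math.sqrt(2.0)
        max_abs = np.abs(z).max(axis=1)
        for c in report.pairwise:
            mc_p = float((max_abs >= abs(c.statistic)).mean())
            assert c.p_adjusted == pytest.approx(mc_p, abs=0.01)

    def test_control_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            kruskal_steel([[1, 2], [3, 4], [5, 6]], control_index=5)


class TestTypeIError:
    """Attained size of each test near the nominal 5% under the null."""

    def test_fisher_balanced_binomial(self):
        rng = np.random.default_rng(12345)
        n, rejections = 500, 0
        for _ in range(2000):
            a, c = rng.binomial(n, 0.5), rng.binomial(n, 0.5)
            p = fisher_exact(ContingencyTable2x2(a, n - a, c, n - c)).p_value
            rejections += p < 0.05
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_mann_whitney_normal_null(self):
        rng = np.random.default_rng(12345)
        rejections = sum(
            mann_whitney_u(rng.normal(0, 1, 30), rng.normal(0, 1, 30)).p_value < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_kruskal_wallis_omnibus_null(self):
        rng = np.random.default_rng(12345)
        rejections = 0
        for _ in range(2000):
            groups = [rng.normal(0, 1, 30) for _ in range(3)]
            rejections += kruskal_steel_dwass(groups).p_value < 0.05
        assert 0.035 <= rejections / 2000 <= 0.065


def test_star_thresholds():
    assert stars(0.2) == "NS"
    assert stars(0.04) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
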