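"""Population tables, Wilcoxon pairing, proportion tests, summaries."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from imic.gating import POPULATIONS
from imic.populations import (
    paired_region_test,
    pairwise_proportion_tests,
    summarize,
    tabulate,
    two_proportion_z,
)


def classified_frame(rows):
    return pd.DataFrame(rows, columns=["region", "population"])


class TestTabulate:
    def test_single_population_stratum_is_100_percent(self):
        df = classified_frame([("epithelium", "triple_negative")] * 10)
        table = tabulate(df)
        pct = table.percentages("all", "epithelium")
        assert pct["triple_negative"] == 100.0
        assert pct.drop("triple_negative").fillna(0).eq(0).all()

    def test_percentages_sum_to_100_per_stratum(self):
        rng = np.random.default_rng(0)
        df = classified_frame(
            [
                (rng.choice(["epithelium", "lamina_propria"]), rng.choice(POPULATIONS))
                for _ in range(500)
            ]
        )
        table = tabulate(df)
        for region in ("epithelium", "lamina_propria"):
            assert table.percentages("all", region).sum() == pytest.approx(100.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [
            (rng.choice(["epithelium", "lamina_propria"]), rng.choice(POPULATIONS))
            for _ in range(200)
        ]
        a = tabulate(classified_frame(rows)).table
        b = tabulate(classified_frame(rows[::-1])).table
        pd.testing.assert_frame_equal(a, b)

    def test_region_none_reported_separately_and_counts_conserved(self):
        rows = [("epithelium", "triple_positive")] * 5 + [
            ("none", "triple_negative")
        ] * 3
        table = tabulate(classified_frame(rows))
        assert table.none_count == 3
        assert table.table["count"].sum() == 5

    def test_empty_stratum_percentage_is_missing(self):
        df = classified_frame([("epithelium", "triple_negative")])
        table = tabulate(df)
        assert np.isnan(table.percentages("all", "lamina_propria")).all()
        assert (table.counts("all", "lamina_propria") == 0).all()

    def test_group_stratification(self):
        rows = [
            {"region": "epithelium", "population": "triple_positive", "dx": "control"},
            {"region": "epithelium", "population": "triple_negative", "dx": "crs"},
        ]
        table = tabulate(pd.DataFrame(rows), group_col="dx")
        assert table.percentages("control", "epithelium")["triple_positive"] == 100.0
        assert table.percentages("crs", "epithelium")["triple_negative"] == 100.0


def wilcoxon_exact_enumeration(diffs):
    """Null distribution of W+ over all sign assignments, two-sided p as
    the doubled smaller tail (capped at 1)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_lo = (ws <= w_obs).mean()
    p_hi = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_lo, p_hi))


class TestPairedRegionTest:
    def test_all_tied_pairs_flagged_undefined(self):
        res = paired_region_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert "zero" in res.note

    def test_mirrored_pairs_give_identical_p(self):
        x = [1.0, 5.0, 2.0, 8.0, 3.0, 9.0]
        y = [2.0, 3.0, 4.0, 5.0, 7.0, 1.0]
        assert paired_region_test(x, y).p_value == pytest.approx(
            paired_region_test(y, x).p_value
        )

    def test_exact_p_matches_full_enumeration(self):
        # 9 informative pairs -> 2^9 sign assignments enumerated directly
        epi = [0.8, 0.3, 1.4, 0.9, 0.37, 0.25, 0.6, 1.1, 0.45]
        lp = [5.6, 3.1, 4.0, 2.2, 3.9, 5.5, 1.9, 0.7, 3.3]
        res = paired_region_test(epi, lp)
        expected = wilcoxon_exact_enumeration(np.subtract(epi, lp))
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_reference_strength_of_evidence(self):
        # 9 consistently one-sided pairs: the exact two-sided floor 2/2^9
        epi = list(range(1, 10))
        lp = [v + 1 for v in epi]
        assert paired_region_test(epi, lp).p_value == pytest.approx(2 / 512)

    def test_few_pairs_warns_in_note(self):
        res = paired_region_test([1.0, 2.0, 3.0], [4.0, 1.0, 5.0])
        assert "non-zero pairs" in res.note


class TestProportionTests:
    def test_equal_proportions_give_z0_p1(self):
        z, p = two_proportion_z(30, 100, 30, 100)
        assert z == 0.0 and p == 1.0

    def test_closed_form_oracle(self):
        # 80/100 vs 20/100: pooled p=0.5, se=sqrt(0.5*0.5*0.02)
        z, p = two_proportion_z(80, 100, 20, 100)
        se = np.sqrt(0.5 * 0.5 * (1 / 100 + 1 / 100))
        z_expected = (0.8 - 0.2) / se
        from scipy.stats import norm

        assert z == pytest.approx(z_expected)
        assert p == pytest.approx(2 * norm.sf(abs(z_expected)))

    def test_three_groups_make_three_tests_with_m3(self):
        res = pairwise_proportion_tests(
            {"A": 50, "B": 20, "C": 10}, {"A": 100, "B": 100, "C": 100}
        )
        assert len(res) == 3
        for r in res:
            assert r.adjustment == "bonferroni"
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_value))

    def test_larger_group_flagged_on_significant_pairs(self):
        res = pairwise_proportion_tests(
            {"A": 80, "B": 20}, {"A": 100, "B": 100}
        )
        assert res[0].larger == "A"

    def test_zero_denominator_skipped_with_note(self):
        res = pairwise_proportion_tests({"A": 5, "B": 0}, {"A": 10, "B": 0})
        assert len(res) == 1
        assert not res[0].defined
        assert "zero denominator" in res[0].note


class TestSummarize:
    def test_odd_sample_median(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        s = summarize([7.0])
        assert s.median == s.q1 == s.q3 == 7.0

    def test_linear_interpolation_oracle(self):
        vals = [2.0, 9.0, 4.0, 7.0, 1.0, 8.0, 3.0, 6.0, 5.0]
        s = summarize(vals)
        x = sorted(vals)

        def quantile(q):  # sorted-interpolation oracle, h = (n-1)q
            h = (len(x) - 1) * q
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        assert s.q1 == pytest.approx(quantile(0.25))
        assert s.median == pytest.approx(quantile(0.50))
        assert s.q3 == pytest.approx(quantile(0.75))
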