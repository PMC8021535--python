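"""Cell/background-ratio gate: ratios, sampling, CI, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imic.gating import (
    POPULATIONS,
    assign_population,
    cell_background_ratio,
    classify_cell,
    classify_cells,
    compute_thresholds,
    draw_threshold_sample,
    median_ratio_ci,
)


class TestRatio:
    def test_quotient_arithmetic(self):
        assert cell_background_ratio(144.0, 100.0, "quotient") == pytest.approx(1.44)

    def test_printed_difference_arithmetic(self):
        assert cell_background_ratio(200.0, 100.0, "printed_difference") == (
            pytest.approx(0.5)
        )

    def test_printed_difference_identity_case(self):
        assert cell_background_ratio(100.0, 100.0, "printed_difference") == 0.0

    def test_domain_violations(self):
        with pytest.raises(ValueError, match="b > 0"):
            cell_background_ratio(10.0, 0.0, "quotient")
        assert np.isnan(cell_background_ratio(0.0, 5.0, "printed_difference"))


class TestThresholdSample:
    def test_fraction_one_takes_all(self):
        assert draw_threshold_sample(50, 1.0).tolist() == list(range(50))

    def test_floor_convention(self):
        assert draw_threshold_sample(10_000, 0.30).size == 3000
        assert draw_threshold_sample(101, 0.30).size == 30

    def test_seed_reproducibility(self):
        a = draw_threshold_sample(1000, 0.3, seed=42)
        b = draw_threshold_sample(1000, 0.3, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, draw_threshold_sample(1000, 0.3, seed=43))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="below the minimum"):
            draw_threshold_sample(60, 0.3)


def brute_force_median_ci(values, level=0.95):
    """Independent order-statistic CI: enumerate the binomial CDF directly."""
    x = sorted(values)
    n = len(x)
    alpha = 1 - level
    cdf = 0.0
    j_best = -1
    for j in range(n):
        cdf += math.comb(n, j) * 0.5**n
        if cdf <= alpha / 2:
            j_best = j
        else:
            break
    j = max(j_best, 0)
    return x[j], x[n - 1 - j]


class TestMedianCI:
    def test_degenerate_sample(self):
        lo, hi = median_ratio_ci([3.0] * 25)
        assert (lo, hi) == (3.0, 3.0)

    def test_order_statistic_matches_enumeration(self):
        vals = list(range(1, 101))
        got = median_ratio_ci(vals, method="order_statistic")
        assert got == brute_force_median_ci(vals)

    @pytest.mark.parametrize("n", [20, 47, 100, 333])
    def test_order_statistic_matches_enumeration_sizes(self, n):
        rng = np.random.default_rng(n)
        vals = rng.lognormal(0, 0.5, size=n)
        assert median_ratio_ci(vals) == brute_force_median_ci(vals)

    def test_bootstrap_brackets_median_and_approaches_order_statistic(self):
        vals = np.arange(1, 101, dtype=float)
        lo, hi = median_ratio_ci(vals, method="bootstrap", n_boot=10_000, seed=0)
        assert lo < 50.5 < hi
        os_lo, os_hi = median_ratio_ci(vals, method="order_statistic")
        assert lo == pytest.approx(os_lo, abs=5.0)
        assert hi == pytest.approx(os_hi, abs=5.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=100, allow_nan=False),
            min_size=20,
            max_size=200,
        )
    )
    def test_bounds_are_order_statistics_bracketing_median(self, vals):
        lo, hi = median_ratio_ci(vals)
        assert lo in vals and hi in vals
        assert lo <= np.median(vals) <= hi


class TestClassify:
    def test_strict_exceedance(self):
        assert not classify_cell(1.5, 1.5)
        assert classify_cell(1.5 + 1e-12, 1.5)

    def test_population_bijection(self):
        labels = {
            assign_population(*(bool(int(b)) for b in f"{i:03b}")) for i in range(8)
        }
        assert labels == set(POPULATIONS)

    def test_reference_row_labels(self):
        assert assign_population(True, False, False) == "cytokeratin_single_positive"
        assert (
            assign_population(False, True, True)
            == "cd45cd18_vimentin_double_positive"
        )
        assert assign_population(False, False, False) == "triple_negative"


def random_cell_table(rng, n):
    """Synthetic cell table: lognormal positives over a background of 100."""
    df = pd.DataFrame({"cell_id": np.arange(1, n + 1)})
    for c in ("af488", "efluor570", "af594"):
        pos = rng.random(n) < 0.5
        m = np.where(
            pos,
            rng.lognormal(np.log(300), 0.3, n),
            rng.lognormal(np.log(100), 0.05, n),
        )
        df[f"mean_{c}"] = m
    df["flagged"] = False
    return df


BACKGROUND = {"af488": 100.0, "efluor570": 100.0, "af594": 100.0}


class TestGateInvariances:
    @pytest.mark.parametrize("seed", range(6))
    def test_quotient_and_printed_difference_agree(self, seed):
        # d = 1 - 1/r is strictly increasing, and the threshold is an order
        # statistic, so both definitions classify identically
        rng = np.random.default_rng(seed)
        cells = random_cell_table(rng, 400)
        out = {}
        for mode in ("quotient", "printed_difference"):
            th = compute_thresholds(
                cells, BACKGROUND, ratio_mode=mode, seed=seed
            )
            out[mode] = classify_cells(cells, BACKGROUND, th, mode)
        for c in BACKGROUND:
            np.testing.assert_array_equal(
                out["quotient"][f"positive_{c}"],
                out["printed_difference"][f"positive_{c}"],
            )
        assert (
            out["quotient"]["population"] == out["printed_difference"]["population"]
        ).all()

    @pytest.mark.parametrize("k", [0.25, 3.0, 117.0])
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(1)
        cells = random_cell_table(rng, 400)
        scaled = cells.copy()
        scaled["mean_af488"] = scaled["mean_af488"] * k
        bg2 = dict(BACKGROUND, af488=BACKGROUND["af488"] * k)
        th1 = compute_thresholds(cells, BACKGROUND, seed=1)
        th2 = compute_thresholds(scaled, bg2, seed=1)
        a = classify_cells(cells, BACKGROUND, th1)
        b = classify_cells(scaled, bg2, th2)
        assert (a["population"] == b["population"]).all()

    def test_flagged_cells_are_negative_and_excluded(self):
        rng = np.random.default_rng(2)
        cells = random_cell_table(rng, 200)
        cells.loc[:4, "flagged"] = True
        th = compute_thresholds(cells, BACKGROUND, seed=2)
        out = classify_cells(cells, BACKGROUND, th)
        assert (out.loc[:4, "population"] == "triple_negative").all()
        for c in BACKGROUND:
            assert not out.loc[:4, f"positive_{c}"].any()
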