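"""Population tables by region and diagnosis, and the comparison tests.

Classified cells are cross-tabulated into the 8 marker-combination
populations within each (diagnosis group, region) stratum; percentages use
the stratum's total cell count as denominator, so the 8 percentages of any
stratum sum to 100.  Cells that fall in no tissue region are reported
separately and excluded from the strata.

Comparisons mirror the reference analysis: a paired Wilcoxon signed-rank
test for per-patient epithelium-vs-LP metrics (exact for n <= 25), and
pairwise two-proportion z-tests across diagnosis groups within a population
row, Bonferroni-adjusted over the pairs of that row, flagging the
larger-proportion group of each significant pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gating import POPULATIONS
from .io import TISSUE_ROLES

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    adjustment: str = "none"
    p_adjusted: float | None = None
    groups: tuple[str, ...] = ()
    larger: str | None = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_value)


@dataclass
class PopulationTable:
    """Counts and percentages per (group, region, population) stratum.

    ``table`` has a (group, region, population) MultiIndex with ``count``
    and ``percentage`` columns; empty strata carry count 0 and a missing
    percentage.  ``none_count`` is the number of classified cells outside
    every tissue region (excluded from the strata).
    """

    table: pd.DataFrame
    none_count: int = 0

    def percentages(self, group: str, region: str) -> pd.Series:
        return self.table.loc[(group, region)]["percentage"]

    def counts(self, group: str, region: str) -> pd.Series:
        return self.table.loc[(group, region)]["count"]

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def tabulate(
    classified: pd.DataFrame,
    group_col: str | None = None,
    regions: Sequence[str] = TISSUE_ROLES,
) -> PopulationTable:
    """Cross-tabulate classified cells into the population table.

    ``classified`` needs ``region`` and ``population`` columns and, if
    ``group_col`` is given, a diagnosis-group column.  Counts partition the
    cells exactly; the result is invariant to row order and cell ids.
    """
    df = classified.copy()
    if group_col is None:
        df["_group"] = "all"
        group_col = "_group"
    none_mask = ~df["region"].isin(regions)
    none_count = int(none_mask.sum())
    df = df.loc[~none_mask]

    groups = sorted(df[group_col].unique()) if len(df) else []
    index = pd.MultiIndex.from_product(
        [groups, list(regions), list(POPULATIONS)],
        names=["group", "region", "population"],
    )
    counts = (
        df.groupby([group_col, "region", "population"], observed=False)
        .size()
        .reindex(index, fill_value=0)
    )
    table = counts.to_frame("count")
    totals = table.groupby(level=["group", "region"])["count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        table["percentage"] = np.where(
            totals > 0, 100.0 * table["count"] / totals.replace(0, np.nan), np.nan
        )
    if none_count:
        logger.info("%d cells outside all tissue regions (reported separately)", none_count)
    return PopulationTable(table=table, none_count=none_count)


def paired_region_test(
    epithelium: Sequence[float], lamina_propria: Sequence[float]
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-patient metrics.

    Exact null distribution for n <= 25 pairs, normal approximation beyond.
    Zero differences are discarded (Wilcoxon's convention); if every
    difference is zero the test is undefined and flagged as such.  Fewer
    than 5 informative pairs triggers a warning note (exact p still
    reported).
    """
    x = np.asarray(epithelium, dtype=float)
    y = np.asarray(lamina_propria, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return ComparisonResult(
            test="wilcoxon_signed_rank",
            statistic=float("nan"),
            p_value=float("nan"),
            note="all paired differences are zero; test undefined",
        )
    note = ""
    if nz.size < 5:
        note = f"only {nz.size} non-zero pairs; exact small-sample p-value"
        logger.warning("paired test on %d informative pairs only", nz.size)
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return ComparisonResult(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        note=note,
    )


def two_proportion_z(
    pos1: int, n1: int, pos2: int, n2: int
) -> tuple[float, float]:
    """Two-sided pooled two-proportion z-test; returns (z, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("zero denominator")
    p1, p2 = pos1 / n1, pos2 / n2
    pooled = (pos1 + pos2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def pairwise_proportion_tests(
    positives: Mapping[str, int],
    totals: Mapping[str, int],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """All pairwise two-proportion z-tests within one population row.

    Bonferroni adjustment uses m = number of pairs tested in the row
    (p_adj = min(1, m*p)).  For each pair significant after adjustment,
    ``larger`` names the group with the larger proportion.  Pairs with a
    zero denominator are skipped with a note.
    """
    groups = sorted(positives)
    pairs = list(combinations(groups, 2))
    testable = [
        (a, b) for a, b in pairs if totals.get(a, 0) > 0 and totals.get(b, 0) > 0
    ]
    m = len(testable)
    results = []
    for a, b in pairs:
        if (a, b) not in testable:
            results.append(
                ComparisonResult(
                    test="two_proportion_z",
                    statistic=float("nan"),
                    p_value=float("nan"),
                    adjustment="bonferroni",
                    groups=(a, b),
                    note="skipped: zero denominator",
                )
            )
            continue
        z, p = two_proportion_z(positives[a], totals[a], positives[b], totals[b])
        p_adj = min(1.0, m * p)
        larger = None
        if p_adj < alpha:
            larger = a if positives[a] / totals[a] > positives[b] / totals[b] else b
        results.append(
            ComparisonResult(
                test="two_proportion_z",
                statistic=z,
                p_value=p,
                adjustment="bonferroni",
                p_adjusted=p_adj,
                groups=(a, b),
                larger=larger,
            )
        )
    return results


@dataclass
class Summary:
    median: float
    q1: float
    q3: float


def summarize(values: Sequence[float]) -> Summary:
    """Median and quartiles with linear interpolation between order stats."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize needs a non-empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return Summary(median=float(med), q1=float(q1), q3=float(q3))
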