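"""Positive/negative gating by the cell/background ratio.

For every cell and marker channel, the cell's mean intensity m is compared
with the sample's background median b through a ratio statistic.  Two
definitions are supported:

* ``quotient`` — r = m / b (default).  The realized channel thresholds of
  the reference workflow (1.44, 2.01, 1.18) all exceed 1, which is only
  possible under this form.
* ``printed_difference`` — d = (m - b) / m = 1 - b / m, the relative
  difference form.

Since d = 1 - 1/r is a strictly increasing map for m, b > 0, and the
threshold is a sample quantile (an order statistic), classification is
identical under either definition.

The threshold τ per channel is the upper bound of the 95% confidence
interval of the median ratio, estimated on a 30% simple random sample of
all cells (pooled across samples), by a distribution-free order-statistic
interval (default) or a percentile bootstrap.  A cell is positive iff its
ratio strictly exceeds τ.  The three per-channel booleans map onto the 8
marker-combination populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MARKER_CHANNELS
from .phantom import POPULATION_NAMES

logger = logging.getLogger(__name__)

RatioMode = Literal["quotient", "printed_difference"]
CiMethod = Literal["order_statistic", "bootstrap"]

#: Table-style display order of the 8 populations.
POPULATIONS = (
    "cytokeratin_single_positive",
    "vimentin_single_positive",
    "cd45cd18_single_positive",
    "cd45cd18_vimentin_double_positive",
    "cytokeratin_vimentin_double_positive",
    "cytokeratin_cd45cd18_double_positive",
    "triple_positive",
    "triple_negative",
)

MIN_SAMPLE = 20


@dataclass
class ChannelThreshold:
    """Positivity cutoff for one channel: τ = upper 95% CI bound of the
    median cell/background ratio, plus provenance."""

    channel: str
    tau: float
    ci_lower: float
    ci_upper: float
    n_sample: int
    ci_method: str
    ratio_mode: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau):
            raise ValueError(f"threshold for {self.channel} is not finite")


def cell_background_ratio(
    m: float | np.ndarray, b: float, mode: RatioMode = "quotient"
) -> np.ndarray:
    """Cell/background ratio(s); NaN where the definition's domain fails.

    quotient: m / b (requires b > 0, enforced).  printed_difference:
    1 - b / m (cells with m <= 0 yield NaN and are flagged downstream).
    """
    m = np.asarray(m, dtype=float)
    if mode == "quotient":
        if not b > 0:
            raise ValueError("quotient ratio requires background b > 0")
        return m / b
    if mode == "printed_difference":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = 1.0 - b / m
        return np.where(m > 0, r, np.nan)
    raise ValueError(f"unknown ratio mode {mode!r}")


def draw_threshold_sample(
    n_cells: int, fraction: float = 0.30, seed: int | None = 0
) -> np.ndarray:
    """Indices of a simple random sample of floor(n * fraction) cells.

    Sampling is without replacement and reproducible under ``seed``; the
    returned indices are sorted so downstream behaviour is independent of
    draw order.  Fewer than 20 sampled cells is an error (the CI would be
    unreliable).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(math.floor(n_cells * fraction))
    if k < MIN_SAMPLE:
        raise ValueError(
            f"threshold sample of {k} cells (n={n_cells}, fraction={fraction}) "
            f"is below the minimum of {MIN_SAMPLE}"
        )
    if k == n_cells:
        return np.arange(n_cells)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_cells, size=k, replace=False)
    return np.sort(idx)


def median_ratio_ci(
    ratios: Sequence[float] | np.ndarray,
    level: float = 0.95,
    method: CiMethod = "order_statistic",
    n_boot: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Confidence interval for the median of ``ratios``.

    order_statistic: the distribution-free binomial interval — with sorted
    values x(1) <= ... <= x(n), the bounds are x(l) and x(n-l+1) where l is
    the largest rank with Binom(n, 1/2).cdf(l-1) <= (1-level)/2, so coverage
    is at least ``level`` with no distributional assumption.

    bootstrap: percentile interval of the sample median over ``n_boot``
    seeded resamples.

    A degenerate sample (all values equal) gives a zero-width interval.
    """
    x = np.sort(np.asarray(ratios, dtype=float))
    n = x.size
    if n < MIN_SAMPLE:
        raise ValueError(f"need at least {MIN_SAMPLE} ratios, got {n}")
    alpha = 1.0 - level
    if method == "order_statistic":
        # largest j with P(X <= j) <= alpha/2 for X ~ Binom(n, 1/2); the
        # lower bound is then x(j+1) and the upper x(n-j), giving coverage
        # 1 - 2*cdf(j) >= level.  ppf returns the smallest k with
        # cdf(k) >= alpha/2, so j is k or k-1.
        k = int(stats.binom.ppf(alpha / 2, n, 0.5))
        j = k if stats.binom.cdf(k, n, 0.5) <= alpha / 2 else k - 1
        j = max(j, 0)
        return float(x[j]), float(x[n - 1 - j])
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        meds = np.median(
            x[rng.integers(0, n, size=(n_boot, n))], axis=1
        )
        lo, hi = np.percentile(meds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def classify_cell(ratio: float, tau: float) -> bool:
    """Positive iff the ratio strictly exceeds the threshold."""
    return bool(ratio > tau)


def assign_population(ck: bool, vim: bool, cd: bool) -> str:
    """Map the (cytokeratin, vimentin, cd45cd18) triple to its population."""
    return POPULATION_NAMES[(bool(ck), bool(vim), bool(cd))]


def compute_thresholds(
    cells: pd.DataFrame,
    background: Mapping[str, float],
    ratio_mode: RatioMode = "quotient",
    fraction: float = 0.30,
    seed: int | None = 0,
    ci_method: CiMethod = "order_statistic",
    level: float = 0.95,
    n_boot: int = 2000,
) -> dict[str, ChannelThreshold]:
    """Per-channel thresholds from a 30% random sample of eligible cells.

    One sample of cells is drawn (the same subset serves every channel, as
    the reference procedure samples cells, not per-channel measurements).
    Cells flagged upstream, or outside the ratio definition's domain in a
    channel, are excluded from that channel's CI.
    """
    eligible = (
        ~cells["flagged"].to_numpy()
        if "flagged" in cells.columns
        else np.ones(len(cells), dtype=bool)
    )
    cells_ok = cells.loc[eligible].reset_index(drop=True)
    idx = draw_threshold_sample(len(cells_ok), fraction=fraction, seed=seed)
    sample = cells_ok.iloc[idx]
    thresholds: dict[str, ChannelThreshold] = {}
    for c in MARKER_CHANNELS:
        b = float(background[c])
        r = cell_background_ratio(sample[f"mean_{c}"].to_numpy(), b, ratio_mode)
        r = r[np.isfinite(r)]
        lo, hi = median_ratio_ci(
            r, level=level, method=ci_method, n_boot=n_boot, seed=seed
        )
        thresholds[c] = ChannelThreshold(
            channel=c,
            tau=hi,
            ci_lower=lo,
            ci_upper=hi,
            n_sample=int(r.size),
            ci_method=ci_method,
            ratio_mode=ratio_mode,
        )
        logger.info(
            "threshold %s: tau=%.4f (CI %.4f-%.4f, n=%d, %s, %s)",
            c,
            hi,
            lo,
            hi,
            r.size,
            ci_method,
            ratio_mode,
        )
    return thresholds


def classify_cells(
    cells: pd.DataFrame,
    background: Mapping[str, float],
    thresholds: Mapping[str, ChannelThreshold],
    ratio_mode: RatioMode = "quotient",
) -> pd.DataFrame:
    """Classified-cell table: ratios, per-channel booleans, population label.

    Flagged cells and cells with a domain-invalid ratio are negative in the
    affected channels; the count of such cells is logged.
    """
    out = cells.copy()
    flagged = (
        out["flagged"].to_numpy()
        if "flagged" in out.columns
        else np.zeros(len(out), dtype=bool)
    )
    n_domain = 0
    positives = {}
    for c in MARKER_CHANNELS:
        b = float(background[c])
        r = cell_background_ratio(out[f"mean_{c}"].to_numpy(), b, ratio_mode)
        invalid = ~np.isfinite(r)
        n_domain += int((invalid & ~flagged).sum())
        tau = thresholds[c].tau
        pos = np.where(invalid | flagged, False, r > tau)
        out[f"ratio_{c}"] = r
        out[f"positive_{c}"] = pos
        positives[c] = pos
    if n_domain:
        logger.warning(
            "%d cell-channel ratio(s) outside the definition domain were "
            "classified negative",
            n_domain,
        )
    out["population"] = [
        assign_population(ck, vim, cd)
        for ck, vim, cd in zip(
            positives["af488"], positives["efluor570"], positives["af594"]
        )
    ]
    return out
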