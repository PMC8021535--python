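"""Negative-control and channel-spillover quality checks.

Two controls guard the positivity gate:

* Isotype ROC — per channel, the per-cell mean intensities of the tissue
  run are compared against those of the isotype-control run with a ROC
  analysis.  The AUC is computed through the rank-sum (Mann-Whitney)
  construction with mid-ranked ties, tissue as the positive class, together
  with the Mann-Whitney p-value.  AUC 0.5 means the stain adds nothing over
  the control.
* Spillover — each single-stained slide is pushed through the full pipeline
  with the thresholds of the corresponding multiplexed run, and the
  fraction of cells called positive in the two off-target channels is
  reported per source -> target pair (6 pairs for 3 channels), with a
  configurable pass bound defaulting to 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import MARKER_CHANNELS

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """AUC of tissue vs isotype intensities in one channel."""

    channel: str
    auc: float
    p_value: float
    n_tissue: int
    n_isotype: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def isotype_roc(
    tissue: np.ndarray, isotype: np.ndarray, channel: str = ""
) -> RocResult:
    """ROC comparison of tissue vs isotype-control cell intensities.

    AUC = U / (n1 * n2) from the Mann-Whitney U statistic of the tissue
    arm, which equals the probability that a random tissue cell outshines a
    random control cell (ties counted half).  Invariant under any strictly
    increasing intensity transform.
    """
    t = np.asarray(tissue, dtype=float)
    i = np.asarray(isotype, dtype=float)
    if t.size == 0 or i.size == 0:
        raise ValueError("ROC needs non-empty samples in both arms")
    res = stats.mannwhitneyu(t, i, alternative="two-sided")
    auc = float(res.statistic) / (t.size * i.size)
    return RocResult(
        channel=channel,
        auc=auc,
        p_value=float(res.pvalue),
        n_tissue=int(t.size),
        n_isotype=int(i.size),
    )


def roc_points(tissue: np.ndarray, isotype: np.ndarray) -> pd.DataFrame:
    """ROC curve coordinates (fpr, tpr, threshold) for plain-text export."""
    from sklearn.metrics import roc_curve

    t = np.asarray(tissue, dtype=float)
    i = np.asarray(isotype, dtype=float)
    y = np.concatenate([np.ones(t.size), np.zeros(i.size)])
    fpr, tpr, thr = roc_curve(y, np.concatenate([t, i]))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class SpilloverReport:
    """Off-target positivity per source -> target channel pair.

    ``fractions`` is a source x target DataFrame of positive-cell fractions
    (diagonal is NaN); ``bound`` the pass criterion; ``passed`` whether all
    6 off-target fractions stayed below it.
    """

    fractions: pd.DataFrame
    bound: float
    passed: bool

    def off_target(self) -> pd.Series:
        s = self.fractions.stack()
        return s[
            s.index.get_level_values(0) != s.index.get_level_values(1)
        ]


def spillover_estimate(
    classified_by_source: Mapping[str, pd.DataFrame],
    bound: float = 0.01,
) -> SpilloverReport:
    """Off-target positive fractions from single-stain pipeline runs.

    ``classified_by_source`` maps each stained source channel to the
    classified-cell table of its single-stain run (gated with the
    multiplexed run's thresholds).  The fraction for (source, target) is
    positives in the target channel over all classified cells of that run.
    """
    mat = pd.DataFrame(
        np.nan, index=list(MARKER_CHANNELS), columns=list(MARKER_CHANNELS)
    )
    mat.index.name = "source"
    mat.columns.name = "target"
    for source, table in classified_by_source.items():
        if source not in MARKER_CHANNELS:
            raise ValueError(f"unknown source channel {source!r}")
        n = len(table)
        if n == 0:
            raise ValueError(f"no classified cells in the {source} single-stain run")
        for target in MARKER_CHANNELS:
            if target == source:
                continue
            frac = float(table[f"positive_{target}"].sum()) / n
            mat.loc[source, target] = frac
    off = mat.stack()
    off = off[off.index.get_level_values(0) != off.index.get_level_values(1)]
    passed = bool((off < bound).all())
    if not passed:
        logger.warning(
            "spillover above the %.2f%% bound: %s",
            100 * bound,
            off[off >= bound].to_dict(),
        )
    return SpilloverReport(fractions=mat, bound=bound, passed=passed)
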