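"""Per-cell mean intensities and the background statistic.

Each gated nucleus yields one cell record with, per marker channel, the
arithmetic mean of the raw pixel values over that channel's grown cell mask
and the mask area.  The background statistic is the per-channel median of
the background-event intensities.  Both feed the cell/background-ratio
classifier, which is scale invariant, so no intensity normalization is
applied by default; an optional per-channel affine rescale is provided for
users who need to match an external calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import MARKER_CHANNELS, ROLE_NONE, ImageStack, RegionSet, assign_region

logger = logging.getLogger(__name__)


@dataclass
class BackgroundEstimate:
    """Per-channel median background intensity and the event count behind it."""

    median: dict[str, float]
    n_events: dict[str, int]

    def __post_init__(self) -> None:
        for c, b in self.median.items():
            if b < 0:
                raise ValueError(f"background median for {c} is negative")
        for c, n in self.n_events.items():
            if n <= 0:
                raise ValueError(f"no background events for {c}")


def estimate_background(events: Mapping[str, np.ndarray]) -> BackgroundEstimate:
    """Median intensity of the background events, per channel."""
    median = {}
    counts = {}
    for c, v in events.items():
        v = np.asarray(v)
        if v.size == 0:
            raise ValueError(f"empty background event sample for channel {c}")
        median[c] = float(np.median(v))
        counts[c] = int(v.size)
    return BackgroundEstimate(median=median, n_events=counts)


def channel_means(
    raster: np.ndarray, mask: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean raster value and pixel count per mask label.

    Returns (means, counts) aligned with ``labels``; means are NaN where a
    label has no mask pixels.  bincount-based, so no full-frame float copy
    of the raster is made.
    """
    flat = mask.ravel()
    max_label = int(labels.max()) if labels.size else 0
    counts_all = np.bincount(flat, minlength=max_label + 1)
    sums_all = np.bincount(
        flat, weights=raster.ravel().astype(np.float64, copy=False),
        minlength=max_label + 1,
    )
    counts = counts_all[labels]
    sums = sums_all[labels]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def quantify_cells(
    stack: ImageStack,
    nucleus_table: pd.DataFrame,
    masks: Mapping[str, np.ndarray],
    regions: RegionSet | None = None,
    normalization: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One row per gated nucleus with per-channel mask means and areas.

    Columns: ``cell_id`` (the nucleus label), ``region``,
    ``nucleus_area_um2``, centroid, and per marker channel ``mean_<ch>`` and
    ``mask_area_um2_<ch>``.  Cells whose mask is empty in any channel are
    flagged (``flagged`` = True) and later excluded from threshold
    estimation and classified negative; their count is logged.

    ``normalization`` maps channel -> (scale, offset) applied affinely to
    the mean intensities; the default is the identity (no-op), because the
    downstream ratio statistic is scale invariant.
    """
    labels = nucleus_table["label"].to_numpy()
    out = pd.DataFrame({"cell_id": labels})
    out["nucleus_area_um2"] = nucleus_table["area_um2"].to_numpy()
    out["centroid_row"] = nucleus_table["centroid_row"].to_numpy()
    out["centroid_col"] = nucleus_table["centroid_col"].to_numpy()

    if regions is not None and regions.has_tissue:
        xy = np.column_stack([out["centroid_col"], out["centroid_row"]])
        out["region"] = assign_region(xy, regions)
    else:
        out["region"] = ROLE_NONE

    px_area = stack.pixel_area_um2
    flagged = np.zeros(len(labels), dtype=bool)
    for c in MARKER_CHANNELS:
        means, counts = channel_means(stack.channel(c), masks[c], labels)
        if normalization and c in normalization:
            scale, offset = normalization[c]
            means = scale * means + offset
        out[f"mean_{c}"] = means
        out[f"mask_area_um2_{c}"] = counts * px_area
        flagged |= counts == 0
    out["flagged"] = flagged
    n_flagged = int(flagged.sum())
    if n_flagged:
        logger.warning(
            "%d cell(s) with an empty mask in at least one channel were "
            "flagged and will not enter classification",
            n_flagged,
        )
    return out
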