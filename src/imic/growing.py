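"""Per-channel cell masks grown outward and inward from the nuclear margin.

Because a 5 µm section places cytoplasmic immunostaining both around and on
top of the nucleus, each cell mask is allowed to grow in both directions
from the nuclear border.  Growth proceeds in rings of ``step_width_um``:

* outward — a ring is accepted while its median intensity has not dropped
  by at least ``step_drop_fraction`` relative to the previously accepted
  ring (the "sudden step" criterion) and the ring count stays within the
  per-channel ``max_growing_steps`` limit.  Fractional step counts mean
  fractional physical reach: the final ring is cut at
  ``max_growing_steps * step_width_um``.
* inward — from the margin toward the nucleus centre under the same sudden-
  step rule, until the centre is reached; the margin ring itself is always
  part of the mask.

Pixels contested by several nuclei go to the nearest nucleus (Euclidean
distance to the nuclear margin), which makes per-channel masks of different
cells disjoint by construction.

The deeper default limit for eFluor 570 (4.0 steps vs 2.0 for AF488/AF594)
reflects the elongated shape of vimentin-positive connective-tissue cells,
whose immunoreactivity often starts away from the nuclear membrane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .io import MARKER_CHANNELS, ImageStack

logger = logging.getLogger(__name__)

DEFAULT_MAX_STEPS = {"af488": 2.0, "efluor570": 4.0, "af594": 2.0}


@dataclass
class GrowingParams:
    """Ring width, per-channel growing limits and the sudden-step threshold.

    ``step_width_um`` is the thickness of one growing step (the physical
    width of one ring).  ``max_growing_steps`` caps outward growth per
    channel; fractional values are honoured as fractional reach.
    ``step_drop_fraction`` is the relative drop between consecutive ring
    medians that counts as a sudden intensity step (0.5 = halving).
    """

    step_width_um: float = 0.5
    max_growing_steps: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_STEPS)
    )
    step_drop_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.step_width_um <= 0:
            raise ValueError("step_width_um must be positive")
        if any(v < 0 for v in self.max_growing_steps.values()):
            raise ValueError("max_growing_steps must be >= 0")
        if not 0 < self.step_drop_fraction < 1:
            raise ValueError("step_drop_fraction must lie in (0, 1)")


def fractional_step_reach(max_growing_steps: float, step_width_um: float) -> float:
    """Outward reach in µm: ``max_growing_steps * step_width_um``.

    Fractional step counts (e.g. the 4.0 vs 2.0 channel settings, or 2.5)
    are realized by distance-thresholding the final ring, so 2.5 steps of
    0.5 µm reach 1.25 µm with a half-width last ring.
    """
    if max_growing_steps < 0 or step_width_um <= 0:
        raise ValueError("invalid growing parameters")
    return max_growing_steps * step_width_um


class _GrowGeometry:
    """Distance geometry shared by all channels of one label map.

    Precomputes, once per (gated) label map: the Euclidean distance of every
    outside pixel to the nearest nucleus and which nucleus that is, the
    inward distance from the margin for nucleus pixels, and the ring indices
    implied by the step width.
    """

    def __init__(
        self, labelmap: np.ndarray, pixel_size_um: float, step_width_um: float
    ) -> None:
        self.labelmap = labelmap
        self.pixel_size_um = pixel_size_um
        self.step_width_um = step_width_um
        self.max_label = int(labelmap.max())

        inside = labelmap > 0
        dist_out, inds = ndi.distance_transform_edt(
            ~inside, sampling=pixel_size_um, return_indices=True
        )
        self.owner = labelmap[inds[0], inds[1]].astype(np.int32, copy=False)
        self.owner[inside] = 0
        del inds
        self.dist_out = dist_out.astype(np.float32)
        del dist_out
        dist_in = ndi.distance_transform_edt(inside, sampling=pixel_size_um)
        # ring index: ring k covers distances ((k-1)w, kw]
        w = step_width_um
        self.ring_in = np.ceil(dist_in / w).astype(np.int16)
        del dist_in
        self.ring_out = np.ceil(self.dist_out / np.float32(w)).astype(np.int16)
        self.inside = inside


def _ring_medians(
    labels: np.ndarray, rings: np.ndarray, values: np.ndarray
) -> pd.DataFrame:
    """Median value per (label, ring), as a label x ring wide table."""
    df = pd.DataFrame({"label": labels, "ring": rings, "val": values})
    med = df.groupby(["label", "ring"], sort=True)["val"].median()
    return med.unstack()


def _accepted_counts(
    meds: pd.DataFrame,
    baseline: pd.Series,
    drop_fraction: float,
    max_rings: int,
) -> pd.Series:
    """Number of consecutive accepted rings per label.

    Ring k is accepted if rings 1..k-1 were, the ring is non-empty, and the
    median has not dropped by >= drop_fraction relative to the previous
    accepted ring (ring 0 = baseline).  Vectorized over labels.
    """
    idx = meds.index
    accepted = pd.Series(0, index=idx, dtype=int)
    stopped = pd.Series(False, index=idx)
    prev = baseline.reindex(idx)
    for k in range(1, max_rings + 1):
        med_k = meds[k] if k in meds.columns else pd.Series(np.nan, index=idx)
        empty = med_k.isna()
        with np.errstate(invalid="ignore", divide="ignore"):
            drop = (prev - med_k) / prev
        sudden = (prev > 0) & (drop >= drop_fraction)
        stopped |= empty | sudden
        take = ~stopped
        accepted[take] = k
        prev = med_k.where(take, prev)
    return accepted


def grow_cell_masks(
    labelmap: np.ndarray,
    raster: np.ndarray,
    pixel_size_um: float,
    max_growing_steps: float,
    params: GrowingParams | None = None,
    geometry: _GrowGeometry | None = None,
) -> np.ndarray:
    """Grow per-cell masks on one channel raster; returns a label image.

    Mask labels equal the nucleus labels of ``labelmap``.  Masks of
    different cells are disjoint (contested pixels go to the nearer
    nucleus); each mask contains its nuclear margin ring.
    """
    params = params or GrowingParams()
    if raster.shape != labelmap.shape:
        raise ValueError("raster and labelmap shapes differ")
    if labelmap.max() == 0:
        return np.zeros_like(labelmap, dtype=np.int32)
    geom = geometry or _GrowGeometry(labelmap, pixel_size_um, params.step_width_um)

    w = params.step_width_um
    reach = fractional_step_reach(max_growing_steps, w)
    n_out_rings = int(np.ceil(max_growing_steps)) if reach > 0 else 0

    vals = raster.astype(np.float32, copy=False)

    # interior rings (ring 1 = margin ring)
    in_sel = geom.inside
    in_labels = geom.labelmap[in_sel]
    in_rings = geom.ring_in[in_sel]
    meds_in = _ring_medians(in_labels, in_rings, vals[in_sel])
    if 1 not in meds_in.columns:
        warnings.warn("labels without a margin ring encountered; skipped")
    baseline = meds_in[1] if 1 in meds_in.columns else pd.Series(dtype=float)
    max_in_ring = int(meds_in.columns.max())
    # margin ring is unconditionally part of the mask; the stopping rule
    # applies from ring 2 inward, with ring 1 as baseline
    inner = meds_in.drop(columns=[1]).rename(columns=lambda k: k - 1)
    acc_inner = _accepted_counts(
        inner, baseline, params.step_drop_fraction, max_in_ring - 1
    )
    acc_in = acc_inner + 1  # rings 1..acc_in included

    # outward rings
    if n_out_rings > 0:
        out_sel = (geom.owner > 0) & (geom.dist_out <= reach)
        out_labels = geom.owner[out_sel]
        out_rings = geom.ring_out[out_sel]
        meds_out = _ring_medians(out_labels, out_rings, vals[out_sel])
        acc_out = _accepted_counts(
            meds_out, baseline, params.step_drop_fraction, n_out_rings
        )
    else:
        acc_out = pd.Series(0, index=baseline.index, dtype=int)

    lut_in = np.zeros(geom.max_label + 1, dtype=np.int16)
    lut_in[acc_in.index.astype(int)] = acc_in.to_numpy(dtype=np.int16)
    lut_out = np.zeros(geom.max_label + 1, dtype=np.int16)
    lut_out[acc_out.index.astype(int)] = acc_out.to_numpy(dtype=np.int16)

    out = np.zeros_like(labelmap, dtype=np.int32)
    keep_in = in_sel & (geom.ring_in <= lut_in[geom.labelmap])
    out[keep_in] = geom.labelmap[keep_in]
    if n_out_rings > 0:
        keep_out = (
            (geom.owner > 0)
            & (geom.dist_out <= reach)
            & (geom.ring_out <= lut_out[geom.owner])
        )
        out[keep_out] = geom.owner[keep_out]
    return out


def grow_all_channels(
    labelmap: np.ndarray,
    stack: ImageStack,
    params: GrowingParams | None = None,
) -> dict[str, np.ndarray]:
    """Grow masks for every marker channel, sharing the distance geometry."""
    params = params or GrowingParams()
    if labelmap.max() == 0:
        return {c: np.zeros_like(labelmap, dtype=np.int32) for c in MARKER_CHANNELS}
    geom = _GrowGeometry(labelmap, stack.pixel_size_um, params.step_width_um)
    masks = {}
    for c in MARKER_CHANNELS:
        steps = params.max_growing_steps.get(c, 0.0)
        masks[c] = grow_cell_masks(
            labelmap,
            stack.channel(c),
            stack.pixel_size_um,
            steps,
            params,
            geometry=geom,
        )
        logger.info(
            "grew %s masks: %.1f steps x %.2f um",
            c,
            steps,
            params.step_width_um,
        )
    return masks
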