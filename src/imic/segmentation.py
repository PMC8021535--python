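"""Nuclear segmentation in the DAPI master channel.

Nuclei are found by smoothing, intensity thresholding and connected-component
labeling; components large enough to be nucleus conglomerates are split by a
distance-transform watershed whose seeds must be at least
``min_split_distance_um`` apart.  The *remove labels* gate then discards
segmented nuclei whose area falls outside a closed interval — by default
40–100 µm², which rejects fragments (marginally cut nuclei) below and
conglomerates above, keeping only biologically plausible nuclei.

The nucleus-free complement of the pre-gate label map, restricted to the
analyzed tissue, provides the background "events" (individual pixels by
default) from which the per-channel background intensity is estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

from .io import CHANNELS, ImageStack, RegionSet, rasterize_roles

logger = logging.getLogger(__name__)


class EmptyBackgroundError(ValueError):
    """Nuclei cover the whole analyzed area; background is unestimable."""


@dataclass
class SegmentationParams:
    """Knobs of the smoothing + threshold + watershed nucleus detector.

    ``intensity_threshold_method`` is ``"otsu"`` (default) or ``"fixed"``
    (uses ``fixed_threshold``).  ``smoothing_sigma_um`` is the Gaussian
    pre-smoothing scale; ``min_split_distance_um`` the minimum seed spacing
    for the conglomerate-splitting watershed.  ``area_min_um2`` /
    ``area_max_um2`` are the closed-interval bounds of the remove-labels
    gate (defaults 40 and 100 µm²).
    """

    intensity_threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    smoothing_sigma_um: float = 0.4
    min_split_distance_um: float = 4.0
    area_min_um2: float = 40.0
    area_max_um2: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.area_min_um2 < self.area_max_um2:
            raise ValueError("need 0 < area_min_um2 < area_max_um2")
        if self.intensity_threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")


def segment_nuclei(
    dapi: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 0.25378,
) -> np.ndarray:
    """Label individual nuclei in a single-channel DAPI raster.

    Returns an int32 label map (0 = background).  Touching nuclei whose
    merged component is larger than the gate's upper bound are split by a
    watershed on the distance transform, seeded at local maxima at least
    ``min_split_distance_um`` apart.  Deterministic for fixed input; a blank
    image yields an empty label map.
    """
    params = params or SegmentationParams()
    if dapi.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel 2-D raster")
    img = ndi.gaussian_filter(
        dapi.astype(np.float32), sigma=params.smoothing_sigma_um / pixel_size_um
    )
    if img.max() == img.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    if params.intensity_threshold_method == "otsu":
        thr = float(threshold_otsu(img))
    else:
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    mask = img > thr
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    labels = labels.astype(np.int32)
    if n == 0:
        return labels

    # split only components big enough to be conglomerates
    px_area = pixel_size_um**2
    min_dist_px = max(1, int(round(params.min_split_distance_um / pixel_size_um)))
    areas = ndi.sum_labels(np.ones_like(labels, bool), labels, np.arange(1, n + 1))
    big = np.flatnonzero(areas * px_area > params.area_max_um2) + 1
    if big.size:
        objects = ndi.find_objects(labels)
        next_label = n + 1
        for lab in big:
            sl = objects[lab - 1]
            comp = labels[sl] == lab
            dist = ndi.distance_transform_edt(comp)
            peaks = peak_local_max(
                dist, min_distance=min_dist_px, labels=comp, exclude_border=False
            )
            if len(peaks) <= 1:
                continue
            markers = np.zeros(comp.shape, dtype=np.int32)
            for i, (r, c) in enumerate(peaks):
                markers[r, c] = i + 1
            parts = watershed(-dist, markers=markers, mask=comp)
            sub = labels[sl]
            for i in range(1, len(peaks) + 1):
                sub[parts == i] = next_label
                next_label += 1

    # compact labels to 1..K; remap the (possibly sparse) post-split ids
    # directly so watershed cuts survive
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[uniq] = np.arange(1, uniq.size + 1, dtype=np.int32)
    out = lut[labels]
    logger.info("segmented %d nuclei", uniq.size)
    return out


def nucleus_records(labelmap: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Per-nucleus table: label, area_um2, centroid (px) and bounding box."""
    if labelmap.max() == 0:
        return pd.DataFrame(
            columns=[
                "label",
                "area_um2",
                "centroid_row",
                "centroid_col",
                "bbox_min_row",
                "bbox_min_col",
                "bbox_max_row",
                "bbox_max_col",
            ]
        )
    props = regionprops_table(
        labelmap, properties=("label", "area", "centroid", "bbox")
    )
    df = pd.DataFrame(props)
    df = df.rename(
        columns={
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
            "bbox-0": "bbox_min_row",
            "bbox-1": "bbox_min_col",
            "bbox-2": "bbox_max_row",
            "bbox-3": "bbox_max_col",
        }
    )
    df["area_um2"] = df.pop("area") * pixel_size_um**2
    return df[
        [
            "label",
            "area_um2",
            "centroid_row",
            "centroid_col",
            "bbox_min_row",
            "bbox_min_col",
            "bbox_max_row",
            "bbox_max_col",
        ]
    ]


def remove_labels(
    labelmap: np.ndarray,
    pixel_size_um: float,
    area_min_um2: float = 40.0,
    area_max_um2: float = 100.0,
) -> np.ndarray:
    """Delete labels whose area lies outside the closed interval
    [area_min_um2, area_max_um2]; surviving labels keep their ids.

    The endpoints are retained ("smaller than 40 µm² and larger than
    100 µm²" are excluded, so the interval is closed).  The removed count is
    logged.  A gate of (0, inf) is the identity.
    """
    if labelmap.max() == 0:
        return labelmap.copy()
    labels = np.unique(labelmap)
    labels = labels[labels > 0]
    areas_px = ndi.sum_labels(np.ones_like(labelmap, bool), labelmap, labels)
    areas = areas_px * pixel_size_um**2
    keep = (areas >= area_min_um2) & (areas <= area_max_um2)
    removed = labels[~keep]
    out = labelmap.copy()
    if removed.size:
        lut = np.ones(int(labelmap.max()) + 1, dtype=bool)
        lut[removed] = False
        out[~lut[labelmap]] = 0
    logger.info(
        "remove_labels: kept %d, removed %d outside [%.0f, %.0f] um^2",
        int(keep.sum()),
        int(removed.size),
        area_min_um2,
        area_max_um2,
    )
    return out


def background_area(
    labelmap: np.ndarray,
    stack: ImageStack,
    regions: RegionSet | None = None,
    event_px: int = 1,
) -> dict[str, np.ndarray]:
    """Per-channel intensity samples of the nucleus-free background.

    The background is the complement of all pre-gate nuclei, intersected
    with the analyzed tissue regions (all tissue polygons minus exclusions)
    when ``regions`` is given.  Events default to individual pixels
    (``event_px=1``); larger values average square tiles of that side length
    that lie entirely in the background, which tames pixel noise.
    """
    bg = labelmap == 0
    if regions is not None and regions.has_tissue:
        bg &= rasterize_roles(regions, labelmap.shape) > 0
    if not bg.any():
        raise EmptyBackgroundError(
            "no nucleus-free pixels in the analyzed area; background "
            "cannot be estimated"
        )
    events: dict[str, np.ndarray] = {}
    if event_px <= 1:
        # native dtype: at full-frame scale these samples are large
        for c in CHANNELS:
            events[c] = stack.channel(c)[bg]
        return events
    h, w = labelmap.shape
    th, tw = h // event_px, w // event_px
    crop_bg = bg[: th * event_px, : tw * event_px]
    tiles_bg = crop_bg.reshape(th, event_px, tw, event_px).all(axis=(1, 3))
    if not tiles_bg.any():
        raise EmptyBackgroundError(
            f"no {event_px}x{event_px} tile lies fully in the background"
        )
    for c in CHANNELS:
        crop = stack.channel(c)[: th * event_px, : tw * event_px].astype(np.float64)
        tiles = crop.reshape(th, event_px, tw, event_px).mean(axis=(1, 3))
        events[c] = tiles[tiles_bg]
    return events
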