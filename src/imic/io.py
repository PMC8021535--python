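"""Multichannel image stacks and region-of-interest geometry.

The imaging side of the pipeline works on 4-channel epifluorescence stacks:
a DAPI nuclear counterstain (the master channel used for segmentation) and
three marker channels named after their fluorophores — AF488 (pancytokeratin),
eFluor 570 (vimentin) and AF594 (CD45/CD18).  Pixel data use 14-bit camera
semantics stored in 16-bit containers; the physical pixel pitch defaults to
0.25378 µm.

Tissue compartments (epithelium, lamina propria) and artifact exclusions are
simple polygons in pixel coordinates.  Conventions: 0-based row-major arrays,
pixel centers at integer coordinates, polygon boundaries closed (a point on
the edge is inside).  Exclusion polygons take precedence over tissue
polygons; where tissue polygons overlap, the first listed wins.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon
from skimage.measure import grid_points_in_poly

logger = logging.getLogger(__name__)

CHANNELS = ("dapi", "af488", "efluor570", "af594")
MARKER_CHANNELS = ("af488", "efluor570", "af594")
MARKERS = ("cytokeratin", "vimentin", "cd45cd18")
MARKER_FOR_CHANNEL = dict(zip(MARKER_CHANNELS, MARKERS))
CHANNEL_FOR_MARKER = dict(zip(MARKERS, MARKER_CHANNELS))

DEFAULT_PIXEL_SIZE_UM = 0.25378
BIT_DEPTH = 14
INTENSITY_MAX = 2**BIT_DEPTH - 1  # 16383

ROLE_EPITHELIUM = "epithelium"
ROLE_LAMINA_PROPRIA = "lamina_propria"
ROLE_EXCLUDED = "excluded"
ROLE_NONE = "none"
TISSUE_ROLES = (ROLE_EPITHELIUM, ROLE_LAMINA_PROPRIA)
ROLE_CODES = {ROLE_NONE: 0, ROLE_EPITHELIUM: 1, ROLE_LAMINA_PROPRIA: 2}


class ChannelCountError(ValueError):
    """Raised when a stack does not contain exactly the 4 expected channels."""


@dataclass
class ImageStack:
    """A 4-channel fluorescence image with physical pixel-size metadata.

    Parameters
    ----------
    channels
        Mapping of channel name -> 2-D intensity raster.  All four of
        :data:`CHANNELS` must be present and share one shape.
    pixel_size_um
        Physical size of one pixel side in micrometres.
    bit_depth
        Dynamic-range tag; 14 means values live in [0, 16383] even though the
        arrays are stored as uint16.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = BIT_DEPTH

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.channels)
        extra = set(self.channels) - set(CHANNELS)
        if missing or extra:
            raise ChannelCountError(
                f"expected channels {CHANNELS}; missing={sorted(missing)} "
                f"unexpected={sorted(extra)}"
            )
        shapes = {self.channels[c].shape for c in CHANNELS}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[CHANNELS[0]].shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def as_array(self) -> np.ndarray:
        """Channels stacked in canonical order, shape (4, H, W)."""
        return np.stack([self.channels[c] for c in CHANNELS])


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multipage TIFF with JSON metadata in the description.

    The round trip through :func:`read_stack` is lossless for both pixel data
    and pixel-size metadata.
    """
    meta = {
        "axes": "CYX",
        "channels": list(CHANNELS),
        "pixel_size_um": stack.pixel_size_um,
        "bit_depth": stack.bit_depth,
    }
    # resolution tags carry pixels-per-centimetre for third-party readers;
    # the JSON description is what read_stack treats as authoritative.
    px_per_cm = 1e4 / stack.pixel_size_um
    tifffile.imwrite(
        Path(path),
        stack.as_array(),
        photometric="minisblack",
        description=json.dumps(meta),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a 4-channel TIFF written by :func:`write_stack` or compatible.

    A file without recoverable pixel-size metadata falls back to the default
    0.25378 µm with a logged warning.  A file whose first axis is not 4
    raises :class:`ChannelCountError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] != len(CHANNELS):
        raise ChannelCountError(
            f"{path} has {arr.shape[0] if arr.ndim == 3 else 1} channel(s); "
            f"expected {len(CHANNELS)} ({', '.join(CHANNELS)})"
        )
    names = meta.get("channels", list(CHANNELS))
    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        logger.warning(
            "%s carries no pixel-size metadata; assuming %.5f um/px",
            path,
            DEFAULT_PIXEL_SIZE_UM,
        )
        warnings.warn(
            f"{path}: no pixel-size metadata, assuming "
            f"{DEFAULT_PIXEL_SIZE_UM} um/px",
            stacklevel=2,
        )
        pixel_size = DEFAULT_PIXEL_SIZE_UM
    channels = {str(n): arr[i] for i, n in enumerate(names)}
    return ImageStack(
        channels=channels,
        pixel_size_um=float(pixel_size),
        bit_depth=int(meta.get("bit_depth", BIT_DEPTH)),
    )


def write_labelmap(labelmap: np.ndarray, path: str | Path) -> None:
    """Write a label image as a single-channel 16-bit TIFF.

    Label ids above 65535 do not fit the container and raise.
    """
    if labelmap.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed the 16-bit range")
    tifffile.imwrite(Path(path), labelmap.astype(np.uint16), photometric="minisblack")


def read_labelmap(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


@dataclass
class Region:
    """One named polygon with a tissue or exclusion role."""

    name: str
    role: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.role not in (*TISSUE_ROLES, ROLE_EXCLUDED):
            raise ValueError(f"unknown region role {self.role!r}")
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.name!r}: polygon is not simple/valid")


@dataclass
class RegionSet:
    """Ordered collection of tissue and exclusion polygons (pixel x/y coords)."""

    regions: list[Region] = field(default_factory=list)

    def by_role(self, role: str) -> list[Region]:
        return [r for r in self.regions if r.role == role]

    @property
    def has_tissue(self) -> bool:
        return any(r.role in TISSUE_ROLES for r in self.regions)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": [
                {
                    "name": r.name,
                    "role": r.role,
                    "vertices": [list(xy) for xy in r.polygon.exterior.coords[:-1]],
                }
                for r in self.regions
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionSet":
        payload = json.loads(Path(path).read_text())
        regions = [
            Region(rec["name"], rec["role"], Polygon(rec["vertices"]))
            for rec in payload["regions"]
        ]
        return cls(regions)


def rasterize_roles(regions: RegionSet, shape: tuple[int, int]) -> np.ndarray:
    """Role-code raster for a region set (0 none, 1 epithelium, 2 LP).

    Each pixel receives exactly one role, so areas measured on the result
    partition the frame exactly: first-listed tissue polygon wins where
    tissue polygons overlap, and exclusion polygons zero their pixels out
    last (precedence over tissue).
    """
    out = np.zeros(shape, dtype=np.uint8)
    for reg in regions.regions:
        if reg.role not in TISSUE_ROLES:
            continue
        m = _polygon_mask(reg.polygon, shape)
        out[m & (out == 0)] = ROLE_CODES[reg.role]
    for reg in regions.by_role(ROLE_EXCLUDED):
        out[_polygon_mask(reg.polygon, shape)] = 0
    return out


def _polygon_mask(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    # grid_points_in_poly fills the same pixels as polygon2mask but in O(1)
    # extra memory, which matters on full-frame rasters
    xy = np.asarray(poly.exterior.coords)
    rc = np.ascontiguousarray(xy[:, ::-1])
    return grid_points_in_poly(shape, rc)


def area_um2(
    geometry: np.ndarray | Polygon,
    pixel_size_um: float,
    image_shape: tuple[int, int] | None = None,
) -> float:
    """Physical area of a boolean mask or polygon in µm².

    Masks are pixel counts times the pixel area.  Polygons are rasterized to
    the image grid first (so mask and polygon areas agree); ``image_shape``
    is required for polygons.  Empty geometry returns 0.
    """
    if isinstance(geometry, Polygon):
        if geometry.is_empty:
            return 0.0
        if image_shape is None:
            raise ValueError("image_shape is required to rasterize a polygon")
        geometry = _polygon_mask(geometry, image_shape)
    mask = np.asarray(geometry)
    if mask.size == 0:
        return 0.0
    return float(np.count_nonzero(mask)) * pixel_size_um**2


def assign_region(
    centroids_xy: np.ndarray | Sequence[Sequence[float]],
    regions: RegionSet,
) -> np.ndarray:
    """Tissue role for each (x, y) centroid: epithelium, lamina_propria or none.

    Points inside an exclusion polygon are "none" regardless of tissue
    membership; a point on a polygon edge counts as inside (closed-boundary
    convention); points outside every tissue polygon are "none".
    """
    pts = np.atleast_2d(np.asarray(centroids_xy, dtype=float))
    n = len(pts)
    out = np.full(n, ROLE_NONE, dtype=object)
    if n == 0:
        return out.astype(str)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    excluded = np.zeros(n, dtype=bool)
    for reg in regions.by_role(ROLE_EXCLUDED):
        excluded |= shapely.covers(reg.polygon, geoms)
    assigned = np.zeros(n, dtype=bool)
    for reg in regions.regions:
        if reg.role not in TISSUE_ROLES:
            continue
        inside = shapely.covers(reg.polygon, geoms) & ~assigned & ~excluded
        out[inside] = reg.role
        assigned |= inside
    return out.astype(str)
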