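"""Synthetic 4-channel tissue phantoms with full per-cell ground truth.

The generator emulates a pseudostratified respiratory epithelium sitting on a
thicker lamina propria: a horizontal epithelial band over a connective-tissue
block, populated by eight cell lineages defined by the binary expression
triple (cytokeratin, vimentin, CD45/CD18).  Nuclei are non-overlapping
ellipses whose areas follow a lognormal law centred on a 64 µm² median;
the overall cell density targets 3486 cells/mm².  Marker channels carry
specific signal on cytoplasmic annuli of expressing lineages, on top of a
diffuse autofluorescence background, mixed through a 3x3 spillover matrix
and degraded by additive Gaussian noise.  Everything is clipped to the
14-bit camera range.

Three acquisition modes mirror the control slides used in practice:

* ``generate_phantom`` — the multiplexed stain (all three antibodies);
* ``generate_isotype_control`` — no specific marker signal at all, same
  nuclei and DAPI content for the same config/seed;
* ``generate_single_stain`` — one antibody only, so the other two marker
  channels see nothing but spillover from the stained one plus background.

All randomness flows from ``config.seed`` through one generator, and the
three modes consume the stream identically, so a phantom and its controls
are pixel-aligned and individually bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from .io import (
    DEFAULT_PIXEL_SIZE_UM,
    INTENSITY_MAX,
    MARKER_CHANNELS,
    ROLE_EPITHELIUM,
    ROLE_LAMINA_PROPRIA,
    ImageStack,
    Region,
    RegionSet,
)

logger = logging.getLogger(__name__)

POPULATION_NAMES = {
    (True, False, False): "cytokeratin_single_positive",
    (False, True, False): "vimentin_single_positive",
    (False, False, True): "cd45cd18_single_positive",
    (False, True, True): "cd45cd18_vimentin_double_positive",
    (True, True, False): "cytokeratin_vimentin_double_positive",
    (True, False, True): "cytokeratin_cd45cd18_double_positive",
    (True, True, True): "triple_positive",
    (False, False, False): "triple_negative",
}

#: all-patient mean population fractions (both compartments pooled) used as
#: the default lineage mix in either region; they sum to 1.
DEFAULT_LINEAGE_FRACTIONS = {
    "cytokeratin_single_positive": 0.26,
    "vimentin_single_positive": 0.13,
    "cd45cd18_single_positive": 0.06,
    "cd45cd18_vimentin_double_positive": 0.23,
    "cytokeratin_vimentin_double_positive": 0.03,
    "cytokeratin_cd45cd18_double_positive": 0.10,
    "triple_positive": 0.11,
    "triple_negative": 0.08,
}

#: mean specific signal added on the cytoplasmic annulus, per marker channel
#: (camera units); chosen so realized cell/background ratios sit in the
#: 1.5–4 range over a background of ~200 counts.
DEFAULT_SIGNAL_LEVELS = {"af488": 600.0, "efluor570": 800.0, "af594": 500.0}


class PlacementError(RuntimeError):
    """Nucleus placement failed; the message names the achievable density."""


@dataclass(frozen=True)
class LineageProfile:
    """One of the 8 canonical lineages defined by the marker triple.

    ``expresses`` orders the booleans as (cytokeratin, vimentin, cd45cd18).
    ``signal_level`` gives the mean specific intensity per marker channel in
    camera units when the corresponding marker is expressed; ``signal_cv``
    is the cell-to-cell coefficient of variation of that amplitude.
    Fibroblast-like cells (vimentin-single-positive) carry an elongated
    cytoplasmic halo, which is what motivates the deeper eFluor 570 growing
    limit downstream.
    """

    name: str
    expresses: tuple[bool, bool, bool]
    signal_level: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_LEVELS)
    )
    signal_cv: float = 0.2
    elongated: bool = False

    def __post_init__(self) -> None:
        if len(self.expresses) != 3:
            raise ValueError("expresses must be a triple of booleans")


def canonical_profiles(
    signal_levels: Mapping[str, float] | None = None, signal_cv: float = 0.2
) -> dict[str, LineageProfile]:
    """The 8 canonical lineage profiles, one per element of {0,1}^3."""
    levels = dict(signal_levels or DEFAULT_SIGNAL_LEVELS)
    profiles = {}
    for triple, name in POPULATION_NAMES.items():
        profiles[name] = LineageProfile(
            name=name,
            expresses=triple,
            signal_level=levels,
            signal_cv=signal_cv,
            elongated=(name == "vimentin_single_positive"),
        )
    return profiles


@dataclass
class PhantomConfig:
    """Geometry, cytology and optics of one synthetic tissue field.

    Defaults reproduce the reference acquisition conditions: 0.25378 µm
    pixels, 3486 cells/mm², lognormal nucleus areas with a 64 µm² median,
    sub-1% channel spillover and a 14-bit dynamic range.  The default field
    is a 1 mm² square with the epithelial band occupying the top 10% of the
    height (epithelium-to-LP area ratio close to the measured one).
    """

    width_px: int = 3940
    height_px: int = 3940
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    epithelium_fraction: float = 0.10
    cell_density_per_mm2: float = 3486.0
    nucleus_area_um2_median: float = 64.0
    nucleus_area_log_sd: float = 0.10
    lineage_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            ROLE_EPITHELIUM: dict(DEFAULT_LINEAGE_FRACTIONS),
            ROLE_LAMINA_PROPRIA: dict(DEFAULT_LINEAGE_FRACTIONS),
        }
    )
    signal_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_LEVELS)
    )
    signal_cv: float = 0.2
    nuclear_signal_level: float = 3000.0
    background_level: dict[str, float] = field(
        default_factory=lambda: {
            "dapi": 100.0,
            "af488": 200.0,
            "efluor570": 200.0,
            "af594": 200.0,
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "dapi": 10.0,
            "af488": 20.0,
            "efluor570": 20.0,
            "af594": 20.0,
        }
    )
    spillover: np.ndarray = field(
        default_factory=lambda: np.eye(3) + 0.005 * (1 - np.eye(3))
    )
    annulus_width_um: float = 2.0
    elongated_extra_um: float = 4.0
    min_separation_um: float = 1.0
    axis_ratio_range: tuple[float, float] = (1.0, 2.5)
    gland_cluster_sd_um: float = 25.0
    glands_per_mm2: float = 8.0
    gland_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.spillover = np.asarray(self.spillover, dtype=float)
        if self.spillover.shape != (3, 3):
            raise ValueError("spillover must be a 3x3 matrix")
        if not np.allclose(np.diag(self.spillover), 1.0):
            raise ValueError("spillover diagonal must be 1")
        off = self.spillover[~np.eye(3, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("spillover off-diagonals must lie in [0, 1)")
        for region, fracs in self.lineage_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"lineage fractions in {region} sum to {total}, expected 1"
                )
            unknown = set(fracs) - set(POPULATION_NAMES.values())
            if unknown:
                raise ValueError(f"unknown lineage names {sorted(unknown)}")
        levels = [self.nuclear_signal_level, *self.signal_levels.values()]
        levels += list(self.background_level.values())
        if any(v < 0 or v > INTENSITY_MAX for v in levels):
            raise ValueError(f"intensity levels must lie in [0, {INTENSITY_MAX}]")
        if self.width_px <= 0 or self.height_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("image dimensions and pixel size must be positive")
        if not 0 <= self.epithelium_fraction <= 1:
            raise ValueError("epithelium_fraction must lie in [0, 1]")
        if self.cell_density_per_mm2 < 0:
            raise ValueError("cell_density_per_mm2 must be non-negative")

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * self.pixel_size_um**2 / 1e6

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["spillover"] = self.spillover.tolist()
        d["axis_ratio_range"] = list(self.axis_ratio_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "axis_ratio_range" in d:
            d["axis_ratio_range"] = tuple(d["axis_ratio_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-cell truth for one phantom: table plus nucleus label image.

    ``table`` columns: cell_id, centroid_row, centroid_col, nucleus_label,
    nucleus_area_um2, region, lineage, and the three expression booleans.
    ``label_image`` maps each truth nucleus to one connected component whose
    label equals the cell_id.
    """

    table: pd.DataFrame
    label_image: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    def write_table(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_table(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


def _ellipse_patch(
    a_px: float, b_px: float, theta: float
) -> tuple[np.ndarray, int]:
    """Boolean patch of an ellipse (semi-axes in px, rotation theta) centred
    in a square patch; returns (patch, half-size)."""
    half = int(np.ceil(max(a_px, b_px))) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0, half


def _regions_for(config: PhantomConfig) -> tuple[RegionSet, int]:
    """Epithelial band over LP block as rectangles; returns (regions, band rows)."""
    h, w = config.height_px, config.width_px
    band = int(round(config.epithelium_fraction * h))
    regions = []
    if band > 0:
        regions.append(
            Region("epithelium", ROLE_EPITHELIUM, box(-0.5, -0.5, w - 0.5, band - 0.5))
        )
    if band < h:
        regions.append(
            Region(
                "lamina_propria",
                ROLE_LAMINA_PROPRIA,
                box(-0.5, band - 0.5, w - 0.5, h - 0.5),
            )
        )
    return RegionSet(regions), band


def _generate(
    config: PhantomConfig, mode: str
) -> tuple[ImageStack, GroundTruth, RegionSet]:
    """Shared generator behind the three public modes.

    mode is "multiplex", "isotype" or "single:<channel>".  The random stream
    is consumed identically in every mode: suppressed signal contributions
    are multiplied by zero rather than skipped.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    ps = config.pixel_size_um
    regions, band = _regions_for(config)
    profiles = canonical_profiles(config.signal_levels, config.signal_cv)

    n_cells = int(rng.poisson(config.cell_density_per_mm2 * config.area_mm2))

    # gland centres: cytokeratin-positive LP cells cluster around these
    lp_height = h - band
    n_glands = 0
    gland_centers = np.empty((0, 2))
    if lp_height > 0:
        lp_area_mm2 = lp_height * w * ps**2 / 1e6
        n_glands = max(1, int(round(config.glands_per_mm2 * lp_area_mm2)))
        gland_centers = np.column_stack(
            [
                rng.uniform(band, h, size=n_glands),
                rng.uniform(0, w, size=n_glands),
            ]
        )

    margin_px = config.min_separation_um / ps
    occupied = np.zeros((h, w), dtype=bool)
    label_image = np.zeros((h, w), dtype=np.int32)
    dapi_specific = np.zeros((h, w), dtype=np.float32)
    specific = {c: np.zeros((h, w), dtype=np.float32) for c in MARKER_CHANNELS}

    lineage_names = {
        region: list(fracs) for region, fracs in config.lineage_fractions.items()
    }
    lineage_probs = {
        region: np.array([fracs[n] for n in lineage_names[region]])
        for region, fracs in config.lineage_fractions.items()
    }

    rows = []
    placed = 0
    max_attempts_per_cell = 200
    for cell_id in range(1, n_cells + 1):
        area_um2 = config.nucleus_area_um2_median * np.exp(
            config.nucleus_area_log_sd * rng.standard_normal()
        )
        q = rng.uniform(*config.axis_ratio_range)
        theta = rng.uniform(0, np.pi)
        a_um = np.sqrt(area_um2 * q / np.pi)
        b_um = np.sqrt(area_um2 / (np.pi * q))
        a_px, b_px = a_um / ps, b_um / ps
        test_patch, test_half = _ellipse_patch(a_px + margin_px, b_px + margin_px, theta)
        paint_patch, paint_half = _ellipse_patch(a_px, b_px, theta)

        # first draw decides the region by band membership; the lineage is
        # then fixed and only the position is re-drawn on collisions.
        row0 = rng.uniform(0, h)
        region = ROLE_EPITHELIUM if row0 < band else ROLE_LAMINA_PROPRIA
        if region not in config.lineage_fractions:
            region = next(iter(config.lineage_fractions))
        names = lineage_names[region]
        lineage = names[rng.choice(len(names), p=lineage_probs[region])]
        profile = profiles[lineage]
        # glandular cells: a share of CK-single-positive LP cells sit in
        # gland patches rather than uniformly in the connective tissue
        clustered = (
            region == ROLE_LAMINA_PROPRIA
            and lineage == "cytokeratin_single_positive"
            and n_glands > 0
            and rng.uniform() < config.gland_fraction
        )

        lo = band if region == ROLE_LAMINA_PROPRIA else 0
        hi = band if region == ROLE_EPITHELIUM else h
        placed_ok = False
        for attempt in range(max_attempts_per_cell):
            if attempt == max_attempts_per_cell // 2:
                clustered = False  # crowded gland: overflow into the stroma
            if clustered:
                g = gland_centers[rng.integers(n_glands)]
                jitter = rng.normal(0, config.gland_cluster_sd_um / ps, size=2)
                r0, c0 = g[0] + jitter[0], g[1] + jitter[1]
                if not (lo <= r0 < hi and 0 <= c0 < w):
                    continue
            else:
                r0 = rng.uniform(lo, hi)
                c0 = rng.uniform(0, w)
            ri, ci = int(round(r0)), int(round(c0))
            if not lo <= ri < hi:  # rounding must not cross the band boundary
                continue
            if not (
                test_half <= ri < h - test_half and test_half <= ci < w - test_half
            ):
                continue
            sl = (
                slice(ri - test_half, ri + test_half + 1),
                slice(ci - test_half, ci + test_half + 1),
            )
            if occupied[sl][test_patch].any():
                continue
            placed_ok = True
            break
        if not placed_ok:
            achieved = placed / config.area_mm2
            raise PlacementError(
                f"could not place nucleus {cell_id}/{n_cells} after "
                f"{max_attempts_per_cell} attempts; achievable density at this "
                f"geometry is about {achieved:.0f} cells/mm^2 "
                f"(requested {config.cell_density_per_mm2:.0f})"
            )

        # occupancy stores the bare nucleus; candidates test the margin-
        # inflated footprint, so nuclear borders stay >= min_separation apart
        psl0 = (
            slice(ri - paint_half, ri + paint_half + 1),
            slice(ci - paint_half, ci + paint_half + 1),
        )
        occupied[psl0][paint_patch] = True
        psl = (
            slice(ri - paint_half, ri + paint_half + 1),
            slice(ci - paint_half, ci + paint_half + 1),
        )
        label_image[psl][paint_patch] = cell_id

        # amplitude factors are always drawn (stream stability across modes)
        dapi_factor = max(0.0, 1.0 + 0.15 * rng.standard_normal())
        marker_factors = 1.0 + profile.signal_cv * rng.standard_normal(3)
        marker_factors = np.clip(marker_factors, 0.0, None)

        dapi_specific[psl][paint_patch] += config.nuclear_signal_level * dapi_factor

        ann = config.annulus_width_um / ps
        extra = config.elongated_extra_um / ps if profile.elongated else 0.0
        halo_patch, halo_half = _ellipse_patch(a_px + ann + extra, b_px + ann, theta)
        hs = (
            slice(ri - halo_half, ri + halo_half + 1),
            slice(ci - halo_half, ci + halo_half + 1),
        )
        pad = halo_half - paint_half
        donut = halo_patch.copy()
        donut[pad : pad + paint_patch.shape[0], pad : pad + paint_patch.shape[1]] &= (
            ~paint_patch
        )
        # clip halo to frame
        r_lo, r_hi = ri - halo_half, ri + halo_half + 1
        c_lo, c_hi = ci - halo_half, ci + halo_half + 1
        dr_lo, dc_lo = max(0, -r_lo), max(0, -c_lo)
        dr_hi = donut.shape[0] - max(0, r_hi - h)
        dc_hi = donut.shape[1] - max(0, c_hi - w)
        donut_c = donut[dr_lo:dr_hi, dc_lo:dc_hi]
        hs = (slice(max(0, r_lo), min(h, r_hi)), slice(max(0, c_lo), min(w, c_hi)))

        for k, chan in enumerate(MARKER_CHANNELS):
            expressed = profile.expresses[k]
            if mode == "isotype":
                on = False
            elif mode.startswith("single:"):
                on = expressed and (chan == mode.split(":", 1)[1])
            else:
                on = expressed
            if on:
                amp = profile.signal_level[chan] * marker_factors[k]
                specific[chan][hs][donut_c] += amp

        placed += 1
        rows.append(
            {
                "cell_id": cell_id,
                "centroid_row": ri,
                "centroid_col": ci,
                "nucleus_label": cell_id,
                "nucleus_area_um2": int(paint_patch.sum()) * ps**2,
                "region": region,
                "lineage": lineage,
                "cytokeratin": profile.expresses[0],
                "vimentin": profile.expresses[1],
                "cd45cd18": profile.expresses[2],
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "centroid_row",
            "centroid_col",
            "nucleus_label",
            "nucleus_area_um2",
            "region",
            "lineage",
            "cytokeratin",
            "vimentin",
            "cd45cd18",
        ],
    )

    # mix marker channels through the spillover matrix, add background+noise
    channels: dict[str, np.ndarray] = {}
    clipped = 0
    del occupied
    dapi = dapi_specific
    dapi += np.float32(config.background_level["dapi"])
    noise = rng.standard_normal(size=(h, w), dtype=np.float32)
    noise *= np.float32(config.noise_sd["dapi"])
    dapi += noise
    del noise
    clipped += int(np.count_nonzero(dapi > INTENSITY_MAX))
    channels["dapi"] = np.clip(dapi, 0, INTENSITY_MAX).astype(np.uint16)
    del dapi, dapi_specific

    M = config.spillover
    for i, chan in enumerate(MARKER_CHANNELS):
        mixed = np.zeros((h, w), dtype=np.float32)
        for j, src in enumerate(MARKER_CHANNELS):
            if M[i, j] != 0:
                mixed += np.float32(M[i, j]) * specific[src]
        mixed += np.float32(config.background_level[chan])
        noise = rng.standard_normal(size=(h, w), dtype=np.float32)
        noise *= np.float32(config.noise_sd[chan])
        mixed += noise
        del noise
        clipped += int(np.count_nonzero(mixed > INTENSITY_MAX))
        channels[chan] = np.clip(mixed, 0, INTENSITY_MAX).astype(np.uint16)
        del mixed
    del specific
    if clipped:
        logger.info("clipped %d pixels to the 14-bit range", clipped)

    stack = ImageStack(channels=channels, pixel_size_um=ps)
    truth = GroundTruth(table=table, label_image=label_image)
    logger.info(
        "phantom %s: %d cells over %.3f mm^2 (%.0f cells/mm^2)",
        mode,
        placed,
        config.area_mm2,
        placed / config.area_mm2 if config.area_mm2 else 0.0,
    )
    return stack, truth, regions


def generate_phantom(
    config: PhantomConfig,
) -> tuple[ImageStack, GroundTruth, RegionSet]:
    """Multiplexed tissue phantom: all expressed markers carry signal."""
    return _generate(config, "multiplex")


def generate_isotype_control(config: PhantomConfig) -> ImageStack:
    """Isotype-control slide: same nuclei/DAPI, marker channels are
    background and noise only."""
    stack, _, _ = _generate(config, "isotype")
    return stack


def generate_single_stain(
    config: PhantomConfig, channel: str
) -> tuple[ImageStack, GroundTruth]:
    """Single-stain slide: only ``channel`` carries specific signal; the
    other marker channels receive spillover from it plus background."""
    if channel not in MARKER_CHANNELS:
        raise ValueError(
            f"channel must be one of {MARKER_CHANNELS}, got {channel!r}"
        )
    stack, truth, _ = _generate(config, f"single:{channel}")
    return stack, truth
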