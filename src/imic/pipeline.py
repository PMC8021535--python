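"""End-to-end orchestration: simulate -> segment -> grow -> quantify ->
classify -> tabulate -> QC, behind one reproducible configuration.

`analyze_stack` is the library workhorse: it takes a 4-channel stack plus
regions and returns every intermediate product (label maps, cell table,
background, thresholds, classified cells, population table).  `run` wraps
it with configuration parsing, artifact writing and a plain-text log so a
whole experiment reruns byte-identically from a config file and a seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .gating import (
    ChannelThreshold,
    CiMethod,
    RatioMode,
    classify_cells,
    compute_thresholds,
)
from .growing import GrowingParams, _GrowGeometry, grow_cell_masks
from .io import (
    MARKER_CHANNELS,
    ImageStack,
    RegionSet,
    read_stack,
    write_stack,
)
from .phantom import (
    PhantomConfig,
    generate_isotype_control,
    generate_phantom,
    generate_single_stain,
)
from .populations import PopulationTable, tabulate
from .quantify import BackgroundEstimate, estimate_background, quantify_cells
from .segmentation import (
    SegmentationParams,
    background_area,
    nucleus_records,
    remove_labels,
    segment_nuclei,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A run configuration is incomplete or inconsistent."""


class _LazyMasks:
    """Mapping-like view that grows each channel's masks on first access.

    Shares one distance geometry across channels and never retains the
    grown label images, keeping the peak footprint to a single channel.
    """

    def __init__(
        self, labelmap: np.ndarray, stack: ImageStack, params: GrowingParams
    ) -> None:
        self._labelmap = labelmap
        self._stack = stack
        self._params = params
        self._geom = (
            _GrowGeometry(labelmap, stack.pixel_size_um, params.step_width_um)
            if labelmap.max() > 0
            else None
        )

    def __getitem__(self, channel: str) -> np.ndarray:
        if self._geom is None:
            return np.zeros_like(self._labelmap, dtype=np.int32)
        return grow_cell_masks(
            self._labelmap,
            self._stack.channel(channel),
            self._stack.pixel_size_um,
            self._params.max_growing_steps.get(channel, 0.0),
            self._params,
            geometry=self._geom,
        )


@dataclass
class AnalysisResult:
    """Every stage product of one stack analysis."""

    labelmap_pregate: np.ndarray
    labelmap: np.ndarray
    nuclei: pd.DataFrame
    cells: pd.DataFrame
    background: BackgroundEstimate
    thresholds: dict[str, ChannelThreshold]
    classified: pd.DataFrame
    populations: PopulationTable
    counts: dict[str, int]


def analyze_stack(
    stack: ImageStack,
    regions: RegionSet | None = None,
    seg_params: SegmentationParams | None = None,
    grow_params: GrowingParams | None = None,
    ratio_mode: RatioMode = "quotient",
    sample_fraction: float = 0.30,
    ci_method: CiMethod = "order_statistic",
    seed: int | None = 0,
    thresholds: Mapping[str, ChannelThreshold] | None = None,
) -> AnalysisResult:
    """Run the full cytometry chain on one stack.

    When ``thresholds`` is given (e.g. from a matched multiplexed run, as
    used for isotype and single-stain controls) they are applied as-is;
    otherwise thresholds are derived from this stack's own cells.
    """
    seg_params = seg_params or SegmentationParams()
    grow_params = grow_params or GrowingParams()
    ps = stack.pixel_size_um

    pregate = segment_nuclei(stack.channel("dapi"), seg_params, ps)
    gated = remove_labels(
        pregate, ps, seg_params.area_min_um2, seg_params.area_max_um2
    )
    nuclei = nucleus_records(gated, ps)
    n_pre = int(len(np.unique(pregate)) - 1)
    n_post = len(nuclei)
    logger.info("identified %d nuclei, removed %d by the area gate", n_pre, n_pre - n_post)

    events = background_area(pregate, stack, regions)
    background = estimate_background(events)
    del events
    # masks are grown lazily, one channel at a time, so only one per-channel
    # label image is alive at once (full-frame runs are memory-bound)
    masks = _LazyMasks(gated, stack, grow_params)
    cells = quantify_cells(stack, nuclei, masks, regions)
    del masks

    if thresholds is None:
        thresholds = compute_thresholds(
            cells,
            background.median,
            ratio_mode=ratio_mode,
            fraction=sample_fraction,
            seed=seed,
            ci_method=ci_method,
        )
    classified = classify_cells(cells, background.median, thresholds, ratio_mode)
    populations = tabulate(classified)
    return AnalysisResult(
        labelmap_pregate=pregate,
        labelmap=gated,
        nuclei=nuclei,
        cells=cells,
        background=background,
        thresholds=dict(thresholds),
        classified=classified,
        populations=populations,
        counts={
            "nuclei_identified": n_pre,
            "nuclei_removed": n_pre - n_post,
            "nuclei_retained": n_post,
            "cells_classified": len(classified),
        },
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input source: a phantom config (simulated) or paths to a
    stack TIFF and a regions JSON.  All stage parameters are recorded so
    the run report documents every effective value.
    """

    outdir: str = "imic_run"
    phantom: PhantomConfig | None = None
    stack_path: str | None = None
    regions_path: str | None = None
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    grow: GrowingParams = field(default_factory=GrowingParams)
    ratio_mode: RatioMode = "quotient"
    sample_fraction: float = 0.30
    ci_method: CiMethod = "order_statistic"
    seed: int = 0
    write_images: bool = False
    qc: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs and kwargs["phantom"] is not None:
            kwargs["phantom"] = PhantomConfig(**kwargs["phantom"])
        if "seg" in kwargs:
            kwargs["seg"] = SegmentationParams(**kwargs["seg"])
        if "grow" in kwargs:
            kwargs["grow"] = GrowingParams(**kwargs["grow"])
        return cls(**kwargs)


def _load_inputs(config: RunConfig):
    if config.phantom is not None:
        phantom_cfg = config.phantom
        stack, truth, regions = generate_phantom(phantom_cfg)
        return stack, regions, truth
    if config.stack_path is None:
        raise ConfigurationError(
            "configuration needs either a phantom section or a stack_path"
        )
    if config.regions_path is None:
        raise ConfigurationError(
            "region-stratified analysis requested but no regions file given; "
            "set regions_path to the polygon JSON"
        )
    stack = read_stack(config.stack_path)
    regions = RegionSet.from_json(config.regions_path)
    return stack, regions, None


def run(config: RunConfig) -> dict:
    """Execute a configured run; returns the report dict and writes artifacts.

    Artifacts (all delimited text / JSON): nuclei.tsv, cells.tsv,
    classified.tsv, populations.tsv, report.json, run.log, and optionally
    the simulated stack and truth table.  Identical config + seed reproduce
    identical tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("imic")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    timings: dict[str, float] = {}
    try:
        stack, regions, truth = _load_inputs(config)
        timings["inputs_s"] = round(time.time() - t0, 2)
        if truth is not None:
            truth.write_table(outdir / "truth.tsv")
            regions.to_json(outdir / "regions.json")
            if config.write_images:
                write_stack(stack, outdir / "stack.tiff")

        t1 = time.time()
        result = analyze_stack(
            stack,
            regions,
            seg_params=config.seg,
            grow_params=config.grow,
            ratio_mode=config.ratio_mode,
            sample_fraction=config.sample_fraction,
            ci_method=config.ci_method,
            seed=config.seed,
        )
        timings["analysis_s"] = round(time.time() - t1, 2)

        if config.write_images:
            from .io import write_labelmap

            write_labelmap(result.labelmap, outdir / "nuclei_labels.tiff")
        result.nuclei.to_csv(outdir / "nuclei.tsv", sep="\t", index=False)
        result.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
        result.classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)
        result.populations.to_csv(outdir / "populations.tsv")

        report = {
            "provenance": {
                "seed": config.seed,
                "ratio_mode": config.ratio_mode,
                "ci_method": config.ci_method,
                "sample_fraction": config.sample_fraction,
                "seg": asdict(config.seg),
                "grow": asdict(config.grow),
                "pixel_size_um": stack.pixel_size_um,
            },
            "counts": result.counts,
            "background_median": result.background.median,
            "thresholds": {
                c: asdict(t) for c, t in result.thresholds.items()
            },
            "populations": {
                f"{g}/{r}": result.populations.percentages(g, r).round(4).to_dict()
                for g, r in sorted(
                    set(
                        zip(
                            result.populations.table.index.get_level_values(0),
                            result.populations.table.index.get_level_values(1),
                        )
                    )
                )
            },
            "region_none_cells": result.populations.none_count,
            "regions": _region_summary(result, regions, stack),
            "timings": timings,
        }

        if config.qc and config.phantom is not None:
            report["qc"] = run_phantom_qc(config.phantom, result)

        report["timings"]["total_s"] = round(time.time() - t0, 2)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception as exc:  # noqa: BLE001 - stage name in the message
        logger.error("run failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _region_summary(
    result: AnalysisResult, regions: RegionSet | None, stack: ImageStack
) -> dict:
    """Per-region tissue area (mm^2), cell count and density (cells/mm^2)."""
    from .io import TISSUE_ROLES, rasterize_roles

    out: dict[str, dict] = {}
    if regions is None or not regions.has_tissue:
        return out
    roles = rasterize_roles(regions, stack.shape)
    for code, role in enumerate(TISSUE_ROLES, start=1):
        area_mm2 = float(np.count_nonzero(roles == code)) * stack.pixel_area_um2 / 1e6
        n = int((result.classified["region"] == role).sum())
        out[role] = {
            "area_mm2": round(area_mm2, 4),
            "cell_count": n,
            "density_per_mm2": round(n / area_mm2, 1) if area_mm2 > 0 else None,
        }
    return out


def run_phantom_qc(phantom_cfg: PhantomConfig, tissue: AnalysisResult) -> dict:
    """Isotype ROC + triple-negative check and spillover check on phantoms.

    Control slides are re-simulated from the same config/seed; control
    cells are gated with the tissue run's thresholds (the negative-control
    convention: the reference distribution is judged against the assay's
    own cutoffs).
    """
    iso_stack = generate_isotype_control(phantom_cfg)
    iso = analyze_stack(
        iso_stack,
        _phantom_regions(phantom_cfg),
        thresholds=tissue.thresholds,
    )
    roc = {}
    for c in MARKER_CHANNELS:
        r = qc_mod.isotype_roc(
            tissue.cells[f"mean_{c}"].to_numpy(),
            iso.cells[f"mean_{c}"].to_numpy(),
            channel=c,
        )
        roc[c] = {"auc": r.auc, "p_value": r.p_value}
    triple_neg = float(
        (iso.classified["population"] == "triple_negative").mean()
    )

    classified_by_source = {}
    for c in MARKER_CHANNELS:
        ss_stack, _ = generate_single_stain(phantom_cfg, c)
        ss = analyze_stack(
            ss_stack,
            _phantom_regions(phantom_cfg),
            thresholds=tissue.thresholds,
        )
        classified_by_source[c] = ss.classified
    spill = qc_mod.spillover_estimate(classified_by_source)
    return {
        "isotype_roc": roc,
        "isotype_triple_negative_fraction": triple_neg,
        "spillover_off_target": {
            f"{s}->{t}": v for (s, t), v in spill.off_target().items()
        },
        "spillover_bound": spill.bound,
        "spillover_passed": spill.passed,
    }


def _phantom_regions(config: PhantomConfig) -> RegionSet:
    from .phantom import _regions_for

    return _regions_for(config)[0]
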