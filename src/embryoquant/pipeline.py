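"""End-to-end orchestration: phantom → segmentation → quantification →
geometry → statistics, with config, logging and provenance.

A run produces, under one output directory: ``records.csv`` (one row per
cell, merging intensity, geometry and position-class columns),
``geometry.csv``, ``report.json`` (routed inner-vs-outer statistics) and
``provenance.json`` (every parameter and seed, sufficient to re-execute the
deterministic stages bit-identically).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frap import analyze_trace
from .geometry import (
    SurfacePointCloud,
    apical_surface_area,
    aspect_ratio,
    distance_to_embryo_cm,
    extract_apical_surface,
    fit_ellipsoid,
    flatness,
    nuclear_deformation_index,
    oriented_bounding_box,
    sphericity,
    surface_points_from_mask,
)
from .io_formats import (
    LabelVolume,
    VolumeImage,
    write_labels,
    write_provenance,
    write_records_csv,
    write_volume,
)
from .quantify import cell_intensity_record, nucleus_record
from .segmentation import (
    NucleusSegmentationParams,
    classify_inner_outer,
    make_cortex_cytoplasm_masks,
    segment_cells,
    segment_nuclei,
)
from .stats_report import route_and_test, summarize_groups
from .synthetic import PhantomSpec, generate_embryo_phantom

logger = logging.getLogger("embryoquant")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_embryo"]


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; every field has a default."""

    phantom: PhantomSpec | None = None
    input_volume: str | None = None  # alternative to phantom: OME-TIFF path
    spacing_override: tuple[float, float, float] | None = None
    dapi_channel: str = "dapi"
    membrane_channel: str = "actin"
    lamin_channel: str = "lamin"
    shell_um: float = 1.2  # lamina-shell thickness for L:N
    band_um: float = 1.0  # cortex/cytoplasm band
    cutoff_um: float = 1.0  # apical-surface neighbour cutoff
    use_truth_masks: bool = False  # bypass segmentation, use phantom truth labels
    nucleus_params: NucleusSegmentationParams = field(default_factory=NucleusSegmentationParams)
    group_metric: str = "ln_ratio"
    seed: int = 0
    out_dir: str | None = None
    write_volumes: bool = False


@dataclass
class PipelineResult:
    records: pd.DataFrame
    geometry: pd.DataFrame
    report: dict
    cells: LabelVolume
    nuclei: LabelVolume
    truth_table: pd.DataFrame | None = None


def _embryo_center_of_mass(cells: LabelVolume) -> np.ndarray:
    idx = np.argwhere(cells.labels > 0)
    return (idx.mean(axis=0) + 0.5) * np.asarray(cells.voxel_spacing)


def analyze_embryo(
    img: VolumeImage,
    cells: LabelVolume,
    nuclei: LabelVolume,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell intensity and geometry records for one segmented embryo.

    Cell and nucleus label volumes must use matching ids.  Returns
    ``(records, geometry)`` data frames; ``records`` contains everything
    (intensity metrics, position class, geometry columns merged in).
    """
    spacing = cells.voxel_spacing
    ids = [int(i) for i in cells.ids()]
    position = classify_inner_outer(cells)
    embryo_cm = _embryo_center_of_mass(cells)

    clouds = {
        i: surface_points_from_mask(cells.labels == i, spacing, object_id=i) for i in ids
    }

    intensity_rows = []
    geometry_rows = []
    for i in ids:
        t0 = time.perf_counter()
        cell_mask = cells.labels == i
        nucleus_mask = (nuclei.labels == i) & cell_mask
        if not np.any(nucleus_mask):
            raise RuntimeError(f"stage quantify, cell {i}: no matching nucleus label")
        masks = make_cortex_cytoplasm_masks(
            cell_mask,
            nucleus_mask,
            spacing,
            band_um=config.band_um,
            object_id=i,
            shell_thickness_um=config.shell_um,
        )
        masks.validate()
        rec = nucleus_record(img, masks, config.lamin_channel, config.dapi_channel)
        rec.update(cell_intensity_record(img, masks, dapi_channel=config.dapi_channel))
        rec["position_class"] = position[i]

        # geometry
        apical = extract_apical_surface(
            clouds[i], [clouds[j] for j in ids if j != i], cutoff_um=config.cutoff_um
        )
        if len(apical) == 0:
            logger.warning("cell %d: empty apical surface (inner cell)", i)
        box = oriented_bounding_box(clouds[i], embryo_cm, apical if len(apical) else None)
        nuc_cloud = surface_points_from_mask(nucleus_mask, spacing, object_id=i, source="nucleus")
        fit = fit_ellipsoid(nuc_cloud)
        nuc_idx = np.argwhere(nucleus_mask)
        nucleus_cm = (nuc_idx.mean(axis=0) + 0.5) * np.asarray(spacing)
        total_area = apical_surface_area(clouds[i])  # full hull area of the cell cloud
        api_area = apical_surface_area(apical, cell=clouds[i]) if len(apical) >= 3 else 0.0
        geo = {
            "cell_id": i,
            "position_class": position[i],
            "distance_to_embryo_cm": distance_to_embryo_cm(nucleus_cm, embryo_cm),
            "aspect_ratio": aspect_ratio(box),
            "flatness": flatness(box),
            "Lx": box.Lx,
            "Ly": box.Ly,
            "Lz": box.Lz,
            "Lz_api": box.Lz_api,
            "apical_area": api_area,
            "total_area": total_area,
            "apical_fraction": api_area / total_area if total_area > 0 else 0.0,
            "radial_fallback": box.radial_fallback,
            "nuclear_deformation_index": nuclear_deformation_index(nuc_cloud, fit),
            "nucleus_sphericity": sphericity(nucleus_mask, spacing),
        }
        geometry_rows.append(geo)
        rec.update({k: v for k, v in geo.items() if k not in ("cell_id", "position_class")})
        intensity_rows.append(rec)
        logger.info("cell %d analyzed in %.2f s", i, time.perf_counter() - t0)

    records = pd.DataFrame(intensity_rows)
    geometry = pd.DataFrame(geometry_rows)
    return records, geometry


def _group_report(records: pd.DataFrame, metric: str) -> dict:
    """Inner-vs-outer routed comparison plus median/IQR summaries."""
    summary = summarize_groups(records, by="position_class")
    report: dict = {
        "metric": metric,
        "summary": summary.to_dict(orient="records"),
    }
    groups = {
        str(g): sub[metric].dropna().to_numpy()
        for g, sub in records.groupby("position_class")
    }
    sizes = {g: len(v) for g, v in groups.items()}
    if len(groups) >= 2 and all(n >= 3 for n in sizes.values()):
        cmp = route_and_test(groups)
        report["comparison"] = {
            "groups": cmp.group_names,
            "sizes": cmp.group_sizes,
            "normality_p": cmp.normality_p,
            "test_used": cmp.test_used,
            "statistic": cmp.statistic,
            "p_value": cmp.p_value,
            "flags": list(cmp.flags),
        }
        if cmp.posthoc is not None:
            report["comparison"]["posthoc"] = cmp.posthoc.to_dict(orient="records")
    else:
        report["comparison"] = None
        report["comparison_skipped"] = f"group sizes {sizes} (need >= 2 groups with n >= 3)"
    return report


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Stages: acquire volume (generate phantom or read TIFF) → segment nuclei
    and cells (or adopt phantom truth masks) → per-cell quantification and
    geometry → inner-vs-outer group report.  Any stage failure raises with
    the stage name; results are written to ``config.out_dir`` when set.
    """
    truth = None
    stage = "acquire"
    try:
        if config.phantom is not None:
            phantom = generate_embryo_phantom(config.phantom)
            img = phantom.image
            truth = phantom.truth_table
        elif config.input_volume is not None:
            from .io_formats import read_volume

            img = read_volume(config.input_volume, spacing_override=config.spacing_override)
            phantom = None
        else:
            raise ValueError("config needs either a phantom spec or an input volume")

        stage = "segmentation"
        if config.use_truth_masks:
            if phantom is None:
                raise ValueError("use_truth_masks requires a phantom input")
            cells, nuclei = phantom.truth_cells, phantom.truth_nuclei
        else:
            nuclei = segment_nuclei(img, config.dapi_channel, config.nucleus_params)
            cells = segment_cells(img, config.membrane_channel, nuclei)

        stage = "quantify/geometry"
        records, geometry = analyze_embryo(img, cells, nuclei, config)

        stage = "report"
        report = _group_report(records, config.group_metric)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    result = PipelineResult(
        records=records, geometry=geometry, report=report, cells=cells, nuclei=nuclei,
        truth_table=truth,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records_csv(records, out / "records.csv")
        write_records_csv(geometry, out / "geometry.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        if truth is not None:
            write_records_csv(truth, out / "truth_table.csv")
        if config.write_volumes:
            write_volume(img, out / "volume.ome.tif")
            write_labels(cells, out / "cells.ome.tif")
            write_labels(nuclei, out / "nuclei.ome.tif")
        write_provenance(
            out / "provenance.json",
            config=dataclasses.asdict(config),
            software_version=__version__,
            seed=config.seed,
        )
    return result
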