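"""End-to-end orchestration: config, single-cell and cluster workflows.

``run_single_cell`` chains the full quantitation path for one mitochondria
stack: isotropic resampling, tubular enhancement, adaptive segmentation,
skeletonization, graph extraction and network metrics, writing the binary
mask, the skeleton (VTK) and a metrics CSV row.  ``run_cluster`` first
segments cells from a membrane channel, extracts each cell's mitochondria
with background-noise injection, then runs the single-cell path per cell and
joins the 3D cell morphometry columns.

Every run writes the resolved configuration and a log beside its outputs,
and all stochastic stages (noise injection, phantoms) are seed-mandatory, so
a run can be replayed byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cells import (
    CellLabels,
    NoiseModel,
    close_labels,
    estimate_background_noise,
    extract_cell_stack,
    measure_cells,
    segment_cells,
    smooth_membrane,
)
from .io import ImageStack, VoxelSpacing, resample_isotropic, write_stack
from .metrics import classify_phenotype, compute_metrics
from .segmentation import BinaryMask, ScaleSet, enhance_tubular, segment_mitochondria, suggest_floor
from .skeleton import build_graph, export_skeleton, merge_close_junctions, prune_spurs, skeletonize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_single_cell", "run_cluster", "METRIC_COLUMNS"]

METRIC_COLUMNS = [
    "sample_id",
    "cell_id",
    "total_length_um",
    "n_components",
    "n_nodes",
    "n_edges",
    "free_ends",
    "junction3",
    "junction4",
    "avg_edge_length_um",
    "avg_degree",
    "phi",
    "conn_score",
    "phenotype",
]


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; validated on construction."""

    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    mito_channel: int | None = None
    membrane_channel: int | None = None
    scales: ScaleSet = field(default_factory=ScaleSet)
    adaptive_block: int = 10
    global_floor: float | None = None  # None -> noise-adaptive
    min_component_voxels: int = 5
    min_component_um3: float = 0.15
    close_radius: int = 2
    min_spur_um: float = 0.5
    merge_junction_um: float = 0.3
    noise_mean: float | None = None  # None -> estimate from background
    noise_sd: float | None = None
    score_formula: str = "phi_degree_length"
    phenotype_threshold: float = 3.0
    seed: int = 0
    out_dir: str = "mitoquant_out"

    def __post_init__(self) -> None:
        if self.adaptive_block < 2:
            raise ValueError("adaptive_block must be >= 2")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.global_floor is not None and not 0 <= self.global_floor <= 1:
            raise ValueError("global_floor must be in [0, 1]")
        if self.phenotype_threshold <= 0:
            raise ValueError("phenotype_threshold must be > 0")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spacing"] = {"dx": self.spacing.dx, "dy": self.spacing.dy, "dz": self.spacing.dz}
        d["scales"] = {
            "min_scale": self.scales.min_scale,
            "max_scale": self.scales.max_scale,
            "n_scales": self.scales.n_scales,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "spacing" in d:
            d["spacing"] = VoxelSpacing(**d["spacing"])
        if "scales" in d:
            d["scales"] = ScaleSet(**d["scales"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def write_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _prepare_out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_yaml(out / "config.resolved.yaml")
    return out


def _metrics_row(sample_id: str, cell_id, m, call) -> dict:
    row = {"sample_id": sample_id, "cell_id": cell_id}
    row.update(m.to_row())
    row["phenotype"] = call.label if call is not None else ""
    return row


def run_single_cell(
    config: PipelineConfig,
    stack: ImageStack,
    sample_id: str = "sample",
    cell_id: int | str = 1,
    write_artifacts: bool = True,
) -> tuple[dict, "BinaryMask"]:
    """Full single-cell quantitation; returns (metrics row, binary mask).

    An empty segmentation is not fatal: it yields a metrics row of zeros
    with a warning, mirroring how an over-bleached or empty crop should be
    handled in a batch.
    """
    out = _prepare_out(config) if write_artifacts else None
    iso = resample_isotropic(stack)
    enhanced = enhance_tubular(iso, config.scales)
    floor = config.global_floor
    if floor is None:
        # noise must be estimated before isotropic resampling correlates it
        floor = suggest_floor(stack)
        logger.info("%s/%s: noise-adaptive response floor %.3f", sample_id, cell_id, floor)
    mask = segment_mitochondria(
        enhanced,
        adaptive_block=config.adaptive_block,
        global_floor=floor,
        min_component_voxels=config.min_component_voxels,
        min_component_um3=config.min_component_um3,
    )
    logger.info(
        "%s/%s: segmented %d voxels from %s grid", sample_id, cell_id, mask.n_voxels, mask.grid.shape
    )
    skel = skeletonize(mask)
    graph = build_graph(skel)
    if config.min_spur_um > 0:
        graph = prune_spurs(graph, config.min_spur_um)
    if config.merge_junction_um > 0:
        graph = merge_close_junctions(graph, config.merge_junction_um)
    m = compute_metrics(graph, score_formula=config.score_formula)
    call = None
    if m.n_edges == 0:
        logger.warning("%s/%s: empty segmentation; metrics row of zeros", sample_id, cell_id)
    else:
        call = classify_phenotype(m, threshold=config.phenotype_threshold)
    row = _metrics_row(sample_id, cell_id, m, call)
    if write_artifacts:
        write_stack(
            ImageStack(mask.grid.astype(np.uint8) * 255, mask.spacing, "mask"),
            out / f"{sample_id}_{cell_id}_mask.tif",
        )
        export_skeleton(graph, out / f"{sample_id}_{cell_id}_skeleton.vtk")
        (out / f"{sample_id}_{cell_id}_graph.json").write_text(
            json.dumps(graph.to_json_dict())
        )
        pd.DataFrame([row], columns=METRIC_COLUMNS).to_csv(
            out / f"{sample_id}_{cell_id}_metrics.csv", index=False, float_format="%.6f"
        )
    return row, mask


def run_cluster(
    config: PipelineConfig,
    mito: ImageStack,
    membrane: ImageStack | None,
    seeds: list[tuple[int, int, int]],
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Cluster workflow: segment cells, mask + noise-inject, analyse per cell.

    Returns one metrics row per cell with cell morphometry columns joined
    (volume, Feret diameter, centroid).  The fraction of segmented
    mitochondrial signal falling outside all cell masks is logged.
    """
    if membrane is None:
        raise ValueError("cluster analysis requires a membrane channel")
    if not seeds:
        raise ValueError("cluster analysis requires at least one cell seed")
    out = _prepare_out(config)
    smoothed = smooth_membrane(membrane)
    labels = close_labels(segment_cells(smoothed, seeds), radius=config.close_radius)
    write_stack(
        ImageStack(labels.grid.astype(np.uint16), labels.spacing, "cell_labels"),
        out / f"{sample_id}_cells.tif",
    )
    morph = {c.cell_id: c for c in measure_cells(labels)}

    if config.noise_mean is None or config.noise_sd is None:
        noise0 = estimate_background_noise(mito, seed=config.seed)
        noise_mean = config.noise_mean if config.noise_mean is not None else noise0.mean
        noise_sd = config.noise_sd if config.noise_sd is not None else noise0.sd
    else:
        noise_mean, noise_sd = config.noise_mean, config.noise_sd

    # how much signal is assigned to no cell (diagnostic for bad cell masks)
    fg = mito.voxels > np.percentile(mito.voxels, 99)
    unassigned = float((fg & (labels.grid == 0)).sum() / max(1, fg.sum()))
    logger.info("%s: %.1f%% of bright mitochondrial signal outside all cell masks",
                sample_id, 100 * unassigned)

    rows = []
    for cell_id in labels.ids:
        noise = NoiseModel(mean=noise_mean, sd=noise_sd, seed=config.seed + cell_id)
        cell_stack = extract_cell_stack(mito, labels, cell_id, noise)
        row, _ = run_single_cell(
            config, cell_stack, sample_id=sample_id, cell_id=cell_id, write_artifacts=True
        )
        c = morph[cell_id]
        row.update(
            {
                "volume_um3": c.volume_um3,
                "feret_um": c.feret_um,
                "centroid_x_um": c.centroid_um[0],
                "centroid_y_um": c.centroid_um[1],
                "centroid_z_um": c.centroid_um[2],
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / f"{sample_id}_cluster_metrics.csv", index=False, float_format="%.6f")
    return table
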