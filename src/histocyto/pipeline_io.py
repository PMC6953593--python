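"""End-to-end orchestration, result bundles, QC overlays, and the CLI.

The pipeline runs load/generate -> segment -> phenotype -> spatial
quantification -> polarization scoring, flushing one CSV per stage, and
records a JSON manifest (config, seed, package versions) so any bundle can
be reproduced bit-identically. Quantification never depends on QC
rendering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import click
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import MultiChannelImage, RegionOfInterest, rois_from_geojson
from .phenotyping import (
    CellTable,
    RoundnessCutoffs,
    assign_phenotypes,
    classify_roundness,
)
from .polarization import ScoreCutoffs, classify_polarization, score_scene
from .segmentation import (
    SegmentationConfig,
    filter_objects,
    identify_primary_objects,
    identify_secondary_objects,
    object_positive_fraction,
)
from .spatial_quant import (
    ProximityConfig,
    count_objects_in_roi,
    mean_intensity_normalized,
    positive_pixel_area_fraction,
    proximity_bands,
)
from .synthetic_scenes import GroundTruth, SceneConfig, generate_scene, write_scene

log = logging.getLogger("histocyto")

__all__ = ["PipelineConfig", "ResultBundle", "PipelineError", "run_pipeline", "render_qc_overlay", "cli"]

#: Channels segmented as primary objects, with their default diameter gates (um).
PRIMARY_CHANNELS = {
    "DAPI": (3.1, 12.5),
    "CX3CR1": (3.0, 20.0),
    "F4/80": (3.0, 20.0),
    "Emcn": (3.0, 1000.0),  # tubes and merged networks can be very large
}
#: A secondary object counts as marker positive when at least this fraction
#: of its pixels clears the channel threshold.
SECONDARY_POSITIVE_FRAC = 0.5
#: Channels segmented as secondary objects seeded by nuclei (densely packed).
SECONDARY_CHANNELS = ("Gr1",)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """Full run configuration: exactly one of a synthetic scene or an input
    image (+ ROI file) is set."""

    scene: Optional[SceneConfig] = None
    image_path: Optional[str] = None
    roi_path: Optional[str] = None
    segmentation: dict[str, SegmentationConfig] = Field(default_factory=dict)
    phenotype_channels: dict[str, str] = Field(
        default_factory=lambda: {"cx3cr1": "CX3CR1", "f480": "F4/80", "gr1": "Gr1", "nuclei": "DAPI"}
    )
    vessel_channel: str = "CD31"
    proximity: ProximityConfig = Field(default_factory=ProximityConfig)
    min_overlap_frac: float = 0.0
    roundness: RoundnessCutoffs = Field(default=RoundnessCutoffs())
    score_cutoffs: ScoreCutoffs = Field(default=ScoreCutoffs())
    polarization_mode: str = "sum"
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _one_input(self):
        if (self.scene is None) == (self.image_path is None):
            raise ValueError("set exactly one of scene / image_path")
        return self

    def seg_config(self, channel: str) -> SegmentationConfig:
        if channel in self.segmentation:
            return self.segmentation[channel]
        rng = PRIMARY_CHANNELS.get(channel, (3.0, 20.0))
        return SegmentationConfig(object_diameter_range_um=rng)


@dataclass
class ResultBundle:
    """Paths and in-memory tables of one pipeline run."""

    out_dir: Path
    cells: CellTable
    proximity: pd.DataFrame
    roi_quant: pd.DataFrame
    polarization: pd.DataFrame
    manifest: dict
    label_maps: dict[str, np.ndarray]
    image: MultiChannelImage
    rois: dict[str, RegionOfInterest]
    truth: Optional[GroundTruth] = None

    @property
    def paths(self) -> dict[str, Path]:
        return {
            "cells": self.out_dir / "cells.csv",
            "proximity": self.out_dir / "proximity.csv",
            "roi_quant": self.out_dir / "roi_quant.csv",
            "polarization": self.out_dir / "polarization.csv",
            "manifest": self.out_dir / "manifest.json",
        }


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute all stages in order and write the result bundle.

    Deterministic given (config, seed): re-running with the same manifest
    reproduces every table byte-identically.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: load or generate ---------------------------------------
    truth: Optional[GroundTruth] = None
    try:
        if config.scene is not None:
            scene_cfg = config.scene.model_copy(update={"seed": config.seed})
            image, truth = generate_scene(scene_cfg)
            rois = dict(truth.rois)
            log.info("generated scene: %d cells, %d vessels", len(truth.cells), len(truth.vessels))
        else:
            image = MultiChannelImage.from_tiff(config.image_path)
            rois = rois_from_geojson(config.roi_path) if config.roi_path else {}
            log.info("loaded image %s with channels %s", config.image_path, image.channel_names)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", str(e)) from e

    needed = set(config.phenotype_channels.values()) | {config.vessel_channel}
    missing = needed - set(image.channel_names)
    if missing:
        raise PipelineError("load", f"unknown channel(s) {sorted(missing)} in config")

    # -- stage 2: segmentation -------------------------------------------
    s = image.pixel_size_um
    labels: dict[str, np.ndarray] = {}
    try:
        ch = config.phenotype_channels
        labels["nuclei"] = identify_primary_objects(
            image[ch["nuclei"]], config.seg_config(ch["nuclei"]), s
        )
        for key in ("cx3cr1", "f480"):
            labels[key] = identify_primary_objects(
                image[ch[key]], config.seg_config(ch[key]), s
            )
        # secondary objects exist for every seed; refine by intensity so only
        # genuinely positive objects remain. Positivity is judged over the
        # seed (nucleus) footprint — the grown territory is selected by
        # positivity and would bias the fraction upward.
        gr1_all = identify_secondary_objects(
            image[ch["gr1"]], labels["nuclei"], config.seg_config(ch["gr1"]), s
        )
        pos_frac = object_positive_fraction(
            labels["nuclei"], image[ch["gr1"]], config.seg_config(ch["gr1"]), s
        )
        labels["gr1"] = filter_objects(
            gr1_all,
            pos_frac.to_frame(),
            {"positive_frac": (SECONDARY_POSITIVE_FRAC, None)},
        )
        labels["emcn"] = identify_primary_objects(
            image["Emcn"],
            config.segmentation.get(
                "Emcn",
                SegmentationConfig(
                    object_diameter_range_um=PRIMARY_CHANNELS["Emcn"],
                    adaptive_window_um=1100.0,  # > the size gate; one window
                    declump=False,
                    remove_border_objects=False,
                ),
            ),
            s,
        ) if "Emcn" in image.channel_names else np.zeros(image.shape, dtype=np.int32)
        for key, lm in labels.items():
            log.info("segmentation[%s]: %d objects", key, int(lm.max()))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("segment", str(e)) from e

    # -- stage 3: phenotyping --------------------------------------------
    try:
        cells = assign_phenotypes(
            labels["cx3cr1"],
            labels["f480"],
            labels["gr1"],
            labels["nuclei"],
            pixel_size_um=s,
            min_overlap_frac=config.min_overlap_frac,
            image=image,
        )
        if len(cells):
            cells.table["roundness"] = classify_roundness(cells.table, config.roundness)
        for name, roi in rois.items():
            if len(cells):
                poly = roi.polygon
                from shapely.geometry import Point

                cells.table[f"in_{name}"] = [
                    poly.covers(Point(r["centroid_x_px"], r["centroid_y_px"]))
                    for _, r in cells.table.iterrows()
                ]
        log.info("phenotyping: %d cells (DAPI-gated)", len(cells))
        cells.to_csv(out_dir / "cells.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("phenotype", str(e)) from e

    # -- stage 4: spatial quantification ---------------------------------
    try:
        quant_rows = []
        prox_frames = []
        emcn_mask = labels["emcn"] > 0
        for name, roi in rois.items():
            counts = count_objects_in_roi(cells, roi)
            for ch_name in image.channel_names:
                quant_rows.append(
                    {
                        "roi": name,
                        "channel": ch_name,
                        "measure": "mean_intensity_normalized",
                        "value": mean_intensity_normalized(image[ch_name], [roi])[name],
                    }
                )
                quant_rows.append(
                    {
                        "roi": name,
                        "channel": ch_name,
                        "measure": "positive_pixel_fraction",
                        "value": positive_pixel_area_fraction(
                            image[ch_name], roi, pixel_size_um=s
                        ),
                    }
                )
            for pheno, n in sorted(counts.items()):
                quant_rows.append(
                    {"roi": name, "channel": pheno, "measure": "object_count", "value": n}
                )
            if emcn_mask.any() and len(cells):
                prox_frames.append(proximity_bands(cells, emcn_mask, config.proximity, roi))
        roi_quant = pd.DataFrame(quant_rows, columns=["roi", "channel", "measure", "value"])
        proximity = (
            pd.concat(prox_frames, ignore_index=True)
            if prox_frames
            else pd.DataFrame(
                columns=["roi", "phenotype", "n_total", "n_direct", "n_intermediate",
                         "n_distant", "frac_direct", "frac_intermediate", "frac_distant"]
            )
        )
        roi_quant.to_csv(out_dir / "roi_quant.csv", index=False)
        proximity.to_csv(out_dir / "proximity.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("spatial", str(e)) from e

    # -- stage 5: polarization -------------------------------------------
    try:
        needed_rois = {"proximal_adjacent", "distal_adjacent", "homeostatic_control"}
        if needed_rois <= set(rois):
            card = score_scene(
                image.channels,
                rois,
                s,
                sample_id=f"run-{config.seed}",
                vessel_channel=config.vessel_channel,
                cutoffs=config.score_cutoffs,
            )
            cls = classify_polarization(card, mode=config.polarization_mode)
            pol = pd.DataFrame(card.to_records())
            pol["classification"] = cls
            log.info("polarization: %s", cls)
        else:
            pol = pd.DataFrame(columns=["sample", "day", "channel", "side", "score", "classification"])
        pol.to_csv(out_dir / "polarization.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("polarize", str(e)) from e

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "stage_counts": {k: int(v.max()) for k, v in labels.items()} | {"cells": len(cells)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return ResultBundle(
        out_dir=out_dir,
        cells=cells,
        proximity=proximity,
        roi_quant=roi_quant,
        polarization=pol,
        manifest=manifest,
        label_maps=labels,
        image=image,
        rois=rois,
        truth=truth,
    )


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, skimage  # noqa: PLC0415

    import histocyto

    return {
        "histocyto": getattr(histocyto, "__version__", "0"),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
    }


# ---------------------------------------------------------------------------
# QC overlay
# ---------------------------------------------------------------------------


def render_qc_overlay(
    image: MultiChannelImage,
    labels: Optional[np.ndarray] = None,
    cells: Optional[CellTable] = None,
    rois: Optional[dict[str, RegionOfInterest]] = None,
    path: Optional[str | Path] = None,
    background_channel: str = "DAPI",
) -> np.ndarray:
    """Composite raster: background channel, object outlines, phenotype
    colour coding, ROI polygons. Pure reporting; returns an RGB array."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.measure import find_contours

    h, w = image.shape
    fig, ax = plt.subplots(figsize=(w / 100, h / 100), dpi=100)
    ax.imshow(image[background_channel], cmap="gray", interpolation="nearest")
    lab = labels if labels is not None else (cells.labels if cells is not None else None)
    if lab is not None and lab.max() > 0:
        palette = plt.get_cmap("tab10")
        phenos = (
            {cid: p for cid, p in cells.table["phenotype"].items()} if cells is not None else {}
        )
        pheno_names = sorted(set(phenos.values()))
        for lid in range(1, int(lab.max()) + 1):
            m = lab == lid
            if not m.any():
                continue
            color = palette(pheno_names.index(phenos[lid]) % 10) if lid in phenos else "yellow"
            for contour in find_contours(m.astype(float), 0.5):
                ax.plot(contour[:, 1], contour[:, 0], color=color, linewidth=0.8)
    for roi in (rois or {}).values():
        verts = np.vstack([roi.vertices, roi.vertices[:1]])
        ax.plot(verts[:, 0], verts[:, 1], color="cyan", linewidth=1.0)
        ax.text(*roi.vertices[0], roi.name, color="cyan", fontsize=6)
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(h - 0.5, -0.5)
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.canvas.draw()
    rgba = np.asarray(fig.canvas.buffer_rgba())
    rgb = rgba[..., :3].copy()
    if path is not None:
        fig.savefig(path, dpi=100)
    plt.close(fig)
    return rgb


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _load_config(path: str, seed: Optional[int], out: Optional[str]) -> PipelineConfig:
    text = Path(path).read_text()
    data = json.loads(text)
    cfg = PipelineConfig.model_validate(data)
    updates = {}
    if seed is not None:
        updates["seed"] = seed
    if out is not None:
        updates["out_dir"] = out
    return cfg.model_copy(update=updates) if updates else cfg


@click.group()
def cli() -> None:
    """Histocytometric quantification of multi-channel fluorescence images."""


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="scene")
def simulate(config_path, seed, out):
    """Generate a synthetic scene (TIFF + manifest + cell CSV + ROI GeoJSON)."""
    scfg = (
        SceneConfig.model_validate(json.loads(Path(config_path).read_text()))
        if config_path
        else SceneConfig()
    )
    scfg = scfg.model_copy(update={"seed": seed})
    image, truth = generate_scene(scfg)
    paths = write_scene(image, truth, out)
    click.echo(f"wrote {paths['image']} ({len(truth.cells)} cells, {len(truth.vessels)} vessels)")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def run(config_path, seed, out):
    """Run the full pipeline from a JSON PipelineConfig."""
    bundle = run_pipeline(_load_config(config_path, seed, out))
    click.echo(f"wrote bundle to {bundle.out_dir} ({len(bundle.cells)} cells)")


@cli.command()
@click.option("--image", "image_path", type=click.Path(exists=True), required=True)
@click.option("--channel", required=True)
@click.option("--out", type=click.Path(), default="labels.tif")
@click.option("--diameter-range", nargs=2, type=float, default=(3.1, 12.5))
def segment(image_path, channel, out, diameter_range):
    """Segment one channel of a multi-page TIFF into primary objects."""
    import tifffile

    image = MultiChannelImage.from_tiff(image_path)
    cfg = SegmentationConfig(object_diameter_range_um=tuple(diameter_range))
    lab = identify_primary_objects(image[channel], cfg, image.pixel_size_um)
    tifffile.imwrite(out, lab.astype(np.int32))
    click.echo(f"{int(lab.max())} objects -> {out}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def phenotype(config_path, seed, out):
    """Run through the phenotyping stage and write cells.csv."""
    bundle = run_pipeline(_load_config(config_path, seed, out))
    click.echo(f"{len(bundle.cells)} cells -> {bundle.paths['cells']}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def quantify(config_path, seed, out):
    """Run the pipeline and report the ROI quantification table."""
    bundle = run_pipeline(_load_config(config_path, seed, out))
    click.echo(bundle.roi_quant.to_string(index=False))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def polarize(config_path, seed, out):
    """Run the pipeline and report the polarization scorecard."""
    bundle = run_pipeline(_load_config(config_path, seed, out))
    click.echo(bundle.polarization.to_string(index=False))


if __name__ == "__main__":
    cli()
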