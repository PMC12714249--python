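"""End-to-end orchestration of the habitat-classification pipeline.

Stages: synthetic inputs -> terrain attributes -> SST compositing ->
predictor stack + collinearity screen -> Monte-Carlo random forest ->
vote-threshold confidence map. Each stage is a thin call into the stage
module; this file owns ordering, logging and file layout only.

On-disk layout under an output directory::

    config.yaml              resolved configuration (reproduces the run)
    depth.asc                fine-resolution bathymetry
    scenes/scene_NN.asc      thermal scenes (Kelvin) + scene_NN.qa.asc
    scenes/manifest.csv      scene file paths and acquisition dates
    truth.csv                ground-truth table (drop_id,row,col,class)
    predictors/<name>.asc    screened coarse predictor layers + depth_coarse
    collinearity.csv/.json   screened-pair report
    metrics/accuracy.csv     per-simulation train/validation accuracy
    metrics/per_class.csv    mean per-class precision/recall/F1
    metrics/importance.csv   mean per-class and model-wide MDA, ranked
    map/confidence.asc       nine-category confidence map
    map/legend.json          category code table
    map/cover.csv            percent cover by class and tier
    manifest.json            seeds, parameters, stage tallies
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import habmap, rfmc, stack as stack_mod, synthgrid, terrain, thermal
from .config import PipelineConfig
from .raster import Raster, read_ascii_grid, write_ascii_grid

logger = logging.getLogger("benthicmap")

__all__ = ["PipelineResult", "build_predictors", "run_pipeline",
           "write_synthetic_inputs", "write_outputs"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    depth: Raster
    depth_coarse: Raster
    collection: thermal.ThermalCollection
    sst: thermal.SSTStats
    n_scenes_kept: int
    full_stack: stack_mod.PredictorStack
    screened: stack_mod.PredictorStack
    screen_report: stack_mod.CollinearityReport
    truth: pd.DataFrame
    table: pd.DataFrame
    results: list[rfmc.SimulationResult]
    summary: rfmc.EnsembleSummary
    votes: habmap.VoteRaster
    confidence: habmap.ConfidenceMap
    cover: pd.DataFrame


def coarse_terrain(
    depth: Raster, params: terrain.TerrainParams, coarse_cell_size: float
) -> tuple[dict[str, terrain.TerrainLayer], Raster]:
    """Fine-resolution terrain attributes aggregated to analysis scale."""
    fine_layers = terrain.compute_all_terrain(depth, params)
    coarse: dict[str, terrain.TerrainLayer] = {}
    for name, layer in fine_layers.items():
        if name == "geomorphon":
            continue  # the class raster itself is not a predictor
        categorical = name in stack_mod.ONEHOT_ORDER
        coarse[name] = terrain.aggregate_to_coarse(
            layer, coarse_cell_size, categorical=categorical
        )
    depth_coarse = terrain.aggregate_to_coarse(depth, coarse_cell_size)
    return coarse, depth_coarse


def build_predictors(
    config: PipelineConfig,
    depth: Raster,
    collection: thermal.ThermalCollection,
):
    """Terrain + SST -> screened predictor stack."""
    logger.info("terrain: computing attributes on %sx%s grid", *depth.shape)
    coarse, depth_coarse = coarse_terrain(
        depth, config.terrain, config.synth.coarse_cell_size
    )
    logger.info("thermal: compositing %d scenes", len(collection.scenes))
    sst, n_kept = thermal.composite_sst(
        collection,
        max_cloud=config.thermal.max_cloud,
        min_obs=config.thermal.min_obs,
    )
    logger.info("thermal: %d scenes retained after cloud rejection", n_kept)
    full = stack_mod.build_stack(
        coarse, sst, depth_coarse,
        aoi_mask=collection.aoi_mask,
        min_depth=config.stack.min_depth,
    )
    screened, report = stack_mod.collinearity_screen(
        full,
        n_cells=config.stack.n_cells,
        threshold=config.stack.threshold,
        priority=config.stack.priority,
        seed=config.seed,
    )
    logger.info(
        "stack: %d layers kept of %d (dropped: %s)",
        len(screened.names), len(full.names),
        [d for d, _ in report.dropped] or "none",
    )
    return depth_coarse, sst, n_kept, full, screened, report


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute every stage on a synthetic study area."""
    config = config or PipelineConfig()
    logger.info("synth: generating study area (seed=%d)", config.seed)
    depth = synthgrid.generate_bathymetry(config.synth)
    collection = synthgrid.generate_thermal_collection(config.synth, depth)

    depth_coarse, sst, n_kept, full, screened, report = build_predictors(
        config, depth, collection
    )

    truth = synthgrid.generate_ground_truth(config.synth, full)
    logger.info(
        "truth: %d observations from %d drops (%s)",
        len(truth), truth["drop_id"].nunique(),
        truth["class"].value_counts().to_dict(),
    )
    table = rfmc.extract_training_table(screened, truth)

    logger.info("rfmc: %d simulations x %d trees", config.mc.n_sim,
                config.rf.ntree)
    results = rfmc.run_monte_carlo(table, config.rf, config.mc)
    summary = rfmc.summarize_ensemble(results)
    logger.info(
        "rfmc: train %.3f / validation %.3f (gap %+.3f)",
        summary.mean_train_accuracy, summary.mean_validation_accuracy,
        summary.overfit_gap,
    )

    votes = habmap.classify_stack(screened, results)
    confidence = habmap.threshold_map(
        votes,
        high=config.map.high,
        low=config.map.low,
        depth_coarse=depth_coarse,
        max_depth=config.map.max_depth,
    )
    cover = habmap.cover_table(confidence)

    return PipelineResult(
        config=config, depth=depth, depth_coarse=depth_coarse,
        collection=collection, sst=sst, n_scenes_kept=n_kept,
        full_stack=full, screened=screened, screen_report=report,
        truth=truth, table=table, results=results, summary=summary,
        votes=votes, confidence=confidence, cover=cover,
    )


# ---------------------------------------------------------------------------
# File plumbing


def write_synthetic_inputs(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate and write the synthetic fixture set (bathymetry, scenes,
    ground truth, config)."""
    out = Path(out_dir)
    (out / "scenes").mkdir(parents=True, exist_ok=True)

    depth = synthgrid.generate_bathymetry(config.synth)
    write_ascii_grid(depth, out / "depth.asc")

    collection = synthgrid.generate_thermal_collection(config.synth, depth)
    manifest = []
    for i, scene in enumerate(collection.scenes):
        tpath = out / "scenes" / f"scene_{i:02d}.asc"
        qpath = out / "scenes" / f"scene_{i:02d}.qa.asc"
        write_ascii_grid(scene.temperature, tpath)
        write_ascii_grid(
            Raster(scene.qa.astype(float), scene.temperature.cell_size), qpath
        )
        manifest.append(
            {"path": tpath.name, "qa_path": qpath.name,
             "date": scene.date.isoformat() if scene.date else ""}
        )
    pd.DataFrame(manifest).to_csv(out / "scenes" / "manifest.csv", index=False)

    _, _, _, full, _, _ = build_predictors(config, depth, collection)
    truth = synthgrid.generate_ground_truth(config.synth, full)
    truth.to_csv(out / "truth.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return out


def read_scenes(scene_dir: str | Path) -> thermal.ThermalCollection:
    """Load a scene collection from a manifest directory."""
    scene_dir = Path(scene_dir)
    manifest = pd.read_csv(scene_dir / "manifest.csv")
    scenes = []
    for rec in manifest.itertuples():
        temp = read_ascii_grid(scene_dir / rec.path)
        qa = read_ascii_grid(scene_dir / rec.qa_path).values.astype(int)
        acq = date.fromisoformat(rec.date) if isinstance(rec.date, str) and rec.date else None
        scenes.append(thermal.ThermalScene(temp, qa, date=acq))
    return thermal.ThermalCollection(scenes=scenes)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write every declared pipeline output under ``out_dir``."""
    out = Path(out_dir)
    for sub in ("predictors", "metrics", "map"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    result.config.to_yaml(out / "config.yaml")
    result.truth.to_csv(out / "truth.csv", index=False)
    result.table.to_csv(out / "metrics" / "training_table.csv", index=False)

    for name, layer in result.screened.layers.items():
        write_ascii_grid(layer, out / "predictors" / f"{name}.asc")
    write_ascii_grid(result.depth_coarse, out / "predictors" / "depth_coarse.asc")

    pd.DataFrame(
        result.screen_report.pairs, columns=["layer_a", "layer_b", "r"]
    ).to_csv(out / "collinearity.csv", index=False)
    (out / "collinearity.json").write_text(json.dumps(
        {
            "sampled_cell_count": result.screen_report.sampled_cell_count,
            "dropped": dict(result.screen_report.dropped),
        },
        indent=2,
    ))

    acc = pd.DataFrame(
        {
            "sim_id": [r.sim_id for r in result.results],
            "train_accuracy": [r.train_accuracy for r in result.results],
            "validation_accuracy": [r.validation_accuracy for r in result.results],
        }
    )
    acc.to_csv(out / "metrics" / "accuracy.csv", index=False)
    result.summary.per_class.to_csv(out / "metrics" / "per_class.csv")
    result.summary.importance.to_csv(out / "metrics" / "importance.csv")

    write_ascii_grid(result.confidence.codes, out / "map" / "confidence.asc")
    (out / "map" / "legend.json").write_text(
        json.dumps({str(k): v for k, v in result.confidence.categories.items()},
                   indent=2)
    )
    result.cover.to_csv(out / "map" / "cover.csv")

    manifest = {
        "seed": result.config.seed,
        "n_scenes_generated": len(result.collection.scenes),
        "n_scenes_kept": result.n_scenes_kept,
        "n_observations": int(len(result.table)),
        "n_predictors": len(result.screened.names),
        "n_sim": result.summary.n_sim,
        "rf": dataclasses.asdict(result.config.rf),
        "mc": dataclasses.asdict(result.config.mc),
        "mean_train_accuracy": result.summary.mean_train_accuracy,
        "mean_validation_accuracy": result.summary.mean_validation_accuracy,
        "overfit_gap": result.summary.overfit_gap,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
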