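"""End-to-end orchestration: simulate -> preprocess -> segment -> split
-> train -> select-bands -> predict, from a single configuration with
seed control and a run manifest.

A single global seed deterministically derives a per-stage seed by
hashing the stage name, so any stage can be rerun in isolation and two
runs with the same configuration produce identical metrics
(single-threaded execution).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import band_select, classify, dataset_split, preprocess, segmentation
from .cube_io import load_profile, write_cube
from .pixels import PixelTable
from .synthetic_scene import (cloth_background, default_species_models,
                              render_scene, SceneSpec)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline",
           "stage_seed"]

logger = logging.getLogger(__name__)

SEGMENTATION_METHODS = ("ndvi", "ndwi-kmeans", "kmeans", "xmeans", "lvq")
BAND_SELECT_METHODS = ("ga", "elbow", "none")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (YAML-serializable)."""

    out_dir: str = "run"
    profile: str = "vnir"
    seed: int = 0
    task: str = "multiclass"           # or "binary"
    # simulate
    scenes_per_class: int = 6
    scene_lines: int = 64
    scene_samples: int = 64
    noise_sd: float = 0.01
    stem_width: int = 2
    n_stems_per_class: int = 3
    # preprocess
    flat_field: bool = False
    white_reference: Optional[str] = None
    sg_window: int = 13
    sg_degree: int = 3
    # segment
    segmentation_method: str = "ndvi"
    ndvi_threshold: float = 0.75
    # split
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    group_by: str = "image"
    # models
    train_models: tuple[str, ...] = ("rf", "nn")
    rf_trees: int = 176
    rf_depth: int = 29
    nn_hidden: tuple[int, int] = (384, 256)
    nn_dropout: tuple[float, float] = (0.1, 0.4)
    nn_learning_rate: float = 2.1e-4
    nn_epochs: int = 100
    nn_batch_size: int = 1024
    # band selection
    band_select_method: str = "ga"
    ga_population: int = 12
    ga_generations: int = 8
    ga_mutation_rate: float = 0.05
    ga_elites: int = 2
    elbow_k_grid: tuple[int, ...] = (2, 5, 10, 20, 40, 80)
    fitness_trees: int = 50            # reduced forest for selection fitness

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        config = cls(**data)
        # YAML lists -> tuples
        for name in ("fractions", "train_models", "nn_hidden", "nn_dropout",
                     "elbow_k_grid"):
            value = getattr(config, name)
            if isinstance(value, list):
                object.__setattr__(config, name, tuple(value))
        return config

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def record(self, name: str, seconds: float, seed: Optional[int],
               outputs: list[str], **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3),
                            "seed": seed, "outputs": outputs, **info})

    def save(self, path: str | Path) -> None:
        payload = {"config": self.config, "version": self.version,
                   "stages": self.stages, "metrics": self.metrics}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed + stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def validate_config(config: RunConfig) -> list[str]:
    """Static checks only; returns a list of problems (empty when valid)."""
    problems = []
    if abs(sum(config.fractions) - 1.0) > 1e-9:
        problems.append(
            f"split fractions {config.fractions} sum to {sum(config.fractions)}, not 1")
    if config.segmentation_method not in SEGMENTATION_METHODS:
        problems.append(
            f"unknown segmentation method {config.segmentation_method!r}; "
            f"expected one of {SEGMENTATION_METHODS}")
    if config.band_select_method not in BAND_SELECT_METHODS:
        problems.append(
            f"unknown band selection method {config.band_select_method!r}")
    if config.profile not in ("vnir", "swir"):
        problems.append(f"unknown camera profile {config.profile!r}")
    if config.task not in ("multiclass", "binary"):
        problems.append(f"unknown task {config.task!r}")
    if config.flat_field and not config.white_reference:
        problems.append("flat_field calibration enabled but no white_reference given")
    if config.flat_field and config.white_reference and \
            not Path(config.white_reference).exists():
        problems.append(f"white reference {config.white_reference!r} does not exist")
    if config.scenes_per_class < 3:
        problems.append("scenes_per_class must be >= 3 to stratify the split")
    for model in config.train_models:
        if model not in ("rf", "nn"):
            problems.append(f"unknown model family {model!r}")
    return problems


def _save_pixels(table: PixelTable, path: Path) -> None:
    np.savez_compressed(path, spectra=table.spectra)
    table.meta.to_csv(path.with_suffix(".meta.csv"), index=False)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order; abort names the failing stage."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    calibration = load_profile(config.profile)

    def run_stage(name, fn):
        start = time.perf_counter()
        try:
            result = fn(stage_seed(config.seed, name))
        except Exception as exc:
            manifest.save(out / "manifest.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return result, time.perf_counter() - start

    # -- simulate -----------------------------------------------------
    def do_simulate(seed):
        models = default_species_models(config.noise_sd)
        scenes, ids = [], []
        scene_dir = out / "scenes"
        scene_dir.mkdir(exist_ok=True)
        for model in models:
            for i in range(config.scenes_per_class):
                spec = SceneSpec(
                    lines=config.scene_lines, samples=config.scene_samples,
                    calibration=calibration, classes=(model,),
                    background_model=cloth_background(config.noise_sd),
                    stem_width=config.stem_width,
                    n_stems_per_class=config.n_stems_per_class,
                    seed=seed + 1000 * models.index(model) + i)
                cube, truth = render_scene(spec)
                image_id = f"{model.name}_{i:02d}"
                write_cube(cube, scene_dir / f"{image_id}.raw")
                scenes.append((cube, truth, model.name, image_id))
                ids.append(image_id)
        return scenes

    scenes, dt = run_stage("simulate", do_simulate)
    manifest.record("simulate", dt, stage_seed(config.seed, "simulate"),
                    [str(out / "scenes")], n_scenes=len(scenes))

    # -- preprocess (smoothing; flat-field when configured) -----------
    def do_preprocess(seed):
        processed = []
        white = None
        if config.flat_field:
            from .cube_io import read_cube
            white = read_cube(config.white_reference)
        for cube, truth, species, image_id in scenes:
            if white is not None:
                cube = preprocess.flat_field_calibrate(cube, white)
            cube = preprocess.savitzky_golay_smooth(
                cube, config.sg_window, config.sg_degree)
            processed.append((cube, truth, species, image_id))
        return processed

    processed, dt = run_stage("preprocess", do_preprocess)
    manifest.record("preprocess", dt, None, [],
                    sg_window=config.sg_window, sg_degree=config.sg_degree)

    # -- segment + semi-supervised labelling --------------------------
    def do_segment(seed):
        tables = []
        n_plant = 0
        for cube, truth, species, image_id in processed:
            if config.segmentation_method == "ndvi":
                mask = segmentation.ndvi_segment(cube, config.ndvi_threshold)
            elif config.segmentation_method == "ndwi-kmeans":
                mask = segmentation.ndwi_kmeans_segment(cube, seed=seed)
            else:
                raise ValueError(
                    f"segmentation method {config.segmentation_method!r} is not "
                    "supported as a pipeline stage; use the library API")
            label = species
            if config.task == "binary" and species != "host":
                label = "parasite"
            tables.append(segmentation.label_plant_pixels(mask, cube, label, image_id))
            n_plant += mask.n_plant
        from .pixels import concat_tables
        table = concat_tables(tables)
        _save_pixels(table, out / "pixels.npz")
        return table, n_plant

    (table, n_plant), dt = run_stage("segment", do_segment)
    manifest.record("segment", dt, stage_seed(config.seed, "segment"),
                    [str(out / "pixels.npz")],
                    method=config.segmentation_method, n_plant_pixels=n_plant)

    # -- split --------------------------------------------------------
    def do_split(seed):
        assignment = dataset_split.grouped_split(
            table, config.fractions, group_by=config.group_by, seed=seed)
        assignment.save(out / "split.csv")
        tagged = assignment.tag(table, "image_id")
        return assignment, tagged

    (assignment, tagged), dt = run_stage("split", do_split)
    manifest.record("split", dt, stage_seed(config.seed, "split"),
                    [str(out / "split.csv")],
                    achieved_fractions=assignment.achieved_fractions())

    train = tagged.subset_split("train")
    val = tagged.subset_split("val")
    test = tagged.subset_split("test")

    # -- normalize (scaler anchored on the train split) ----------------
    def do_normalize(seed):
        scaler = preprocess.fit_minmax(train)
        scaler.save(out / "scaler.txt")
        return (scaler, scaler.transform(train), scaler.transform(val),
                scaler.transform(test))

    (scaler, train_n, val_n, test_n), dt = run_stage("normalize", do_normalize)
    manifest.record("normalize", dt, None, [str(out / "scaler.txt")])

    # -- train + evaluate ---------------------------------------------
    models: dict[str, object] = {}

    def do_train(seed):
        reports = {}
        if "rf" in config.train_models:
            rf_config = classify.RFConfig(n_trees=config.rf_trees,
                                          max_depth=config.rf_depth, seed=seed)
            models["rf"] = classify.train_random_forest(train_n, rf_config)
            reports["rf"] = classify.evaluate(models["rf"], test_n, tag="rf-full")
        if "nn" in config.train_models:
            nn_config = classify.NNConfig(
                hidden_sizes=config.nn_hidden, dropout_rates=config.nn_dropout,
                learning_rate=config.nn_learning_rate, epochs=config.nn_epochs,
                batch_size=config.nn_batch_size, seed=seed)
            models["nn"] = classify.train_neural_network(train_n, nn_config, val_n)
            reports["nn"] = classify.evaluate(models["nn"], test_n, tag="nn-full")
        (out / "reports.json").write_text(json.dumps(
            {k: r.to_dict() for k, r in reports.items()}, indent=2))
        return reports

    reports, dt = run_stage("train", do_train)
    manifest.record("train", dt, stage_seed(config.seed, "train"),
                    [str(out / "reports.json")])
    for name, report in reports.items():
        manifest.metrics[f"{name}_test_macro_f1"] = report.macro_f1
        manifest.metrics[f"{name}_test_accuracy"] = report.accuracy

    # -- band selection (validation only; test guarded) ----------------
    def do_select(seed):
        if config.band_select_method == "none":
            return None
        guarded = band_select.GuardedPixelTable(test_n)
        fitness_config = classify.RFConfig(
            n_trees=config.fitness_trees, max_depth=config.rf_depth, seed=seed)

        def trainer(t: PixelTable):
            return classify.train_random_forest(t, fitness_config)

        if config.band_select_method == "ga":
            ga = band_select.GAConfig(
                population_size=config.ga_population,
                mutation_rate=config.ga_mutation_rate,
                elite_count=config.ga_elites,
                max_generations=config.ga_generations, seed=seed)
            subset, trace = band_select.genetic_band_search(trainer, train_n, val_n, ga)
            trace.to_csv(out / "ga_trace.csv", index=False)
        else:
            ranking = band_select.lime_importances(
                models.get("rf") or trainer(train_n), train_n,
                n_explained=min(50, len(train_n)), n_perturbations=200,
                seed=seed, model_family="rf")
            grid = [k for k in config.elbow_k_grid if k <= train_n.n_bands]
            subset, curve = band_select.elbow_reduce(
                ranking, trainer, train_n, val_n, grid)
            curve.to_csv(out / "elbow_curve.csv", index=False)
        _, report = band_select.retrain_on_subset(subset, trainer, train_n, guarded)
        payload = {"method": subset.method, "n_bands": int(subset.bands.size),
                   "bands": subset.bands.tolist(),
                   "wavelengths_nm": calibration.centers[subset.bands].tolist(),
                   "val_macro_f1": subset.macro_f1,
                   "test_macro_f1": report.macro_f1}
        (out / "band_subset.json").write_text(json.dumps(payload, indent=2))
        return payload

    selection, dt = run_stage("select_bands", do_select)
    manifest.record("select_bands", dt, stage_seed(config.seed, "select_bands"),
                    [str(out / "band_subset.json")] if selection else [])
    if selection:
        manifest.metrics["selected_n_bands"] = selection["n_bands"]
        manifest.metrics["subset_test_macro_f1"] = selection["test_macro_f1"]

    # -- predict: classification map on a fresh scene ------------------
    def do_predict(seed):
        model = models.get("nn") or models.get("rf")
        if model is None:
            return None
        species = default_species_models(config.noise_sd)
        target = species[seed % len(species)]
        spec = SceneSpec(lines=config.scene_lines, samples=config.scene_samples,
                         calibration=calibration, classes=(target,),
                         background_model=cloth_background(config.noise_sd),
                         stem_width=config.stem_width,
                         n_stems_per_class=config.n_stems_per_class, seed=seed)
        cube, truth = render_scene(spec)
        cube = preprocess.savitzky_golay_smooth(cube, config.sg_window, config.sg_degree)
        mask = segmentation.ndvi_segment(cube, config.ndvi_threshold)
        label_map, tallies, class_names = classify.predict_map(model, cube, mask, scaler)
        rgb = classify.render_class_map(label_map, class_names)
        from PIL import Image
        Image.fromarray(rgb).save(out / "classification_map.png")
        legend = ["code,class", "0,background"] + [
            f"{i + 1},{name}" for i, name in enumerate(class_names)]
        (out / "classification_map_legend.csv").write_text("\n".join(legend) + "\n")
        truth_label = target.name if config.task == "multiclass" or \
            target.name == "host" else "parasite"
        plant = mask.mask & (truth.label_map > 0)
        if plant.any():
            codes = label_map[plant]
            correct = np.mean(codes == class_names.index(truth_label) + 1)
        else:
            correct = float("nan")
        return {"scene_species": target.name, "tallies": tallies,
                "plant_pixel_agreement": float(correct)}

    prediction, dt = run_stage("predict", do_predict)
    manifest.record("predict", dt, stage_seed(config.seed, "predict"),
                    [str(out / "classification_map.png")] if prediction else [],
                    **(prediction or {}))
    if prediction:
        manifest.metrics["map_plant_pixel_agreement"] = prediction["plant_pixel_agreement"]

    manifest.save(out / "manifest.json")
    return manifest
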