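"""End-to-end workflow: simulate -> fit -> segment -> features -> stats ->
classify -> cnn, driven by one serializable RunConfig."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cnn, features, fitting, io, segmentation, stats, synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "segment", "features", "stats", "classify", "cnn")
_DEPS = {"fit": "simulate", "segment": "fit", "features": "segment",
         "stats": "features", "classify": "features", "cnn": "segment"}


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    scene: dict = dataclasses.field(default_factory=dict)       # SceneSpec kwargs
    n_scenes: int = 2
    fit: dict = dataclasses.field(default_factory=dict)         # FitConfig kwargs
    compartment: str = "cytoplasm"
    cnn_channels: str = "nadh_all"
    cnn_train: dict = dataclasses.field(default_factory=dict)   # TrainConfig kwargs

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["stages"] = tuple(d.get("stages", STAGES))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    enabled = [s for s in STAGES if s in config.stages]
    for s in enabled:
        dep = _DEPS.get(s)
        if dep and dep not in enabled:
            raise PipelineError(
                f"stage '{s}' requires stage '{dep}'; enable it or run it first")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": json.loads(config.to_json()),
                "config_hash": config.config_hash, "seed": config.seed,
                "artifacts": {}}
    art = manifest["artifacts"]
    profiles = synth.default_profiles()
    two_groups = [profiles["glycolysis_inhibited"], profiles["oxphos_inhibited"]]

    scenes, cube_pairs, irf = [], [], synth.gaussian_irf()
    if "simulate" in enabled:
        for i in range(config.n_scenes):
            spec = synth.SceneSpec(seed=config.seed + i, **config.scene)
            scene = synth.generate_scene(spec, two_groups)
            cubes = synth.render_tcspc(scene, irf, rng_seed=config.seed + 1000 + i)
            path = out / f"scene_{i}.h5"
            io.save_scene(path, scene, cubes, irf)
            io.save_intensity_tiff(out / f"scene_{i}_nadh_intensity.tif", cubes[0])
            scenes.append(scene)
            cube_pairs.append(cubes)
            art.setdefault("scenes", []).append(str(path))

    flim_pairs = []
    if "fit" in enabled:
        fit_cfg = fitting.FitConfig(**config.fit)
        for i, cubes in enumerate(cube_pairs):
            pair = []
            for cube in cubes:
                flim = fitting.fit_image(cube, irf, fit_cfg)
                io.save_flim(out / f"fits_{i}.h5", flim)
                io.save_flim_tiff(out / f"fits_{i}_{cube.channel}.tif", flim)
                pair.append(flim)
            flim_pairs.append(tuple(pair))
            art.setdefault("fits", []).append(str(out / f"fits_{i}.h5"))

    label_sets = []
    if "segment" in enabled:
        for i, (nadh_flim, _) in enumerate(flim_pairs):
            labels = segmentation.segment_cells(nadh_flim.intensity)
            labels = segmentation.mitochondria_mask(labels, nadh_flim.intensity)
            io.save_labels(out / f"labels_{i}.tif", labels)
            label_sets.append(labels)
            art.setdefault("labels", []).append(str(out / f"labels_{i}.tif"))

    table = pd.DataFrame()
    if "features" in enabled:
        frames = []
        for i, ((nadh_flim, fad_flim), labels, scene) in enumerate(
                zip(flim_pairs, label_sets, scenes)):
            match = segmentation.match_to_truth(labels, scene.cell_ids)
            df = features.aggregate_cell_features(
                nadh_flim, fad_flim, labels, compartment=config.compartment,
                batch=f"scene{i}")
            # label detected cells by their matched truth phenotype
            det_to_true = {d: t for t, (d, _) in match["pairs"].items()}
            df["group"] = [scene.phenotypes.get(det_to_true.get(c), "unknown")
                           for c in df["cell_id"]]
            df["cell_id"] = df["cell_id"] + 10000 * i
            frames.append(df)
        table = pd.concat(frames, ignore_index=True) if frames else table
        table.to_csv(out / "features.csv", index=False)
        art["features"] = str(out / "features.csv")

    if "stats" in enabled and not table.empty:
        known = table[table["group"] != "unknown"]
        comp = stats.compare_all_features(known)
        comp.to_csv(out / "comparisons.csv", index=False)
        art["comparisons"] = str(out / "comparisons.csv")
        if len(known) >= 10:
            coords = stats.umap_embed(known, seed=config.seed)
            emb = known[["cell_id", "group"]].copy()
            emb[["umap1", "umap2"]] = coords
            emb.to_csv(out / "umap.csv", index=False)
            stats.plot_embedding(coords, known["group"], out / "umap.png")
            art["umap"] = str(out / "umap.csv")

    if "classify" in enabled:
        # image-derived tables are small; top up with phenotype-level draws
        pool = synth.sample_cell_features(
            {"glycolysis_inhibited": 400, "oxphos_inhibited": 400},
            seed=config.seed + 7)
        train, test = classify.split_train_test(pool, seed=config.seed)
        models = classify.train_models(train, seed=config.seed)
        reports = {}
        for tag, model in models.items():
            rep = classify.evaluate(model, test, model_tag=tag,
                                    cv_table=pool, seed=config.seed)
            reports[tag] = rep.to_dict()
        with open(out / "classifier_reports.json", "w") as fh:
            json.dump(reports, fh, indent=2)
        classify.feature_ranking(train, seed=config.seed).to_csv(
            out / "feature_ranking.csv", index=False)
        art["classifier_reports"] = str(out / "classifier_reports.json")

    if "cnn" in enabled:
        images, labels_arr, names = synth.sample_cell_stacks(
            {"glycolysis_inhibited": 150, "oxphos_inhibited": 150},
            seed=config.seed + 11)
        stacks = cnn.stacks_from_arrays(images, labels_arr, names,
                                        cnn.CHANNEL_SETS[config.cnn_channels])
        n_test = len(stacks) // 4
        tcfg = cnn.TrainConfig(seed=config.seed,
                               **{"learning_rate": 1e-3, "epochs": 8,
                                  **config.cnn_train})
        model, history = cnn.train_cnn(stacks[n_test:], tcfg)
        report = cnn.evaluate_cnn(model, stacks[:n_test])
        pd.DataFrame(history).to_csv(out / "cnn_history.csv", index=False)
        with open(out / "cnn_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        art["cnn_report"] = str(out / "cnn_report.json")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
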