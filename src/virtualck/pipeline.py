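"""Config-driven orchestration of the full virtual-staining pipeline.

Stages: ``simulate`` (phantom slide pair) -> ``register`` -> ``tile`` ->
``train`` -> ``infer`` -> ``score`` -> ``evaluate``.  Each stage reads its
inputs from the run directory, writes its outputs there, and records an
entry in the run manifest (inputs, outputs, parameters hash, status), so a
rerun with an identical config reproduces identical manifests for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, io, patchflow, phantoms, registration, tsr, virtual_stain

logger = logging.getLogger("virtualck")

STAGES = ("simulate", "register", "tile", "train", "infer", "score", "evaluate")


class MissingDependencyError(RuntimeError):
    """A requested stage needs an artifact an earlier stage did not produce."""


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the published operating point."""

    out_dir: str = "runs/phantom"
    seed: int = 0
    # registration
    downsample: int = 32
    region_size: int = 10240
    patch_size: int = 1024
    block_size: int = 151
    offset: float = 10.0
    min_area: int = 200
    # curation
    tile: int = 256
    white_threshold: int = 220
    white_fraction: float = 0.95
    little_dyed_threshold: int = 80
    little_dyed_fraction_limit: float = 0.05
    little_dyed_fraction: float = 0.10
    # training
    lambda1: float = 10.0
    lambda2: float = 0.9
    learning_rate: float = 0.0002
    epochs: int = 200
    batch_size: int = 1
    gen_base: int = 64
    gen_depth: int = 8
    disc_base: int = 64
    disc_layers: int = 3
    max_g_steps: int | None = None
    # scoring
    gray_threshold: int = 200
    dab_threshold: int = 80
    cutoff: float = 65.0
    # phantom simulation
    phantom_size: int = 512
    phantom_noise_sd: float = 3.0
    phantom_shift: tuple[int, int] = (0, 0)
    phantom_stroma_fraction: float = 50.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        defaults = cls()
        for key, value in data.items():
            if value != getattr(defaults, key):
                logger.warning("config override: %s = %r", key, value)
        if "phantom_shift" in data:
            data["phantom_shift"] = tuple(data["phantom_shift"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["phantom_shift"] = list(d["phantom_shift"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def params_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    stages = [s for s in STAGES if s in set(stages)]
    unknown = set(stages if isinstance(stages, set) else stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"params_hash": config.params_hash(), "seed": config.seed, "stages": {}}

    def record(stage, inputs, outputs):
        manifest["stages"][stage] = {
            "status": "completed",
            "inputs": sorted(str(p) for p in inputs),
            "outputs": sorted(str(p) for p in outputs),
        }
        logger.info("stage %s completed", stage)

    def require(stage, *paths):
        for p in paths:
            if not Path(p).exists():
                raise MissingDependencyError(f"stage '{stage}' requires missing artifact: {p}")

    he_path, ck_path = out / "he.png", out / "ck.png"
    shifts_path = out / "shifts.json"
    dataset_dir = out / "dataset"
    model_path = out / "model.npz"
    virtual_path = out / "virtual_ck.png"
    score_path = out / "score.json"
    report_path = out / "report.json"
    hotspot_path = out / "hotspots.json"
    truth_path = out / "truth.json"

    for stage in stages:
        if stage == "simulate":
            spec = phantoms.PhantomSpec(
                size=config.phantom_size,
                tumor_fraction=1.0 - config.phantom_stroma_fraction / 100.0,
                noise_sd=config.phantom_noise_sd,
                seed=config.seed,
            )
            pair = phantoms.render_phantom_pair(spec)
            he, ck, truth = phantoms.make_shifted_pair(pair, registration.ShiftVector(*config.phantom_shift))
            io.write_rgb(he, he_path)
            io.write_rgb(ck, ck_path)
            polys = phantoms._tissue_bbox_polygon(truth.tissue)
            io.write_hotspots(tsr.HotspotAnnotation([polys]), hotspot_path)
            with open(truth_path, "w") as fh:
                json.dump(
                    {
                        "stroma_fraction": truth.stroma_fraction,
                        "planted_shift": [truth.planted_shift.drow, truth.planted_shift.dcol],
                        "true_class": "dTSR-high" if truth.stroma_fraction > config.cutoff else "dTSR-low",
                    },
                    fh,
                )
            record(stage, [], [he_path, ck_path, hotspot_path, truth_path])
        elif stage == "register":
            require(stage, he_path, ck_path)
            he, ck = io.read_rgb(he_path), io.read_rgb(ck_path)
            gshift = registration.estimate_global_shift(
                he, ck, config.downsample, block_size=config.block_size,
                offset=config.offset, min_area=config.min_area,
            )
            region_size = min(
                config.region_size,
                (he.shape[0] // config.patch_size) * config.patch_size or config.patch_size,
            )
            local = registration.estimate_local_shifts(
                he, ck, gshift,
                region_size=region_size,
                patch_size=config.patch_size,
                block_size=config.block_size, offset=config.offset, min_area=config.min_area,
            )
            payload = {
                "global": [gshift.drow, gshift.dcol],
                "region_size": region_size,
                "regions": [
                    {"origin": list(o), "shift": [s.drow, s.dcol], "inliers": local.inlier_counts[o]}
                    for o, s in local.entries
                ],
            }
            with open(shifts_path, "w") as fh:
                json.dump(payload, fh, indent=1)
            record(stage, [he_path, ck_path], [shifts_path])
        elif stage == "tile":
            require(stage, he_path, ck_path, shifts_path)
            he, ck = io.read_rgb(he_path), io.read_rgb(ck_path)
            with open(shifts_path) as fh:
                shifts = json.load(fh)
            dataset_dir.mkdir(exist_ok=True)
            rows = []
            pairs = []
            region_size = shifts.get("region_size", config.region_size)
            for region in shifts["regions"]:
                (r0, c0), (dr, dc) = region["origin"], region["shift"]
                rh = min(region_size, he.shape[0] - r0)
                rw = min(region_size, he.shape[1] - c0)
                he_region = he.pixels[r0 : r0 + rh, c0 : c0 + rw]
                ck_region = registration._crop_with_fill(ck.pixels, r0 + dr, c0 + dc, rh, rw)
                pairs += patchflow.tile_pairs(he_region, ck_region, config.tile, origin=(r0, c0))
            dataset = patchflow.assemble_training_set(pairs, config.little_dyed_fraction, seed=config.seed)
            for i, p in enumerate(dataset.pairs):
                io.write_rgb(p.he, dataset_dir / f"{i:05d}_he.png")
                io.write_rgb(p.ck, dataset_dir / f"{i:05d}_ck.png")
                rows.append(f"{i:05d},{p.origin[0]},{p.origin[1]},{int(p.little_dyed)}")
            (dataset_dir / "manifest.csv").write_text(
                "index,origin_row,origin_col,little_dyed\n" + "\n".join(rows) + "\n"
            )
            record(stage, [he_path, ck_path, shifts_path], [dataset_dir / "manifest.csv"])
        elif stage == "train":
            require(stage, dataset_dir / "manifest.csv")
            idx = [line.split(",")[0] for line in (dataset_dir / "manifest.csv").read_text().splitlines()[1:]]
            pairs = [
                patchflow.PatchPair(
                    he=io.read_rgb(dataset_dir / f"{i}_he.png").pixels,
                    ck=io.read_rgb(dataset_dir / f"{i}_ck.png").pixels,
                )
                for i in idx
            ]
            cfg = virtual_stain.TrainingConfig(
                lambda1=config.lambda1, lambda2=config.lambda2,
                learning_rate=config.learning_rate, epochs=config.epochs,
                seed=config.seed, gen_base=config.gen_base, gen_depth=config.gen_depth,
                disc_base=config.disc_base, disc_layers=config.disc_layers,
                patch_size=config.tile, max_g_steps=config.max_g_steps,
            )
            state = virtual_stain.train(patchflow.PairedPatchDataset(pairs), cfg)
            virtual_stain.save_model(state, model_path)
            with open(out / "loss_log.json", "w") as fh:
                json.dump(state.loss_log, fh, indent=1)
            record(stage, [dataset_dir / "manifest.csv"], [model_path, out / "loss_log.json"])
        elif stage == "infer":
            require(stage, he_path, model_path)
            state = virtual_stain.load_model(model_path)
            he = io.read_rgb(he_path)
            stitched = virtual_stain.generate_and_stitch(he, state, tile=config.tile)
            io.write_rgb(stitched, virtual_path)
            record(stage, [he_path, model_path], [virtual_path])
        elif stage == "score":
            require(stage, he_path, model_path, hotspot_path)
            state = virtual_stain.load_model(model_path)
            he = io.read_rgb(he_path)
            hotspots = io.read_hotspots(hotspot_path)
            score = tsr.score_wsi(
                he, state, hotspots, cutoff=config.cutoff, tile=config.tile,
                gray_threshold=config.gray_threshold, dab_threshold=config.dab_threshold,
            )
            with open(score_path, "w") as fh:
                json.dump(
                    {
                        "dtsr": score.dtsr,
                        "class": score.tsr_class,
                        "hotspot_scores": score.hotspot_scores,
                        "tumor_area": score.tumor_area,
                        "stroma_area": score.stroma_area,
                    },
                    fh,
                    indent=1,
                )
            record(stage, [he_path, model_path, hotspot_path], [score_path])
        elif stage == "evaluate":
            require(stage, score_path, truth_path)
            with open(score_path) as fh:
                score = json.load(fh)
            with open(truth_path) as fh:
                truth = json.load(fh)
            table = evaluation.build_contingency(
                [truth["true_class"].replace("dTSR-", "")], [score["class"].replace("dTSR-", "")]
            )
            report = evaluation.agreement_report(table)
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=1, default=float)
            record(stage, [score_path, truth_path], [report_path])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
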