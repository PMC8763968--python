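"""End-to-end pipeline: synth -> train -> detect -> morpho -> stats.

A YAML ``PipelineConfig`` drives all stages; every stage writes its outputs
under one run directory, a manifest records the config, seeds, package
versions and output hashes, and a rerun with the same config and seed
reproduces all CSV/JSON artifacts bit-for-bit.  Any prefix of stages can be
skipped when its outputs already exist in the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from temquant import io as tio
from temquant.density_stats import (cell_profile, chi_square_2x2,
                                    ks_two_sample, summarize_groups)
from temquant.morphometry import Contour, measure_neuron
from temquant.synth import (ko_like_params, make_patch_dataset,
                            synthesize_scene, synthesize_vesicle_field,
                            wt_like_params)
from temquant.vesnet import ModelBundle, TrainConfig, train_stage

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("temquant")

STAGES = ("synth", "train", "detect", "morpho", "stats")


@dataclass
class SynthConfig:
    n_scenes_per_group: int = 4
    scene_nm_per_px: float = 20.0
    render_scenes: bool = False
    n_cells_per_group: int = 8
    field_px: int = 256
    field_nm_per_px: float = 5.0
    wt_density_per_um2: float = 20.0
    ko_density_per_um2: float = 40.0


@dataclass
class TrainSection:
    n_train_fields: int = 12
    train_field_px: int = 512
    train_density_per_um2: float = 5.0
    n_patches_stage1: int = 600
    n_patches_stage2: int = 600
    stage1: dict = field(default_factory=dict)
    stage2: dict = field(default_factory=dict)


@dataclass
class DetectConfig:
    stride_px: int = 16
    roi_threshold: float = 0.5


@dataclass
class MorphoConfig:
    threshold_um: float = 0.25
    n_samples: int = 720


@dataclass
class StatsConfig:
    eps_nm: float = 200.0
    min_pts: int = 3
    min_count: int = 3
    hull_mode: str = "all_points"


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    train: TrainSection = field(default_factory=TrainSection)
    detect: DetectConfig = field(default_factory=DetectConfig)
    morpho: MorphoConfig = field(default_factory=MorphoConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, source=str(path))

    @classmethod
    def from_dict(cls, raw: dict, source: str = "<dict>") -> "PipelineConfig":
        sections = {"synth": SynthConfig, "train": TrainSection,
                    "detect": DetectConfig, "morpho": MorphoConfig,
                    "stats": StatsConfig}
        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                known = sections[key].__dataclass_fields__
                bad = set(value) - set(known)
                if bad:
                    raise ValueError(
                        f"{source}: unknown field(s) {sorted(bad)} "
                        f"in section {key!r}")
                kwargs[key] = sections[key](**value)
            elif key in ("seed", "log_level"):
                kwargs[key] = value
            else:
                raise ValueError(f"{source}: unknown config key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synth.n_cells_per_group < 1:
            raise ValueError("synth.n_cells_per_group must be >= 1")
        if not 0 < self.detect.roi_threshold < 1:
            raise ValueError("detect.roi_threshold must be in (0, 1)")
        if self.morpho.threshold_um <= 0:
            raise ValueError("morpho.threshold_um must be positive")
        if self.stats.eps_nm <= 0 or self.stats.min_pts < 1:
            raise ValueError("stats.eps_nm/min_pts out of range")
        TrainConfig(stage=1, seed=self.seed, **self.train.stage1).resolved()
        TrainConfig(stage=2, seed=self.seed, **self.train.stage2).resolved()

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_logging(out: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers = [logging.StreamHandler()]
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)


# ---------------------------------------------------------------------------
# stages


def _stage_synth(cfg: PipelineConfig, out: Path) -> None:
    scenes_dir = out / "scenes"
    fields_dir = out / "fields"
    scenes_dir.mkdir(exist_ok=True)
    fields_dir.mkdir(exist_ok=True)
    for g, maker, density in (("WT", wt_like_params,
                               cfg.synth.wt_density_per_um2),
                              ("KO", ko_like_params,
                               cfg.synth.ko_density_per_um2)):
        for i in range(cfg.synth.n_scenes_per_group):
            seed = cfg.seed * 1000 + i + (0 if g == "WT" else 500)
            params = maker(seed=seed, nm_per_px=cfg.synth.scene_nm_per_px,
                           vesicle_density_per_um2=0.0)
            img, truth = synthesize_scene(params,
                                          render=cfg.synth.render_scenes)
            tio.write_truth(scenes_dir / f"{g}_{i:03d}.json", truth)
            if img is not None:
                tio.write_image(scenes_dir / f"{g}_{i:03d}.tiff", img)
        for i in range(cfg.synth.n_cells_per_group):
            seed = cfg.seed * 1000 + 100 + i + (0 if g == "WT" else 500)
            img, truth = synthesize_vesicle_field(
                size_px=cfg.synth.field_px,
                nm_per_px=cfg.synth.field_nm_per_px,
                density_per_um2=density, seed=seed)
            tio.write_image(fields_dir / f"{g}_{i:03d}.tiff", img)
            tio.write_truth(fields_dir / f"{g}_{i:03d}.json", truth)
    log.info("synth: %d scenes and %d fields per group",
             cfg.synth.n_scenes_per_group, cfg.synth.n_cells_per_group)


def _stage_train(cfg: PipelineConfig, out: Path) -> None:
    t = cfg.train
    fields = [synthesize_vesicle_field(size_px=t.train_field_px,
                                       density_per_um2=t.train_density_per_um2,
                                       seed=cfg.seed * 1000 + 900 + s)
              for s in range(t.n_train_fields)]
    bundle = ModelBundle()
    for stage, n in ((1, t.n_patches_stage1), (2, t.n_patches_stage2)):
        mode = "classify" if stage == 1 else "segment"
        ds = make_patch_dataset(fields, 32, n, mode, seed=cfg.seed)
        tc = TrainConfig(stage=stage, seed=cfg.seed,
                         **getattr(t, f"stage{stage}"))
        bundle = train_stage(ds, tc, bundle)
        rep = bundle.training_report[f"stage{stage}"]
        log.info("train stage %d: val accuracy %.4f after %d epochs",
                 stage, rep["validation_accuracy"], rep["n_epochs"])
    bundle.save(out / "model.bundle")


def _stage_detect(cfg: PipelineConfig, out: Path) -> None:
    bundle_path = out / "model.bundle"
    fields_dir = out / "fields"
    if not bundle_path.exists():
        raise FileNotFoundError("detect stage needs model.bundle "
                                "(run the train stage first)")
    if not fields_dir.exists():
        raise FileNotFoundError("detect stage needs fields/ "
                                "(run the synth stage first)")
    bundle = ModelBundle.load(bundle_path)
    det = bundle.detector(stride_px=cfg.detect.stride_px,
                          roi_threshold=cfg.detect.roi_threshold)
    results = {}
    for tiff in sorted(fields_dir.glob("*.tiff")):
        img = tio.read_image(tiff)
        results[tiff.stem] = det.detect(img)
    (out / "detections.json").write_text(
        json.dumps(tio.detections_to_json(results), sort_keys=True))
    log.info("detect: %d images, %d vesicles total", len(results),
             sum(len(v) for v in results.values()))


def _stage_morpho(cfg: PipelineConfig, out: Path) -> None:
    scenes_dir = out / "scenes"
    if not scenes_dir.exists():
        raise FileNotFoundError("morpho stage needs scenes/ "
                                "(run the synth stage first)")
    records = []
    for path in sorted(scenes_dir.glob("*.json")):
        truth = tio.read_truth(path)
        neuron = Contour(truth.neuron_contour, truth.nm_per_px)
        sgc = Contour(truth.sgc_inner_contour, truth.nm_per_px)
        records.append(measure_neuron(
            neuron, sgc, neuron_id=path.stem,
            threshold_um=cfg.morpho.threshold_um,
            n_samples=cfg.morpho.n_samples))
    tio.write_morphometry_csv(out / "morpho.csv", records)
    log.info("morpho: %d neurons measured", len(records))


def _stage_stats(cfg: PipelineConfig, out: Path) -> None:
    det_path = out / "detections.json"
    if not det_path.exists():
        raise FileNotFoundError("stats stage needs detections.json "
                                "(run the detect stage first)")
    detections = tio.detections_from_json(json.loads(det_path.read_text()))
    nm_per_px = cfg.synth.field_nm_per_px
    profiles = []
    for name, instances in sorted(detections.items()):
        group = name.split("_")[0]
        profiles.append(cell_profile(
            instances, cell_id=name, group=group,
            min_count=cfg.stats.min_count, eps_nm=cfg.stats.eps_nm,
            min_pts=cfg.stats.min_pts, nm_per_px=nm_per_px,
            hull_mode=cfg.stats.hull_mode))
    tio.write_profiles_csv(out / "profiles.csv", profiles)
    comparisons = []
    groups = sorted({p.group for p in profiles})
    if len(groups) == 2:
        g1, g2 = groups
        table = [[sum(p.detectable for p in profiles if p.group == g),
                  sum(not p.detectable for p in profiles if p.group == g)]
                 for g in (g1, g2)]
        if all(sum(row) for row in table) and all(sum(c) for c in zip(*table)):
            comparisons.append(chi_square_2x2(table))
        d1 = [p.density_per_um2 for p in profiles
              if p.group == g1 and p.density_per_um2 is not None]
        d2 = [p.density_per_um2 for p in profiles
              if p.group == g2 and p.density_per_um2 is not None]
        if d1 and d2:
            comparisons.append(ks_two_sample(d1, d2))
    tio.write_comparisons_csv(out / "comparisons.csv", comparisons)
    summary = summarize_groups(profiles)
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1))
    log.info("stats: %d profiles, %d comparisons (seed %d)",
             len(profiles), len(comparisons), cfg.seed)


_STAGE_FN = {"synth": _stage_synth, "train": _stage_train,
             "detect": _stage_detect, "morpho": _stage_morpho,
             "stats": _stage_stats}

_STAGE_DONE = {"synth": "fields", "train": "model.bundle",
               "detect": "detections.json", "morpho": "morpho.csv",
               "stats": "comparisons.csv"}


def run_pipeline(config: PipelineConfig, out_dir,
                 stages: tuple[str, ...] = STAGES,
                 skip_existing: bool = False) -> Path:
    """Run the pipeline stages into ``out_dir``; returns the run directory.

    With ``skip_existing`` a stage whose output artifact is already present
    is not recomputed (so any prefix can be resumed).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        if skip_existing and (out / _STAGE_DONE[stage]).exists():
            log.info("%s: outputs exist, skipped", stage)
            continue
        log.info("running stage: %s", stage)
        _STAGE_FN[stage](config, out)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {"temquant": _pkg_version(), "numpy": np.__version__},
        "outputs": {p.relative_to(out).as_posix(): _sha256(p)
                    for p in sorted(out.rglob("*"))
                    if p.is_file() and p.name != "manifest.json"
                    and p.name != "run.log"},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return out


def _pkg_version() -> str:
    from temquant import __version__
    return __version__
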