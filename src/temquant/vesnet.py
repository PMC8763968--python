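"""Functional surface of the two-stage vesicle detector.

Thin wrappers over :mod:`temquant.models`: a ``TrainConfig`` capturing each
stage's training regime (mini-batch 25 / max epoch 500 with +-10% resize +
reflection for stage 1; mini-batch 100 / max epoch 1,000 with augmentation
limited to +-5% resize, reflection and a +-2 px pixel shift for stage 2;
20% random validation split for both), a ``ModelBundle`` holding both
trained stages with a JSON manifest, and the pipeline operations
``train_stage`` / ``grad_cam`` / ``scan_localize`` / ``segment_vesicles``.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from temquant.models import (
    LocalizationMap,
    PatchClassifier,
    PatchSegmenter,
    RegionOfInterest,
    VesicleDetector,
    VesicleInstance,
)
from temquant.synth import PatchDataset, PixelImage

__all__ = [
    "TrainConfig",
    "ModelBundle",
    "LocalizationMap",
    "RegionOfInterest",
    "VesicleInstance",
    "train_stage",
    "grad_cam",
    "scan_localize",
    "segment_vesicles",
]

_STAGE_DEFAULTS = {
    1: dict(mini_batch=25, max_epoch=500, augment_resize=0.10,
            augment_reflect=True, augment_shift_px=0),
    2: dict(mini_batch=100, max_epoch=1000, augment_resize=0.05,
            augment_reflect=True, augment_shift_px=2),
}
_AUGMENT_CAPS = {1: (0.10, 0), 2: (0.05, 2)}   # (max resize, max shift)


@dataclass
class TrainConfig:
    """Training regime of one detector stage; ``None`` fields take the
    stage's default."""

    stage: int
    mini_batch: int | None = None
    max_epoch: int | None = None
    augment_resize: float | None = None
    augment_reflect: bool = True
    augment_shift_px: int | None = None
    validation_fraction: float = 0.20
    lr: float | None = None
    seed: int = 0

    def resolved(self) -> dict:
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        d = dict(_STAGE_DEFAULTS[self.stage])
        for k in ("mini_batch", "max_epoch", "augment_resize",
                  "augment_shift_px"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        d["augment_reflect"] = self.augment_reflect
        cap_resize, cap_shift = _AUGMENT_CAPS[self.stage]
        if d["augment_resize"] > cap_resize or d["augment_shift_px"] > cap_shift:
            raise ValueError(
                f"stage-{self.stage} augmentation exceeds its caps "
                f"(resize <= {cap_resize}, shift <= {cap_shift} px)")
        if self.lr is not None:
            d["lr"] = self.lr
        d["validation_fraction"] = self.validation_fraction
        d["random_state"] = self.seed
        return d


@dataclass
class ModelBundle:
    """Both trained stages plus patch geometry and training reports."""

    stage1: PatchClassifier | None = None
    stage2: PatchSegmenter | None = None
    patch_px: int | None = None
    class_semantics: dict = field(
        default_factory=lambda: {0: "background", 1: "vesicle"})
    training_report: dict = field(default_factory=dict)

    def require(self, *stages: int) -> None:
        if 1 in stages and self.stage1 is None:
            raise ValueError("stage-1 classifier missing from bundle")
        if 2 in stages and self.stage2 is None:
            raise ValueError("stage-2 segmenter missing from bundle")

    def detector(self, **kwargs) -> VesicleDetector:
        self.require(1, 2)
        return VesicleDetector(classifier=self.stage1, segmenter=self.stage2,
                               **kwargs)

    # -- serialization: one zip archive with a JSON manifest ---------------

    def save(self, path) -> None:
        manifest = {
            "patch_px": self.patch_px,
            "class_semantics": {str(k): v
                                for k, v in self.class_semantics.items()},
            "training_report": self.training_report,
            "stages": {},
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, est in (("stage1", self.stage1), ("stage2", self.stage2)):
                if est is None:
                    continue
                manifest["stages"][name] = {
                    "params": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in est.get_params().items()},
                    "patch_px": est.patch_px_,
                    "validation_accuracy": est.validation_accuracy_,
                }
                buf = io.BytesIO()
                np.savez(buf, **est.net_.state_arrays())
                zf.writestr(f"{name}.npz", buf.getvalue())
            zf.writestr("manifest.json", json.dumps(manifest, indent=1,
                                                    sort_keys=True))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            bundle = cls(patch_px=manifest["patch_px"],
                         class_semantics={int(k): v for k, v in
                                          manifest["class_semantics"].items()},
                         training_report=manifest["training_report"])
            for name, klass in (("stage1", PatchClassifier),
                                ("stage2", PatchSegmenter)):
                info = manifest["stages"].get(name)
                if info is None:
                    continue
                params = {k: (tuple(v) if isinstance(v, list) else v)
                          for k, v in info["params"].items()}
                est = klass(**params)
                rng = np.random.default_rng(0)
                est.net_ = est._build(rng)
                with zf.open(f"{name}.npz") as f:
                    state = dict(np.load(io.BytesIO(f.read())))
                est.net_.load_state_arrays(state)
                est.patch_px_ = info["patch_px"]
                est.validation_accuracy_ = info["validation_accuracy"]
                est.classes_ = np.array([0, 1])
                setattr(bundle, name, est)
        return bundle


# ---------------------------------------------------------------------------
# operations


def train_stage(dataset: PatchDataset, config: TrainConfig,
                bundle: ModelBundle | None = None) -> ModelBundle:
    """Train one detector stage on a labeled patch dataset.

    Stage 1 expects ``mode='classify'`` data, stage 2 ``mode='segment'``.
    Returns a bundle with the trained stage filled (augmenting ``bundle``
    in place when one is given).
    """
    opts = config.resolved()
    expected_mode = "classify" if config.stage == 1 else "segment"
    if dataset.mode != expected_mode:
        raise ValueError(f"stage {config.stage} needs a {expected_mode!r} "
                         f"dataset, got {dataset.mode!r}")
    Xt, yt = dataset.subset("train")
    Xv, yv = dataset.subset("val")
    if len(Xv) == 0 or len(Xt) == 0:
        raise ValueError("dataset must contain both train and val items")
    bundle = bundle or ModelBundle()
    if config.stage == 1:
        est = PatchClassifier(**{k: v for k, v in opts.items()
                                 if k != "validation_fraction"})
        est.fit(Xt, yt, validation_data=(Xv, yv))
        bundle.stage1 = est
    else:
        est = PatchSegmenter(**{k: v for k, v in opts.items()
                                if k != "validation_fraction"})
        est.fit(Xt, yt, validation_data=(Xv, yv))
        bundle.stage2 = est
    bundle.patch_px = est.patch_px_
    bundle.training_report[f"stage{config.stage}"] = {
        "validation_accuracy": est.validation_accuracy_,
        "n_epochs": est.n_epochs_,
        "history": est.history_,
        "seed": config.seed,
    }
    return bundle


def grad_cam(model: ModelBundle, patch, class_index: int = 1) -> LocalizationMap:
    """Grad-CAM localization map of one patch under the stage-1 model."""
    model.require(1)
    data = patch.data if isinstance(patch, PixelImage) else np.asarray(patch)
    if data.max() > 1.5:
        data = data.astype(float) / 255.0
    if data.shape != (model.stage1.patch_px_,) * 2:
        raise ValueError(f"patch shape {data.shape} does not match "
                         f"patch_px {model.stage1.patch_px_}")
    return model.stage1.grad_cam(data[None], class_index)[0]


def scan_localize(model: ModelBundle, image: PixelImage,
                  stride_px: int | None = None,
                  roi_threshold: float = 0.5) -> list[RegionOfInterest]:
    """Scan a micrograph with the stage-1 model; return candidate ROIs."""
    model.require(1)
    det = VesicleDetector(classifier=model.stage1, segmenter=model.stage2,
                          roi_threshold=roi_threshold)
    rois, _ = det.scan_localize(image, stride_px=stride_px)
    return rois


def segment_vesicles(model: ModelBundle, image: PixelImage,
                     rois: list[RegionOfInterest]) -> list[VesicleInstance]:
    """Segment individual vesicles inside ROIs with the stage-2 model."""
    model.require(2)
    det = VesicleDetector(classifier=model.stage1, segmenter=model.stage2)
    return det.segment_rois(image, rois)
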