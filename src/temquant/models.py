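"""Scikit-learn-style estimators for the two-stage vesicle detector.

Stage 1 (`PatchClassifier`) is a small CNN that labels fixed-size grayscale
patches as vesicle / background and exposes Grad-CAM localization maps.
Stage 2 (`PatchSegmenter`) is a small fully-convolutional network that
labels vesicle pixels inside regions of interest.  `VesicleDetector`
composes the two: it scans a micrograph with the classifier, stitches
Grad-CAM maps into an image-level localization map, extracts ROIs, and
segments individual vesicles inside them.

Both trainable estimators follow the sklearn protocol (``fit``,
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) and train with mini-batch Adam, capped-magnitude data
augmentation, and early stopping when validation accuracy plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, ClassifierMixin
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize as sk_resize

from temquant._minicnn import (
    Adam,
    Conv2D,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    Sequential,
    Upsample2,
    pixel_softmax_xent,
    softmax,
    softmax_xent,
)
from temquant.synth import PixelImage

__all__ = [
    "PatchClassifier",
    "PatchSegmenter",
    "VesicleDetector",
    "LocalizationMap",
    "VesicleInstance",
    "RegionOfInterest",
    "grad_cam_from_net",
]


@dataclass
class LocalizationMap:
    """A Grad-CAM score map aligned to an image region."""

    scores: np.ndarray                 # 2-D, values in [0, 1]
    origin: tuple[int, int] = (0, 0)   # (x0, y0) offset of the region


@dataclass
class RegionOfInterest:
    """A candidate vesicle region: bounding box + its localization map."""

    x0: int
    y0: int
    x1: int
    y1: int
    map: LocalizationMap


@dataclass
class VesicleInstance:
    """One detected vesicle."""

    centroid: tuple[float, float]      # (x, y) px, image coordinates
    mask: np.ndarray                   # 2-D bool, cropped to the bbox
    bbox: tuple[int, int, int, int]    # (x0, y0, x1, y1) of the mask
    equivalent_diameter_nm: float
    score: float


# ---------------------------------------------------------------------------
# shared helpers


def _as_nchw(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        X = X[:, None]
    if X.ndim != 4 or X.shape[1] != 1:
        raise ValueError("X must be (n, p, p) or (n, 1, p, p) grayscale patches")
    return X


def _augment_batch(X: np.ndarray, rng: np.random.Generator, resize: float,
                   reflect: bool, shift_px: int) -> np.ndarray:
    """Random per-patch resize (bounded), reflection and integer pixel shift.

    Augmentation magnitudes are capped at the configured limits; resizing
    resamples about the patch centre so content stays centred.
    """
    n, _, h, w = X.shape
    out = X
    if reflect:
        flips = rng.random(n) < 0.5
        out = out.copy()
        out[flips] = out[flips][..., ::-1]
    if resize > 0 or shift_px > 0:
        out2 = np.empty_like(out)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        gy, gx = np.mgrid[0:h, 0:w].astype(float)
        for i in range(n):
            s = 1.0 + rng.uniform(-resize, resize) if resize > 0 else 1.0
            dy = dx = 0
            if shift_px > 0:
                dy, dx = rng.integers(-shift_px, shift_px + 1, size=2)
            iy = (gy - cy) / s + cy + dy
            ix = (gx - cx) / s + cx + dx
            out2[i, 0] = ndi.map_coordinates(out[i, 0], [iy, ix], order=1,
                                             mode="reflect")
        out = out2
    return out


def _stratified_split(y: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of validation items, stratified per class."""
    val = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        val[idx[: int(round(fraction * len(idx)))]] = True
    return val


def grad_cam_from_net(net: Sequential, X: np.ndarray, class_index: int,
                      feature_layer: int, out_size: tuple[int, int]):
    """Grad-CAM maps for a batch, w.r.t. the output of ``feature_layer``.

    Channel weights are the spatial average of the class-score (logit)
    gradient over the feature maps; the map is the rectified weighted sum,
    bilinearly upsampled to ``out_size`` and max-normalized to [0, 1].
    """
    a = X
    for layer in net.layers[: feature_layer + 1]:
        a = layer.forward(a)
    feats = a                                       # (n, C, h, w)
    logits = a
    for layer in net.layers[feature_layer + 1:]:
        logits = layer.forward(logits)
    if not 0 <= class_index < logits.shape[1]:
        raise ValueError(f"class_index {class_index} out of range")
    dy = np.zeros_like(logits)
    dy[:, class_index] = 1.0
    dfeats = net.backward(dy, stop_at=feature_layer + 1)
    alpha = dfeats.mean(axis=(2, 3))                # (n, C)
    cam = np.maximum((alpha[:, :, None, None] * feats).sum(axis=1), 0.0)
    maps = np.empty((len(X), *out_size))
    for i in range(len(X)):
        m = sk_resize(cam[i], out_size, order=1, mode="edge",
                      anti_aliasing=False)
        peak = m.max()
        maps[i] = m / peak if peak > 0 else m
    return maps


# ---------------------------------------------------------------------------
# stage 1: patch classifier


class PatchClassifier(ClassifierMixin, BaseEstimator):
    """Small-CNN vesicle/background patch classifier with Grad-CAM.

    Defaults follow the stage-1 training regime: mini-batch 25, up to 500
    epochs, augmentation capped at +-10% resizing plus reflection, a random
    20% validation split, and early stopping on a 20-epoch validation
    plateau.

    Attributes set by :meth:`fit` (trailing underscore): ``net_``,
    ``classes_``, ``history_``, ``validation_accuracy_``, ``n_epochs_``,
    ``patch_px_``.
    """

    def __init__(self, mini_batch: int = 25, max_epoch: int = 500,
                 lr: float = 1e-3, augment_resize: float = 0.10,
                 augment_reflect: bool = True, augment_shift_px: int = 0,
                 validation_fraction: float = 0.20, patience: int = 20,
                 min_delta: float = 1e-4,
                 channels: tuple[int, int, int] = (8, 16, 32),
                 random_state: int = 0):
        self.mini_batch = mini_batch
        self.max_epoch = max_epoch
        self.lr = lr
        self.augment_resize = augment_resize
        self.augment_reflect = augment_reflect
        self.augment_shift_px = augment_shift_px
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.channels = channels
        self.random_state = random_state

    def _build(self, rng: np.random.Generator) -> Sequential:
        c1, c2, c3 = self.channels
        return Sequential([
            Conv2D(1, c1, 3, "same", rng), ReLU(), MaxPool2(),
            Conv2D(c1, c2, 3, "same", rng), ReLU(), MaxPool2(),
            Conv2D(c2, c3, 3, "same", rng), ReLU(),
            GlobalAvgPool(), Dense(c3, 2, rng),
        ])

    # output of layer 7 (last ReLU) = the last convolutional feature maps
    _FEATURE_LAYER = 7

    def fit(self, X, y, validation_data=None):
        X = _as_nchw(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        rng = np.random.default_rng(self.random_state)
        if validation_data is None:
            val_mask = _stratified_split(y, self.validation_fraction, rng)
            Xv, yv = X[val_mask], y[val_mask]
            Xt, yt = X[~val_mask], y[~val_mask]
        else:
            Xt, yt = X, y
            Xv, yv = validation_data
            Xv = _as_nchw(Xv)
            yv = np.asarray(yv, dtype=int)
        self.patch_px_ = X.shape[-1]
        self.net_ = self._build(rng)
        opt = Adam(self.net_, lr=self.lr)
        best_acc, best_state, since_best = -1.0, None, 0
        self.history_ = []
        for epoch in range(self.max_epoch):
            order = rng.permutation(len(Xt))
            losses = []
            for i in range(0, len(order), self.mini_batch):
                idx = order[i:i + self.mini_batch]
                xb = _augment_batch(Xt[idx], rng, self.augment_resize,
                                    self.augment_reflect, self.augment_shift_px)
                loss, d = softmax_xent(self.net_.forward(xb), yt[idx])
                self.net_.backward(d)
                opt.step()
                losses.append(loss)
            acc = float((self._predict_classes(Xv) == yv).mean())
            self.history_.append({"epoch": epoch, "loss": float(np.mean(losses)),
                                  "val_accuracy": acc})
            significant = acc >= best_acc + self.min_delta
            if acc > best_acc:
                best_acc = acc
                best_state = {k: v.copy()
                              for k, v in self.net_.state_arrays().items()}
            since_best = 0 if significant else since_best + 1
            if since_best >= self.patience:
                break
        if best_state is not None:
            self.net_.load_state_arrays(best_state)
        self.validation_accuracy_ = best_acc
        self.n_epochs_ = len(self.history_)
        return self

    def _predict_classes(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        X = _as_nchw(X)
        out = []
        for i in range(0, len(X), 512):
            out.append(softmax(self.net_.forward(X[i:i + 512])))
        return np.vstack(out) if out else np.zeros((0, 2))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self._predict_classes(_as_nchw(X))]

    def grad_cam(self, X, class_index: int = 1) -> list[LocalizationMap]:
        """Grad-CAM localization maps (one per patch), in [0, 1]."""
        X = _as_nchw(X)
        maps = grad_cam_from_net(self.net_, X, class_index,
                                 self._FEATURE_LAYER, X.shape[-2:])
        return [LocalizationMap(m) for m in maps]


# ---------------------------------------------------------------------------
# stage 2: pixelwise segmenter


class PatchSegmenter(BaseEstimator):
    """Fully-convolutional vesicle-pixel segmenter.

    Defaults follow the stage-2 regime: mini-batch 100, up to 1,000 epochs,
    augmentation limited to +-5% resizing plus reflection and a +-2 px pixel
    shift, 20% validation split.  Validation accuracy is per-pixel.  Being
    fully convolutional, the trained network accepts regions of any size.
    """

    def __init__(self, mini_batch: int = 100, max_epoch: int = 1000,
                 lr: float = 2e-3, augment_resize: float = 0.05,
                 augment_reflect: bool = True, augment_shift_px: int = 2,
                 validation_fraction: float = 0.20, patience: int = 20,
                 min_delta: float = 1e-4,
                 channels: tuple[int, int, int] = (8, 16, 8),
                 foreground_weight: float = 2.0, random_state: int = 0):
        self.mini_batch = mini_batch
        self.max_epoch = max_epoch
        self.lr = lr
        self.augment_resize = augment_resize
        self.augment_reflect = augment_reflect
        self.augment_shift_px = augment_shift_px
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.channels = channels
        self.foreground_weight = foreground_weight
        self.random_state = random_state

    def _build(self, rng: np.random.Generator) -> Sequential:
        # encoder-decoder: the wide middle convolutions run at half
        # resolution, a final full-resolution conv restores boundary detail;
        # cheap per iteration and adequate for ~10 px objects
        c1, c2, c3 = self.channels
        return Sequential([
            Conv2D(1, c1, 3, "same", rng), ReLU(), MaxPool2(),
            Conv2D(c1, c2, 3, "same", rng), ReLU(),
            Conv2D(c2, c2, 3, "same", rng), ReLU(),
            Conv2D(c2, c3, 3, "same", rng), ReLU(), Upsample2(),
            Conv2D(c3, 2, 3, "same", rng),
        ])

    def fit(self, X, Y, validation_data=None):
        """Fit on patches ``X`` (n, p, p) with per-pixel labels ``Y``."""
        X = _as_nchw(X)
        Y = np.asarray(Y, dtype=int)
        if Y.shape != (X.shape[0], X.shape[2], X.shape[3]):
            raise ValueError("Y must be (n, p, p) per-pixel labels")
        if len(np.unique(Y)) < 2:
            raise ValueError("training data contains a single pixel class")
        rng = np.random.default_rng(self.random_state)
        if validation_data is None:
            has_fg = Y.any(axis=(1, 2)).astype(int)
            val_mask = _stratified_split(has_fg, self.validation_fraction, rng)
            Xv, Yv = X[val_mask], Y[val_mask]
            Xt, Yt = X[~val_mask], Y[~val_mask]
        else:
            Xt, Yt = X, Y
            Xv, Yv = validation_data
            Xv = _as_nchw(Xv)
            Yv = np.asarray(Yv, dtype=int)
        self.patch_px_ = X.shape[-1]
        self.net_ = self._build(rng)
        opt = Adam(self.net_, lr=self.lr)
        best_acc, best_state, since_best = -1.0, None, 0
        self.history_ = []
        for epoch in range(self.max_epoch):
            order = rng.permutation(len(Xt))
            losses = []
            for i in range(0, len(order), self.mini_batch):
                idx = order[i:i + self.mini_batch]
                xb = Xt[idx]
                yb = Yt[idx]
                if self.augment_reflect:
                    flips = rng.random(len(idx)) < 0.5
                    xb = xb.copy()
                    yb = yb.copy()
                    xb[flips] = xb[flips][..., ::-1]
                    yb[flips] = yb[flips][..., ::-1]
                if self.augment_shift_px > 0:
                    sh = rng.integers(-self.augment_shift_px,
                                      self.augment_shift_px + 1, size=2)
                    xb = np.roll(xb, tuple(sh), axis=(-2, -1))
                    yb = np.roll(yb, tuple(sh), axis=(-2, -1))
                if self.augment_resize > 0:
                    # one bounded scale per batch; nearest-neighbour labels
                    s = 1.0 + rng.uniform(-self.augment_resize,
                                          self.augment_resize)
                    xb, yb = self._rescale(xb, yb, s)
                loss, d = pixel_softmax_xent(self.net_.forward(xb), yb,
                                             self.foreground_weight)
                self.net_.backward(d)
                opt.step()
                losses.append(loss)
            acc = self._pixel_accuracy(Xv, Yv)
            self.history_.append({"epoch": epoch, "loss": float(np.mean(losses)),
                                  "val_accuracy": acc})
            significant = acc >= best_acc + self.min_delta
            if acc > best_acc:
                best_acc = acc
                best_state = {k: v.copy()
                              for k, v in self.net_.state_arrays().items()}
            since_best = 0 if significant else since_best + 1
            if since_best >= self.patience:
                break
        if best_state is not None:
            self.net_.load_state_arrays(best_state)
        self.validation_accuracy_ = best_acc
        self.n_epochs_ = len(self.history_)
        return self

    @staticmethod
    def _rescale(xb: np.ndarray, yb: np.ndarray, s: float):
        n, _, h, w = xb.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        gy, gx = np.mgrid[0:h, 0:w].astype(float)
        iy = (gy - cy) / s + cy
        ix = (gx - cx) / s + cx
        xo = np.empty_like(xb)
        yo = np.empty_like(yb)
        for i in range(n):
            xo[i, 0] = ndi.map_coordinates(xb[i, 0], [iy, ix], order=1,
                                           mode="reflect")
            yo[i] = ndi.map_coordinates(yb[i], [iy, ix], order=0,
                                        mode="reflect")
        return xo, yo

    def _pixel_accuracy(self, X: np.ndarray, Y: np.ndarray) -> float:
        pred = self.predict(X)
        return float((pred == Y).mean())

    def predict_proba(self, X) -> np.ndarray:
        """Foreground (vesicle) probability per pixel: (n, H, W).

        Regions of any size are accepted; odd dimensions are reflect-padded
        to even (the network downsamples once) and cropped back.
        """
        X = _as_nchw(X)
        h, w = X.shape[2:]
        ph, pw = h % 2, w % 2
        if ph or pw:
            X = np.pad(X, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        out = []
        for i in range(0, len(X), 256):
            logits = self.net_.forward(X[i:i + 256])
            out.append(softmax(logits, axis=1)[:, 1])
        probs = (np.concatenate(out) if out
                 else np.zeros((0,) + X.shape[2:]))
        return probs[:, :h, :w]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def score(self, X, Y) -> float:
        return self._pixel_accuracy(_as_nchw(X), np.asarray(Y, dtype=int))


# ---------------------------------------------------------------------------
# the composed detector


class VesicleDetector(BaseEstimator):
    """Two-stage vesicle detector: Grad-CAM scan + per-ROI segmentation.

    ``classifier`` and ``segmenter`` may be pre-fitted or are fitted by
    :meth:`fit` from (classification dataset, segmentation dataset) pairs.
    """

    def __init__(self, classifier: PatchClassifier | None = None,
                 segmenter: PatchSegmenter | None = None,
                 stride_px: int | None = None, roi_threshold: float = 0.5,
                 roi_margin_px: int = 8, min_area_px: int = 15,
                 dedup_radius_px: float = 5.0):
        self.classifier = classifier
        self.segmenter = segmenter
        self.stride_px = stride_px
        self.roi_threshold = roi_threshold
        self.roi_margin_px = roi_margin_px
        self.min_area_px = min_area_px
        self.dedup_radius_px = dedup_radius_px

    # -- training ----------------------------------------------------------

    def fit(self, classify_data, segment_data):
        """Fit both stages from (X, y[, validation_data]) tuples."""
        self.classifier_ = self.classifier or PatchClassifier()
        self.segmenter_ = self.segmenter or PatchSegmenter()
        self.classifier_.fit(*classify_data)
        self.segmenter_.fit(*segment_data)
        return self

    def _clf(self) -> PatchClassifier:
        clf = getattr(self, "classifier_", None) or self.classifier
        if clf is None or not hasattr(clf, "net_"):
            raise ValueError("stage-1 classifier is not fitted")
        return clf

    def _seg(self) -> PatchSegmenter:
        seg = getattr(self, "segmenter_", None) or self.segmenter
        if seg is None or not hasattr(seg, "net_"):
            raise ValueError("stage-2 segmenter is not fitted")
        return seg

    # -- inference ---------------------------------------------------------

    def scan_localize(self, image: PixelImage, stride_px: int | None = None,
                      roi_threshold: float | None = None
                      ) -> tuple[list[RegionOfInterest], np.ndarray]:
        """Scan the image; return candidate ROIs and the stitched map.

        Overlapping patches whose vesicle-class probability reaches
        ``roi_threshold`` contribute their Grad-CAM maps to an image-level
        localization map (averaged over contributing patches); connected
        regions of that map above the threshold become ROIs.
        """
        clf = self._clf()
        p = clf.patch_px_
        stride = stride_px or self.stride_px or p // 2
        if stride > p:
            raise ValueError("stride_px must not exceed the patch size")
        thr = self.roi_threshold if roi_threshold is None else roi_threshold
        img = image.data.astype(float) / 255.0
        h, w = img.shape
        if h < p or w < p:
            raise ValueError(f"image {img.shape} smaller than patch size {p}")
        ys = sorted(set(list(range(0, h - p + 1, stride)) + [h - p]))
        xs = sorted(set(list(range(0, w - p + 1, stride)) + [w - p]))
        tiles = np.array([img[y:y + p, x:x + p] for y in ys for x in xs])
        coords = [(x, y) for y in ys for x in xs]
        probs = clf.predict_proba(tiles)[:, 1]
        hot = np.flatnonzero(probs >= thr)
        accum = np.zeros((h, w))
        count = np.zeros((h, w))
        for i in range(0, len(hot), 256):
            sel = hot[i:i + 256]
            cams = grad_cam_from_net(clf.net_, tiles[sel][:, None], 1,
                                     clf._FEATURE_LAYER, (p, p))
            for j, k in enumerate(sel):
                x, y = coords[k]
                accum[y:y + p, x:x + p] += cams[j]
                count[y:y + p, x:x + p] += 1.0
        stitched = np.divide(accum, count, out=np.zeros_like(accum),
                             where=count > 0)
        lab = cc_label(stitched >= thr)
        rois = []
        m = self.roi_margin_px
        for r in regionprops(lab):
            y0, x0, y1, x1 = r.bbox
            x0, y0 = max(x0 - m, 0), max(y0 - m, 0)
            x1, y1 = min(x1 + m, w), min(y1 + m, h)
            rois.append(RegionOfInterest(
                x0, y0, x1, y1,
                LocalizationMap(stitched[y0:y1, x0:x1], origin=(x0, y0))))
        return rois, stitched

    def segment_rois(self, image: PixelImage,
                     rois: list[RegionOfInterest]) -> list[VesicleInstance]:
        """Segment individual vesicles inside the given ROIs."""
        seg = self._seg()
        img = image.data.astype(float) / 255.0
        cand = []
        for roi in rois:
            crop = img[roi.y0:roi.y1, roi.x0:roi.x1]
            if min(crop.shape) < 8:
                continue
            prob = seg.predict_proba(crop[None])[0]
            lab = cc_label(prob >= 0.5)
            for r in regionprops(lab):
                if r.area < self.min_area_px:
                    continue
                cy, cx = r.centroid
                y0, x0, y1, x1 = r.bbox
                mask = lab[y0:y1, x0:x1] == r.label
                diam = 2.0 * np.sqrt(r.area / np.pi) * image.nm_per_px
                score = float(prob[lab == r.label].mean())
                cand.append(VesicleInstance(
                    centroid=(cx + roi.x0, cy + roi.y0),
                    mask=mask,
                    bbox=(x0 + roi.x0, y0 + roi.y0, x1 + roi.x0, y1 + roi.y0),
                    equivalent_diameter_nm=float(diam),
                    score=score))
        # deduplicate across overlapping ROIs
        cand.sort(key=lambda v: -v.score)
        kept: list[VesicleInstance] = []
        for v in cand:
            c = np.array(v.centroid)
            if all(np.linalg.norm(c - np.array(u.centroid)) >=
                   self.dedup_radius_px for u in kept):
                kept.append(v)
        return kept

    def detect(self, image: PixelImage) -> list[VesicleInstance]:
        """Full two-stage detection on one micrograph."""
        rois, _ = self.scan_localize(image)
        return self.segment_rois(image, rois)
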