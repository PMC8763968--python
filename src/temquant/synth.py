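"""Synthetic TEM scene generation with full ground truth.

Emulates the two kinds of micrograph the quantification pipeline consumes:

* whole neuron-SGC units: a large, roughly elliptic neuron soma wrapped by a
  thin satellite-glial sheath.  The neuron-SGC separation is normally tens of
  nanometres; the "KO-like" condition injects micron-scale gap sectors and a
  doubled vesicle density, emulating the Fmr1-KO phenotype.
* small high-resolution fields of SGC cytoplasm, where ~50 nm vesicular
  profiles are scattered as a homogeneous Poisson process.

Geometry notes.  Contours are polygons in (x=col, y=row) pixel coordinates,
counter-clockwise, 0-based.  The SGC inner membrane is the neuron contour
offset along the neuron's outward normal by ``baseline_gap + gap(theta)``;
offsetting along the normal (rather than radially) makes the nearest-point
distance at a gap peak equal the injected depth exactly, so ground-truth gap
depths are recoverable to sub-pixel precision.  Gap sectors use a raised
cos^2 profile wide enough that the sector floor, not its walls, is the
nearest membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.draw import disk as draw_disk

__all__ = [
    "PixelImage",
    "GapSector",
    "SceneParams",
    "SceneTruth",
    "FieldTruth",
    "PatchDataset",
    "synthesize_scene",
    "synthesize_vesicle_field",
    "make_patch_dataset",
    "wt_like_params",
    "ko_like_params",
]

# grey levels of an 8-bit rendering (background, neuron, cytoplasm, membrane,
# vesicle ring, vesicle lumen) -- stand-ins, no published raw-image properties
_LEVELS = {"extra": 200.0, "neuron": 120.0, "cyto": 145.0, "membrane": 40.0,
           "ves_ring": 60.0, "ves_lumen": 175.0}
_MEMBRANE_NM = 8.0          # drawn membrane thickness
_TEXTURE_SD = 6.0           # cytoplasm texture amplitude (grey levels)
_ILLUM_AMPLITUDE = 10.0     # low-frequency illumination gradient amplitude


@dataclass
class PixelImage:
    """A 2-D grayscale micrograph with a physical scale."""

    data: np.ndarray            # (H, W), uint8 or float
    nm_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GapSector:
    """An angular sector of neuron-SGC separation.

    ``depth_um`` is the *additional* separation at the sector centre, on top
    of the baseline gap; the profile tapers as cos^2 to zero at the edges.
    """

    center_deg: float
    extent_deg: float
    depth_um: float


@dataclass
class SceneParams:
    image_size_px: tuple[int, int] | None = None   # (H, W); None -> auto-fit
    nm_per_px: float = 5.0
    soma_axes_um: tuple[float, float] = (10.0, 8.0)   # (major, minor) semi-axes
    baseline_gap_nm: float = 30.0
    gap_spec: tuple[GapSector, ...] = ()
    sheath_thickness_um: float = 0.5
    vesicle_density_per_um2: float = 3.0
    vesicle_diameter_nm: float = 50.0
    vesicle_diameter_sd_nm: float = 5.0
    noise_sd: float = 8.0
    boundary_wobble: float = 0.02    # relative low-order radial perturbation
    n_contour_vertices: int = 2048
    seed: int = 0

    def validate(self) -> None:
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        a, b = self.soma_axes_um
        if a <= 0 or b <= 0 or b > a:
            raise ValueError("soma_axes_um must be positive (major, minor)")
        if self.baseline_gap_nm < 0:
            raise ValueError("baseline_gap_nm must be nonnegative")
        if self.sheath_thickness_um <= 0:
            raise ValueError("sheath_thickness_um must be positive")
        if self.vesicle_density_per_um2 < 0:
            raise ValueError("vesicle_density_per_um2 must be nonnegative")
        if self.vesicle_diameter_nm <= 0:
            raise ValueError("vesicle_diameter_nm must be positive")
        ivals = []
        for s in self.gap_spec:
            if s.depth_um < 0:
                raise ValueError("gap depth_um must be nonnegative")
            if not 0 < s.extent_deg <= 180:
                raise ValueError("gap extent_deg must be in (0, 180]")
            ivals.append((s.center_deg % 360.0, s.extent_deg))
        ivals.sort()
        for (c0, e0), (c1, e1) in zip(ivals, ivals[1:] + ivals[:1]):
            gap = (c1 - c0) % 360.0
            if len(ivals) > 1 and gap < (e0 + e1) / 2.0:
                raise ValueError("gap sectors overlap")


@dataclass
class SceneTruth:
    """Ground-truth geometry of a synthetic neuron-SGC scene (px coords)."""

    neuron_contour: np.ndarray        # (N, 2) float, (x, y), CCW, closed implicitly
    sgc_inner_contour: np.ndarray
    sgc_outer_contour: np.ndarray
    gap_sectors: tuple[GapSector, ...]
    vesicle_centers: np.ndarray       # (M, 2) float px
    vesicle_radii_px: np.ndarray      # (M,) float
    vesicle_masks: list               # M x (ox, oy, 2-D bool array)
    nm_per_px: float

    @property
    def vesicle_count(self) -> int:
        return len(self.vesicle_centers)


@dataclass
class FieldTruth:
    """Ground truth of a small cytoplasm field: vesicles only."""

    vesicle_centers: np.ndarray
    vesicle_radii_px: np.ndarray
    vesicle_masks: list
    nm_per_px: float

    @property
    def vesicle_count(self) -> int:
        return len(self.vesicle_centers)


@dataclass
class PatchDataset:
    """Fixed-size labeled grayscale patches with a deterministic 80/20 split."""

    patches: np.ndarray        # (n, p, p) float in [0, 1]
    labels: np.ndarray         # (n,) int for classify; (n, p, p) int for segment
    split: np.ndarray          # (n,) '<U5' tags: 'train' | 'val'
    mode: str                  # 'classify' | 'segment'
    seed: int

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == tag
        return self.patches[m], self.labels[m]


# ---------------------------------------------------------------------------
# contour construction


def _gap_um(theta: np.ndarray, params: SceneParams) -> np.ndarray:
    g = np.full_like(theta, params.baseline_gap_nm / 1000.0)
    deg = np.degrees(theta) % 360.0
    for s in params.gap_spec:
        d = (deg - s.center_deg + 180.0) % 360.0 - 180.0
        inside = np.abs(d) <= s.extent_deg / 2.0
        g[inside] += s.depth_um * np.cos(np.pi * d[inside] / s.extent_deg) ** 2
    return g


def _scene_contours_um(params: SceneParams, rng: np.random.Generator):
    """Neuron / SGC-inner / SGC-outer polygons in um, centred on the soma."""
    n = params.n_contour_vertices
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a, b = params.soma_axes_um
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    # smooth low-order wobble so the soma is only *roughly* elliptic
    amps = rng.normal(0.0, params.boundary_wobble / 2.0, size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    wobble = sum(amp * np.cos((m + 2) * theta + ph)
                 for m, (amp, ph) in enumerate(zip(amps, phases)))
    r = r * (1.0 + wobble)
    neuron = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # outward unit normal from the (periodic) tangent
    tangent = np.gradient(neuron, axis=0, edge_order=2)
    tangent[0] = (neuron[1] - neuron[-1]) / 2.0
    tangent[-1] = (neuron[0] - neuron[-2]) / 2.0
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    flip = np.sign(np.sum(normal * neuron, axis=1, keepdims=True))
    normal *= np.where(flip == 0, 1.0, flip)
    g = _gap_um(theta, params)
    inner = neuron + g[:, None] * normal
    outer = neuron + (g + params.sheath_thickness_um)[:, None] * normal
    return neuron, inner, outer


def _canvas_and_px(params: SceneParams, contours_um):
    scale = 1000.0 / params.nm_per_px          # px per um
    outer = contours_um[2]
    half_extent_um = np.abs(outer).max() + 0.5
    need = 2 * int(math.ceil(half_extent_um * scale))
    if params.image_size_px is None:
        size = (need, need)
    else:
        size = tuple(params.image_size_px)
        if size[0] < need or size[1] < need:
            raise ValueError(
                f"image_size_px {size} cannot contain soma + sheath: "
                f"required extent {need} px "
                f"(soma_axes_um={params.soma_axes_um}, "
                f"sheath_thickness_um={params.sheath_thickness_um})")
    center = np.array([size[1] / 2.0, size[0] / 2.0])
    px = [c * scale + center for c in contours_um]
    return size, px


# ---------------------------------------------------------------------------
# vesicles


def _truncated_normal_diameters(n: int, mean: float, sd: float,
                                rng: np.random.Generator) -> np.ndarray:
    d = rng.normal(mean, sd, size=n)
    lo, hi = mean - 3 * sd, mean + 3 * sd
    bad = (d < lo) | (d > hi)
    while bad.any():
        d[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (d < lo) | (d > hi)
    return d


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0 or poly.is_empty:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    got = 0
    while got < n:
        m = max(4 * n, 256)
        x = rng.uniform(minx, maxx, size=m)
        y = rng.uniform(miny, maxy, size=m)
        keep = shapely.contains_xy(poly, x, y)
        sel = np.column_stack([x[keep], y[keep]])
        pts.append(sel[: n - got])
        got += len(sel[: n - got])
    return np.vstack(pts)


def _vesicle_masks(centers: np.ndarray, radii: np.ndarray,
                   shape: tuple[int, int]) -> list:
    masks = []
    for (cx, cy), r in zip(centers, radii):
        rad = int(math.ceil(r)) + 1
        ox, oy = int(round(cx)) - rad, int(round(cy)) - rad
        side = 2 * rad + 1
        m = np.zeros((side, side), dtype=bool)
        rr, cc = draw_disk((cy - oy, cx - ox), r, shape=m.shape)
        m[rr, cc] = True
        masks.append((ox, oy, m))
    return masks


def _place_vesicles(region: Polygon, density_per_um2: float, params: SceneParams,
                    rng: np.random.Generator, shape: tuple[int, int]):
    """Poisson-scatter vesicles inside `region` (px coords, area in px^2)."""
    scale = 1000.0 / params.nm_per_px
    area_um2 = region.area / scale**2
    count = int(rng.poisson(density_per_um2 * area_um2))
    diam_nm = _truncated_normal_diameters(
        count, params.vesicle_diameter_nm, params.vesicle_diameter_sd_nm, rng)
    radii_px = diam_nm / 2.0 / params.nm_per_px
    margin = (params.vesicle_diameter_nm + 3 * params.vesicle_diameter_sd_nm) \
        / 2.0 / params.nm_per_px + 1.0
    inset = region.buffer(-margin)
    if inset.is_empty and count > 0:
        raise ValueError("cytoplasm region too thin for the vesicle diameter")
    centers = _sample_in_polygon(inset, count, rng)
    masks = _vesicle_masks(centers, radii_px, shape)
    return centers, radii_px, masks


# ---------------------------------------------------------------------------
# rendering


def _region_mask(poly_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon
    rr, cc = draw_polygon(poly_px[:, 1], poly_px[:, 0], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _render(params: SceneParams, shape, contours_px, centers, radii,
            rng: np.random.Generator) -> np.ndarray:
    img = np.full(shape, _LEVELS["extra"])
    neuron_m = _region_mask(contours_px[0], shape)
    inner_m = _region_mask(contours_px[1], shape)
    outer_m = _region_mask(contours_px[2], shape)
    img[outer_m & ~inner_m] = _LEVELS["cyto"]
    img[neuron_m] = _LEVELS["neuron"]
    t = max(1, int(round(_MEMBRANE_NM / params.nm_per_px)))
    selem = np.ones((2 * t + 1, 2 * t + 1), dtype=bool)
    for m in (neuron_m, inner_m, outer_m):
        img[m & ~ndi.binary_erosion(m, selem)] = _LEVELS["membrane"]
    _draw_vesicles(img, centers, radii)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), 3.0)
    texture *= _TEXTURE_SD / max(texture.std(), 1e-9)
    img += texture * (outer_m & ~neuron_m)
    img += _illumination(shape, rng)
    img += rng.normal(0.0, params.noise_sd, shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _draw_vesicles(img: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> None:
    """Dark membrane ring with a lighter lumen, per vesicle."""
    for (cx, cy), r in zip(centers, radii):
        rr, cc = draw_disk((cy, cx), r, shape=img.shape)
        img[rr, cc] = _LEVELS["ves_ring"]
        rr, cc = draw_disk((cy, cx), max(r - 1.8, 0.8), shape=img.shape)
        img[rr, cc] = _LEVELS["ves_lumen"]


def _illumination(shape, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    gy, gx = np.mgrid[0:h, 0:w]
    ay, ax = rng.uniform(-1.0, 1.0, size=2) * _ILLUM_AMPLITUDE
    return ay * (gy / max(h - 1, 1) - 0.5) + ax * (gx / max(w - 1, 1) - 0.5)


# ---------------------------------------------------------------------------
# public generators


def synthesize_scene(params: SceneParams, render: bool = True):
    """Generate one neuron-SGC scene.

    Returns ``(PixelImage, SceneTruth)``; with ``render=False`` the image is
    ``None`` and only the (much cheaper) ground-truth geometry is built.
    Identical ``params`` (including seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    contours_um = _scene_contours_um(params, rng)
    shape, contours_px = _canvas_and_px(params, contours_um)
    ring = Polygon(contours_px[2], holes=[contours_px[1][::-1]])
    centers, radii, masks = _place_vesicles(
        ring, params.vesicle_density_per_um2, params, rng, shape)
    truth = SceneTruth(
        neuron_contour=contours_px[0], sgc_inner_contour=contours_px[1],
        sgc_outer_contour=contours_px[2], gap_sectors=tuple(params.gap_spec),
        vesicle_centers=centers, vesicle_radii_px=radii, vesicle_masks=masks,
        nm_per_px=params.nm_per_px)
    if not render:
        return None, truth
    img = _render(params, shape, contours_px, centers, radii, rng)
    return PixelImage(img, params.nm_per_px), truth


def synthesize_vesicle_field(size_px: int = 256, nm_per_px: float = 5.0,
                             density_per_um2: float = 3.0,
                             vesicle_diameter_nm: float = 50.0,
                             vesicle_diameter_sd_nm: float = 5.0,
                             noise_sd: float = 8.0, seed: int = 0):
    """A small high-resolution field of SGC cytoplasm with scattered vesicles.

    This is what the detection pipeline consumes (the cytoplasm is imaged at
    high magnification; whole-soma scenes are used for morphometry).
    """
    rng = np.random.default_rng(seed)
    shape = (size_px, size_px)
    params = SceneParams(nm_per_px=nm_per_px, noise_sd=noise_sd,
                         vesicle_diameter_nm=vesicle_diameter_nm,
                         vesicle_diameter_sd_nm=vesicle_diameter_sd_nm,
                         seed=seed)
    region = Polygon([(0, 0), (size_px, 0), (size_px, size_px), (0, size_px)])
    centers, radii, masks = _place_vesicles(region, density_per_um2, params,
                                            rng, shape)
    img = np.full(shape, _LEVELS["cyto"])
    _draw_vesicles(img, centers, radii)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), 3.0)
    texture *= _TEXTURE_SD / max(texture.std(), 1e-9)
    img += texture
    img += _illumination(shape, rng)
    img += rng.normal(0.0, noise_sd, shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = FieldTruth(vesicle_centers=centers, vesicle_radii_px=radii,
                       vesicle_masks=masks, nm_per_px=nm_per_px)
    return PixelImage(img, nm_per_px), truth


# ---------------------------------------------------------------------------
# patch datasets

VALIDATION_FRACTION = 0.20   # fraction of labeled patches held out


def _patch_label_mask(truth, x0: int, y0: int, p: int) -> np.ndarray:
    out = np.zeros((p, p), dtype=np.int64)
    for (ox, oy, m) in truth.vesicle_masks:
        sy, sx = oy - y0, ox - x0
        ys0, xs0 = max(sy, 0), max(sx, 0)
        ys1 = min(sy + m.shape[0], p)
        xs1 = min(sx + m.shape[1], p)
        if ys0 >= ys1 or xs0 >= xs1:
            continue
        out[ys0:ys1, xs0:xs1] |= m[ys0 - sy:ys1 - sy, xs0 - sx:xs1 - sx]
    return out


def make_patch_dataset(scenes, patch_px: int = 32, n_patches: int = 2000,
                       mode: str = "classify", seed: int = 0,
                       jitter_px: int = 10) -> PatchDataset:
    """Build a labeled patch dataset from synthetic scenes or fields.

    Positive patches are centred (with +-``jitter_px`` jitter) on ground-truth
    vesicle centres; negatives are sampled from windows free of any vesicle.
    Generous jitter matters: the scanned detector must recognise vesicles
    that sit well off a tile's centre, so positives place the vesicle
    anywhere in the central region of the patch, not only at its middle.
    Labels are binary in ``classify`` mode, per-pixel masks in ``segment``
    mode.  A fixed 20% of each class is assigned to the validation split,
    as a function of the seed only.
    """
    if mode not in ("classify", "segment"):
        raise ValueError(f"unknown mode {mode!r}")
    if not scenes:
        raise ValueError("scenes must be nonempty")
    rng = np.random.default_rng(seed)
    n_pos = n_patches // 2
    n_neg = n_patches - n_pos
    pool = []   # (scene_idx, cx, cy)
    for i, (image, truth) in enumerate(scenes):
        h, w = image.data.shape
        if patch_px >= min(h, w):
            raise ValueError("patch_px must be smaller than the image size")
        half = patch_px // 2
        for (cx, cy) in truth.vesicle_centers:
            if half + jitter_px <= cx < w - half - jitter_px and \
               half + jitter_px <= cy < h - half - jitter_px:
                pool.append((i, cx, cy))
    if n_pos > len(pool):
        raise ValueError(
            f"requested {n_pos} positive patches but only {len(pool)} "
            "vesicles are available (sampling is without replacement)")
    order = rng.permutation(len(pool))[:n_pos]

    patches, labels = [], []
    half = patch_px // 2
    for j in order:
        i, cx, cy = pool[j]
        image, truth = scenes[i]
        jx, jy = rng.integers(-jitter_px, jitter_px + 1, size=2)
        x0 = int(round(cx)) + int(jx) - half
        y0 = int(round(cy)) + int(jy) - half
        patches.append(image.data[y0:y0 + patch_px, x0:x0 + patch_px] / 255.0)
        labels.append(_patch_label_mask(truth, x0, y0, patch_px)
                      if mode == "segment" else 1)

    # negatives: windows whose centre is far from every vesicle centre
    clear = half * math.sqrt(2.0) + 8.0
    got = 0
    while got < n_neg:
        i = int(rng.integers(len(scenes)))
        image, truth = scenes[i]
        h, w = image.data.shape
        x0 = int(rng.integers(0, w - patch_px + 1))
        y0 = int(rng.integers(0, h - patch_px + 1))
        c = np.array([x0 + half, y0 + half])
        if len(truth.vesicle_centers) and \
           np.min(np.linalg.norm(truth.vesicle_centers - c, axis=1)) < clear:
            continue
        patches.append(image.data[y0:y0 + patch_px, x0:x0 + patch_px] / 255.0)
        labels.append(np.zeros((patch_px, patch_px), dtype=np.int64)
                      if mode == "segment" else 0)
        got += 1

    patches = np.asarray(patches, dtype=float)
    labels = np.asarray(labels)
    split = np.empty(n_patches, dtype="<U5")
    # stratified 80/20 so both classes appear in both splits
    for lo, hi in ((0, n_pos), (n_pos, n_patches)):
        idx = lo + rng.permutation(hi - lo)
        n_val = int(round(VALIDATION_FRACTION * (hi - lo)))
        split[idx[:n_val]] = "val"
        split[idx[n_val:]] = "train"
    return PatchDataset(patches=patches, labels=labels, split=split,
                        mode=mode, seed=seed)


DEFAULT_N_TRAIN_FIELDS = 40
DEFAULT_TRAIN_FIELD_PX = 512
DEFAULT_TRAIN_DENSITY = 5.0
DEFAULT_N_PATCHES = 2000


def default_training_fields(seed: int = 1,
                            n_fields: int = DEFAULT_N_TRAIN_FIELDS):
    """The default pool of cytoplasm fields the detector is trained on."""
    return [synthesize_vesicle_field(size_px=DEFAULT_TRAIN_FIELD_PX,
                                     density_per_um2=DEFAULT_TRAIN_DENSITY,
                                     seed=seed * 1000 + s)
            for s in range(n_fields)]


def default_patch_dataset(mode: str, seed: int = 1,
                          n_patches: int = DEFAULT_N_PATCHES,
                          fields=None) -> PatchDataset:
    """The default labeled patch dataset (2,000 patches, 20% validation)."""
    fields = fields if fields is not None else default_training_fields(seed)
    return make_patch_dataset(fields, 32, n_patches, mode, seed=seed)


# ---------------------------------------------------------------------------
# presets


WT_VESICLE_DENSITY = 20.0    # per um^2; ~4% area coverage by 50 nm profiles
KO_VESICLE_DENSITY = 40.0    # 2x the WT-like density


def wt_like_params(seed: int = 0, **overrides) -> SceneParams:
    """Wild-type-like scene: tight sheath (~30 nm baseline gap), no sectors."""
    return replace(SceneParams(seed=seed,
                               vesicle_density_per_um2=WT_VESICLE_DENSITY),
                   **overrides)


def ko_like_params(seed: int = 0, **overrides) -> SceneParams:
    """Fmr1-KO-like scene: 2-4 micron-scale gap sectors, 2x vesicle density.

    Sector widths scale with depth so that the sector floor (not its walls)
    is the nearest membrane; depths are drawn in 0.5-2 um.
    """
    rng = np.random.default_rng(seed + 10_007)
    n_sec = int(rng.integers(2, 5))
    base = SceneParams(seed=seed, vesicle_density_per_um2=KO_VESICLE_DENSITY)
    r_min = base.soma_axes_um[1]
    sectors = []
    centers = (rng.uniform(0, 360) + np.arange(n_sec) * 360.0 / n_sec) % 360.0
    for c in centers:
        depth = float(rng.uniform(0.5, 2.0))
        width = float(np.clip(math.degrees(5.0 * depth / r_min), 30.0,
                              0.9 * 360.0 / n_sec))
        sectors.append(GapSector(center_deg=float(c), extent_deg=width,
                                 depth_um=depth))
    return replace(base, gap_spec=tuple(sectors), **overrides)
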