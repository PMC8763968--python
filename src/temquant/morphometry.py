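"""Structural measurements of neuron-SGC units.

Automates the manual TEM morphometry protocol: for each neuron, the three
largest neuron-to-glia gap distances (taken at distinct locations), a binary
"distant glia" flag, the maximum caliper (Feret) diameter, the traced area,
and a circularity index defined as the major/minor axis ratio of the
second-moment (best-fit) ellipse — 1 for a circle, > 1 for elliptic shapes.

All distance outputs are in micrometres; inputs are polygon contours either
already in um or in pixels with an ``nm_per_px`` scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Polygon

__all__ = [
    "Contour",
    "MorphometryRecord",
    "boundary_gap_profile",
    "top_gaps",
    "classify_gap",
    "feret_diameter",
    "circularity",
    "contour_area",
    "measure_neuron",
]

DEFAULT_GAP_THRESHOLD_UM = 0.25   # "obvious distant glia" operational cutoff
DEFAULT_N_SAMPLES = 720           # gap-profile samples (0.5 degree steps)
DEFAULT_EXCLUSION_DEG = 20.0      # min angular separation of reported gaps


@dataclass
class Contour:
    """A simple closed polygon, vertices in (x, y) order.

    ``nm_per_px`` converts pixel coordinates to physical units; use
    ``nm_per_px=1000`` for vertices already in micrometres.
    """

    vertices: np.ndarray          # (N, 2) float
    nm_per_px: float = 1000.0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if poly.area == 0:
            raise ValueError("contour has zero area")
        if not poly.is_valid:
            raise ValueError("contour is self-intersecting")

    @property
    def um_per_unit(self) -> float:
        return self.nm_per_px / 1000.0

    def vertices_um(self) -> np.ndarray:
        return self.vertices * self.um_per_unit

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class MorphometryRecord:
    """Per-neuron structural measurements."""

    neuron_id: str
    gap_flag: int                     # 0 = no distant glia, 1 = obvious gaps
    gap_distances_um: tuple[float, float, float]   # descending
    diameter_um: float
    area_um2: float
    circularity: float                # >= 1; 1 = circular
    gap_threshold_um: float = DEFAULT_GAP_THRESHOLD_UM
    distinct_gaps: bool = True        # False when < 3 separated maxima existed


def _arc_length_points(vertices: np.ndarray, n: int) -> np.ndarray:
    """n points uniformly spaced by arc length along the closed polygon."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0.0, total, n, endpoint=False)
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg[idx] == 0, 1.0, seg[idx])
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def boundary_gap_profile(neuron: Contour, sgc_inner: Contour,
                         n_samples: int = DEFAULT_N_SAMPLES) -> np.ndarray:
    """Distance (um) from points on the neuron membrane to the SGC membrane.

    Samples ``n_samples`` points uniformly by arc length on the neuron
    contour and measures each point's distance to the nearest point of the
    SGC inner contour.  The neuron must lie strictly inside the SGC contour
    (touching is allowed); intersecting membranes are a geometry error.
    """
    if neuron.nm_per_px != sgc_inner.nm_per_px:
        raise ValueError("contours must share a scale")
    npoly, spoly = neuron.polygon(), sgc_inner.polygon()
    if not spoly.contains(npoly) and not spoly.covers(npoly):
        if npoly.boundary.crosses(spoly.boundary):
            raise ValueError("neuron and SGC contours intersect")
        raise ValueError("neuron contour must lie inside the SGC contour")
    pts = _arc_length_points(neuron.vertices, n_samples)
    boundary = LineString(np.vstack([sgc_inner.vertices, sgc_inner.vertices[:1]]))
    d = shapely.distance(shapely.points(pts), boundary)
    return d * neuron.um_per_unit


def top_gaps(profile: np.ndarray, k: int = 3,
             exclusion_deg: float = DEFAULT_EXCLUSION_DEG) -> tuple[np.ndarray, bool]:
    """The ``k`` largest gap distances at distinct locations.

    Local maxima of the (circular) profile are greedily selected in
    descending order, suppressing further picks within ``exclusion_deg`` of
    an accepted one, so the measurements come from distinct gaps whenever
    possible.  If fewer than ``k`` separated maxima exist, the remainder is
    padded from the global descending order and the second return value is
    False.

    Returns ``(values_descending, distinct)``.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < k:
        raise ValueError(f"profile length {n} < k={k}")
    excl = max(1, int(round(exclusion_deg / 360.0 * n)))
    left = np.roll(profile, 1)
    right = np.roll(profile, -1)
    is_max = (profile >= left) & (profile >= right)
    order = np.argsort(profile, kind="stable")[::-1]
    picked: list[int] = []
    for i in order:
        if not is_max[i]:
            continue
        ang_dist = [min((i - j) % n, (j - i) % n) for j in picked]
        if any(d < excl for d in ang_dist):
            continue
        picked.append(int(i))
        if len(picked) == k:
            break
    distinct = len(picked) == k
    values = [profile[i] for i in picked]
    if not distinct:
        pad = [profile[i] for i in order if i not in picked]
        values += pad[: k - len(values)]
    return np.sort(np.asarray(values))[::-1], distinct


def classify_gap(gaps_um, threshold_um: float = DEFAULT_GAP_THRESHOLD_UM) -> int:
    """1 (obvious distant glia) iff the largest gap reaches the threshold."""
    gaps = np.asarray(gaps_um, dtype=float)
    if gaps.size == 0:
        raise ValueError("gaps_um must be nonempty")
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    return int(gaps.max() >= threshold_um)


def feret_diameter(c: Contour) -> float:
    """Maximum caliper diameter (um): the largest point across the contour."""
    pts = c.vertices_um()
    if len(pts) > 16:
        pts = pts[ConvexHull(pts).vertices]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _region_second_moments(vertices: np.ndarray):
    """Area-normalized central second moments of the enclosed region,
    from exact polygon integrals (Green's theorem)."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    ixx = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    iyy = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    # central, per unit area
    mxx = iyy / a - cx * cx
    myy = ixx / a - cy * cy
    mxy = ixy / a - cx * cy
    return mxx, myy, mxy


def circularity(c: Contour) -> float:
    """Major/minor axis ratio of the best-fit (second-moment) ellipse.

    1 for a circle (and for any shape with equal principal second moments,
    e.g. a square); > 1 for elongated shapes; for an ideal ellipse the ratio
    of semi-axes is recovered exactly.
    """
    mxx, myy, mxy = _region_second_moments(c.vertices)
    tr, det = mxx + myy, mxx * myy - mxy * mxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + np.sqrt(disc)
    l2 = tr / 2.0 - np.sqrt(disc)
    if l2 <= 0:
        raise ValueError("degenerate contour: zero minor second moment")
    return float(np.sqrt(l1 / l2))


def contour_area(c: Contour) -> float:
    """Enclosed (shoelace) area in um^2, orientation-independent."""
    v = c.vertices_um()
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


def measure_neuron(neuron: Contour, sgc_inner: Contour, neuron_id: str = "",
                   threshold_um: float = DEFAULT_GAP_THRESHOLD_UM,
                   n_samples: int = DEFAULT_N_SAMPLES,
                   exclusion_deg: float = DEFAULT_EXCLUSION_DEG) -> MorphometryRecord:
    """Full per-neuron measurement set (gap flag, 3 gaps, diameter, area,
    circularity)."""
    profile = boundary_gap_profile(neuron, sgc_inner, n_samples)
    gaps, distinct = top_gaps(profile, 3, exclusion_deg)
    return MorphometryRecord(
        neuron_id=neuron_id,
        gap_flag=classify_gap(gaps, threshold_um),
        gap_distances_um=tuple(round(float(g), 3) for g in gaps),
        diameter_um=feret_diameter(neuron),
        area_um2=contour_area(neuron),
        circularity=circularity(neuron),
        gap_threshold_um=threshold_um,
        distinct_gaps=distinct,
    )
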