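"""File formats: grayscale images, annotation/detection JSON, CSV tables.

All JSON and CSV artifacts round-trip losslessly and are written with
sorted keys and fixed float formatting so reruns under the same seed are
bit-for-bit identical.  Coordinates are 0-based (x, y); every image record
carries its nm-per-pixel scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from temquant.models import VesicleInstance
from temquant.synth import FieldTruth, PixelImage, SceneTruth

__all__ = [
    "write_image",
    "read_image",
    "rle_encode",
    "rle_decode",
    "truth_to_json",
    "truth_from_json",
    "write_truth",
    "read_truth",
    "detections_to_json",
    "detections_from_json",
    "write_morphometry_csv",
    "read_morphometry_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_comparisons_csv",
]

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# images


def write_image(path, image: PixelImage) -> None:
    """Write a grayscale image; TIFF carries the nm/px scale in its
    description, PNG gets a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.data,
                         description=json.dumps({"nm_per_px": image.nm_per_px}))
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(image.data).save(path)
        path.with_suffix(".scale.json").write_text(
            json.dumps({"nm_per_px": image.nm_per_px}))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path, nm_per_px: float | None = None) -> PixelImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            if nm_per_px is None:
                desc = tf.pages[0].tags.get("ImageDescription")
                if desc is not None:
                    try:
                        nm_per_px = json.loads(desc.value).get("nm_per_px")
                    except (json.JSONDecodeError, AttributeError):
                        pass
    elif path.suffix.lower() == ".png":
        data = np.asarray(PILImage.open(path))
        if nm_per_px is None:
            sidecar = path.with_suffix(".scale.json")
            if sidecar.exists():
                nm_per_px = json.loads(sidecar.read_text())["nm_per_px"]
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if nm_per_px is None:
        raise ValueError(f"no nm_per_px scale found for {path}")
    return PixelImage(data=data, nm_per_px=float(nm_per_px))


# ---------------------------------------------------------------------------
# run-length encoding (row-major, alternating background/foreground runs)


def rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "counts": []}
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    edges = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(edges).tolist()
    if flat[0]:                      # counts always start with a background run
        counts = [0] + counts
    return {"shape": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for c in rle["counts"]:
        if val:
            out[pos:pos + c] = True
        pos += c
        val = not val
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# scene truth


def truth_to_json(truth) -> dict:
    d = {
        "nm_per_px": truth.nm_per_px,
        "vesicles": [
            {"center": [float(cx), float(cy)], "radius_px": float(r),
             "mask_offset": [int(ox), int(oy)], "mask": rle_encode(m)}
            for (cx, cy), r, (ox, oy, m) in zip(
                truth.vesicle_centers, truth.vesicle_radii_px,
                truth.vesicle_masks)
        ],
    }
    if isinstance(truth, SceneTruth):
        d["neuron_contour"] = np.round(truth.neuron_contour, 4).tolist()
        d["sgc_inner_contour"] = np.round(truth.sgc_inner_contour, 4).tolist()
        d["sgc_outer_contour"] = np.round(truth.sgc_outer_contour, 4).tolist()
        d["gap_sectors"] = [
            {"center_deg": s.center_deg, "extent_deg": s.extent_deg,
             "depth_um": s.depth_um} for s in truth.gap_sectors]
    return d


def truth_from_json(d: dict):
    from temquant.synth import GapSector
    centers = np.array([v["center"] for v in d["vesicles"]]).reshape(-1, 2)
    radii = np.array([v["radius_px"] for v in d["vesicles"]])
    masks = [(v["mask_offset"][0], v["mask_offset"][1], rle_decode(v["mask"]))
             for v in d["vesicles"]]
    if "neuron_contour" in d:
        return SceneTruth(
            neuron_contour=np.asarray(d["neuron_contour"], dtype=float),
            sgc_inner_contour=np.asarray(d["sgc_inner_contour"], dtype=float),
            sgc_outer_contour=np.asarray(d["sgc_outer_contour"], dtype=float),
            gap_sectors=tuple(GapSector(**s) for s in d.get("gap_sectors", [])),
            vesicle_centers=centers, vesicle_radii_px=radii,
            vesicle_masks=masks, nm_per_px=d["nm_per_px"])
    return FieldTruth(vesicle_centers=centers, vesicle_radii_px=radii,
                      vesicle_masks=masks, nm_per_px=d["nm_per_px"])


def write_truth(path, truth) -> None:
    Path(path).write_text(json.dumps(truth_to_json(truth), sort_keys=True))


def read_truth(path):
    d = json.loads(Path(path).read_text())
    for key in ("nm_per_px", "vesicles"):
        if key not in d:
            raise ValueError(f"{path}: annotation JSON missing field {key!r}")
    return truth_from_json(d)


# ---------------------------------------------------------------------------
# detections


def detections_to_json(per_image: dict[str, list[VesicleInstance]]) -> dict:
    out = {}
    for name, instances in per_image.items():
        out[name] = [
            {"centroid_px": [round(float(v.centroid[0]), 3),
                             round(float(v.centroid[1]), 3)],
             "diameter_nm": round(float(v.equivalent_diameter_nm), 3),
             "score": round(float(v.score), 6),
             "bbox": [int(b) for b in v.bbox],
             "rle_mask": rle_encode(v.mask)}
            for v in instances]
    return out


def detections_from_json(d: dict) -> dict[str, list[VesicleInstance]]:
    out = {}
    for name, items in d.items():
        out[name] = [
            VesicleInstance(
                centroid=tuple(v["centroid_px"]),
                mask=rle_decode(v["rle_mask"]),
                bbox=tuple(v["bbox"]),
                equivalent_diameter_nm=v["diameter_nm"],
                score=v["score"])
            for v in items]
    return out


# ---------------------------------------------------------------------------
# CSV tables


def write_morphometry_csv(path, records) -> None:
    rows = [{
        "neuron_id": r.neuron_id, "gap_flag": r.gap_flag,
        "gap1_um": r.gap_distances_um[0], "gap2_um": r.gap_distances_um[1],
        "gap3_um": r.gap_distances_um[2], "diameter_um": r.diameter_um,
        "area_um2": r.area_um2, "circularity": r.circularity,
        "gap_threshold_um": r.gap_threshold_um,
        "distinct_gaps": int(r.distinct_gaps),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_morphometry_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles_csv(path, profiles) -> None:
    rows = [{
        "cell_id": p.cell_id, "group": p.group,
        "vesicle_count": p.vesicle_count,
        "hull_area_um2": p.hull_area_um2 if p.hull_area_um2 is not None else "",
        "density_per_um2":
            p.density_per_um2 if p.density_per_um2 is not None else "",
        "detectable": int(p.detectable),
    } for p in profiles]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_profiles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_comparisons_csv(path, comparisons) -> None:
    rows = [{
        "test": c.test_name, "statistic": c.statistic, "p_value": c.p_value,
        "n_group1": c.n_per_group[0], "n_group2": c.n_per_group[1],
        "effect_summary": json.dumps(c.effect_summary, sort_keys=True),
    } for c in comparisons]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
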