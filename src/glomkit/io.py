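"""Readers and writers for every on-disk format the pipeline touches.

* RGB rasters: PNG (8-bit).
* Masks: single-channel indexed PNG, 0 = background, 1..5 = lesion
  classes NL, GS, SS, CR, ISC (documented palette below).
* Instance label maps: 16-bit grayscale PNG (instance ids up to 65535).
* Probability maps: compressed ``.npz`` with a ``probs`` array and an
  ``mpp`` scalar.
* Polygon annotations: JSON of per-glomerulus closed polygons in native
  pixel coordinates with class codes; the importer rasterises them with
  the half-open pixel-centre convention.
* Tables: RFC-4180 CSV with a header row, floats at 9 significant
  digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import LesionClass, MultiClassMask, N_CLASSES, ProbabilityMap, SlideRaster

FLOAT_FORMAT = "%.9g"

#: Indexed-PNG palette for mask values 0..5.
MASK_PALETTE = [
    (255, 255, 255),  # background
    (220, 60, 60),    # NL
    (60, 180, 60),    # GS
    (60, 80, 220),    # SS
    (220, 200, 60),   # CR
    (60, 200, 210),   # ISC
]


def write_slide_png(slide: SlideRaster, path: str | Path) -> None:
    Image.fromarray(slide.pixels).save(path, format="PNG")


def read_slide_png(path: str | Path, mpp: float, slide_id: str | None = None) -> SlideRaster:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return SlideRaster(arr, mpp, slide_id or Path(path).stem)


def write_mask_png(mask: MultiClassMask, path: str | Path) -> None:
    img = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    palette = []
    for rgb in MASK_PALETTE:
        palette.extend(rgb)
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path, format="PNG")


def read_mask_png(path: str | Path, mpp: float) -> MultiClassMask:
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask PNG must be single-channel indexed")
    if arr.max(initial=0) > N_CLASSES:
        r, c = np.unravel_index(int(arr.argmax()), arr.shape)
        raise ValueError(f"{path}: unknown mask index {arr.max()} at pixel ({r}, {c})")
    return MultiClassMask(arr.astype(np.uint8), mpp)


def write_label_map_png(label_map: np.ndarray, path: str | Path) -> None:
    if label_map.max(initial=0) > 65535:
        raise ValueError("instance ids exceed 16-bit range")
    Image.fromarray(label_map.astype(np.uint16)).save(path, format="PNG")


def read_label_map_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)).astype(np.int32)


def write_probmap(probmap: ProbabilityMap, path: str | Path) -> None:
    np.savez_compressed(path, probs=probmap.probs, mpp=probmap.mpp)


def read_probmap(path: str | Path) -> ProbabilityMap:
    with np.load(path) as data:
        return ProbabilityMap(data["probs"], float(data["mpp"]))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\r\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# polygon annotations
# ---------------------------------------------------------------------------


def write_polygons(polygons: list[dict], path: str | Path) -> None:
    """Each entry: {"class": code, "vertices": [[row, col], ...]} with
    vertices in native-scan pixel coordinates (closed implicitly)."""
    Path(path).write_text(json.dumps({"glomeruli": polygons}, indent=1))


def rasterize_polygons(
    polygons: list[dict], shape: tuple[int, int], mpp: float
) -> MultiClassMask:
    """Rasterise closed polygons to a label mask.

    A pixel belongs to a polygon iff its centre (row + 0.5, col + 0.5)
    falls inside (even-odd rule), which realises the half-open window
    convention: a square with corners (0,0) and (10,10) covers exactly
    the 100 pixels of [0,10) x [0,10).  Later polygons paint over
    earlier ones (nearest-label assignment is the annotator's concern).
    """
    from shapely import contains_xy
    from shapely.geometry import Polygon

    labels = np.zeros(shape, dtype=np.uint8)
    for entry in polygons:
        cls = LesionClass[entry["class"]]
        verts = np.asarray(entry["vertices"], dtype=float)
        poly = Polygon(verts[:, ::-1])  # shapely takes (x, y) = (col, row)
        r0 = max(int(np.floor(verts[:, 0].min())), 0)
        r1 = min(int(np.ceil(verts[:, 0].max())) + 1, shape[0])
        c0 = max(int(np.floor(verts[:, 1].min())), 0)
        c1 = min(int(np.ceil(verts[:, 1].max())) + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5).reshape(rr.shape)
        labels[r0:r1, c0:c1][inside] = cls.label
    return MultiClassMask(labels, mpp)


def read_polygons(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    return data["glomeruli"]


def instances_to_table(instances, slide_id: str) -> pd.DataFrame:
    """Instance list -> CSV-ready table (slide_id, instance_id, class,
    area_px, centroid, confidence)."""
    rows = []
    for inst in instances:
        rows.append(
            {
                "slide_id": slide_id,
                "instance_id": inst.instance_id,
                "lesion": inst.lesion.name,
                "area_px": inst.area_px,
                "centroid_row": float(inst.pixels[:, 0].mean()),
                "centroid_col": float(inst.pixels[:, 1].mean()),
                "confidence": inst.confidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "slide_id",
            "instance_id",
            "lesion",
            "area_px",
            "centroid_row",
            "centroid_col",
            "confidence",
        ],
    )
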