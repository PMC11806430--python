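"""Serialization of pipeline inputs and outputs.

Formats are deliberately plain: line scans as TIFF (dtype-preserving) or
8-bit PNG with a JSON sidecar carrying scales, axis, fovea column, and the
Bruch's-membrane trace; sensitivity maps as CSV; atrophy contours as
GeoJSON-style polygon lists in degrees.  ``load_external`` validates all
three against their schemas so externally produced data can enter the
pipeline in place of phantom renders.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .geometry import GridLocus, TestGrid
from .microperimetry import ABSOLUTE, SensitivityMap
from .phantom import LineScan

__all__ = [
    "write_line_scan",
    "load_line_scan",
    "load_sensitivity_map",
    "write_faf_polygons",
    "load_faf_polygons",
    "load_external",
]

_SIDECAR_FIELDS = (
    "lateral_scale_um_per_px",
    "axial_scale_um_per_px",
    "axis",
    "fovea_col",
    "bm_rows",
)


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".json")


def write_line_scan(scan: LineScan, image_path) -> Path:
    """Write a line scan plus its JSON sidecar; returns the sidecar path.

    ``.tif``/``.tiff`` preserves the image dtype bit-exactly; ``.png`` rounds
    to 8-bit grayscale (lossy for float renders).
    """
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(image_path, scan.image)
    elif image_path.suffix.lower() == ".png":
        iio.imwrite(image_path, np.clip(np.rint(scan.image), 0, 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format {image_path.suffix!r}")
    sidecar = _sidecar_path(image_path)
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "lateral_scale_um_per_px": scan.lateral_scale_um_per_px,
                "axial_scale_um_per_px": scan.axial_scale_um_per_px,
                "axis": scan.axis,
                "fovea_col": scan.fovea_col,
                "bm_rows": [float(r) for r in scan.bm_rows],
            },
            fh,
        )
    return sidecar


def load_line_scan(image_path) -> LineScan:
    """Load a line scan and its sidecar, validating the schema."""
    image_path = Path(image_path)
    sidecar = _sidecar_path(image_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} for {image_path}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for field in _SIDECAR_FIELDS:
        if field not in meta:
            raise ValueError(f"sidecar {sidecar} is missing field {field!r}")
    if image_path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(image_path)
    else:
        image = iio.imread(image_path).astype(float)
    return LineScan(
        image=np.asarray(image),
        lateral_scale_um_per_px=float(meta["lateral_scale_um_per_px"]),
        axial_scale_um_per_px=float(meta["axial_scale_um_per_px"]),
        axis=str(meta["axis"]),
        fovea_col=int(meta["fovea_col"]),
        bm_rows=np.asarray(meta["bm_rows"], dtype=float),
    )


def load_sensitivity_map(csv_path) -> SensitivityMap:
    """Load a sensitivity-map CSV (locus_id, axis, x_deg, y_deg, value_db)."""
    df = pd.read_csv(csv_path)
    required = {"locus_id", "axis", "x_deg", "y_deg", "value_db"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    for v in df["value_db"]:
        if v != ABSOLUTE and not 0.0 <= v <= 20.0:
            raise ValueError(
                f"{csv_path}: sensitivity value {v} outside [-1] + [0, 20] dB"
            )
    loci = tuple(
        GridLocus(int(r.locus_id), str(r.axis), float(r.x_deg), float(r.y_deg))
        for r in df.itertuples()
    )
    coords = np.array([abs(l.x_deg) + abs(l.y_deg) for l in loci if l.arm != "foveal"])
    spacing = float(np.min(np.diff(np.unique(coords)))) if len(coords) > 1 else 1.0
    grid = TestGrid(loci, spacing_deg=spacing)
    return SensitivityMap(grid=grid, values=tuple(float(v) for v in df["value_db"]))


def write_faf_polygons(polygons, path) -> None:
    """Write atrophy contours as a GeoJSON-style polygon list (degrees)."""
    with open(path, "w") as fh:
        json.dump(
            {"unit": "degrees", "polygons": [list(p.exterior.coords) for p in polygons]},
            fh,
        )


def load_faf_polygons(path) -> tuple[Polygon, ...]:
    with open(path) as fh:
        data = json.load(fh)
    if "polygons" not in data:
        raise ValueError(f"{path}: missing 'polygons' field")
    polys = []
    for i, coords in enumerate(data["polygons"]):
        poly = Polygon(coords)
        if not poly.is_valid or poly.is_empty:
            raise ValueError(f"{path}: polygon {i} is invalid")
        polys.append(poly)
    return tuple(polys)


def load_external(line_scan_path, mp_csv_path, faf_json_path):
    """Validated pipeline inputs from externally produced files.

    Returns ``(LineScan, SensitivityMap, faf_polygons)`` in the shared
    fovea-centred frame; schema violations raise with the offending file and
    field named.
    """
    scan = load_line_scan(line_scan_path)
    smap = load_sensitivity_map(mp_csv_path)
    polys = load_faf_polygons(faf_json_path)
    return scan, smap, polys
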