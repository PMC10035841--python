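"""File I/O: TIFF stacks, centroid CSVs, polygon JSON and raster sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import DensityRaster, MembraneTruth, NucleusTruth, VoxelStack
from .segmentation import NucleusRecord


def write_stack(path: str | Path, stack: VoxelStack) -> None:
    """ImageJ-compatible TIFF (Z, Y, X) with voxel calibration in metadata."""
    dx, dy, dz = stack.voxel_size
    data = stack.values
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX", "channel": stack.channel},
    )


def read_stack(path: str | Path, channel: str = "nuclei") -> VoxelStack:
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        dz = 1.5
        dx = dy = 0.5205
        try:
            meta = tf.imagej_metadata or {}
            dz = float(meta.get("spacing", dz))
            tags = tf.pages[0].tags
            xres = tags["XResolution"].value
            dx = dy = xres[1] / xres[0]
        except (KeyError, TypeError, ZeroDivisionError):
            pass
    return VoxelStack(values=values, voxel_size=(dx, dy, dz), channel=channel)


def truths_to_frame(truths: list[NucleusTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {
            "id": t.id,
            "x_um": t.center[0],
            "y_um": t.center[1],
            "z_um": t.center[2],
            "radius_um": t.radius,
        }
        row.update({f"marker_{k}": v for k, v in t.markers.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "x_um": r.centroid[0],
            "y_um": r.centroid[1],
            "z_um": r.centroid[2],
            "volume_um3": r.volume,
            "mean_int": r.mean_intensity,
        }
        row.update({f"marker_{k}": v for k, v in r.marker_intensity.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def read_centroids(path: str | Path) -> np.ndarray:
    """(x, y, z) μm array from a centroid CSV (columns x_um, y_um, z_um)."""
    df = pd.read_csv(path)
    return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def write_polygons(path: str | Path, truth: MembraneTruth) -> None:
    """GeoJSON-style polygon export (coordinates in μm)."""
    features = [
        {
            "type": "Feature",
            "properties": {"id": i, "area_um2": float(truth.areas[i]), "group": truth.group},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[float(x), float(y)] for x, y in poly] + [[float(poly[0][0]), float(poly[0][1])]]],
            },
        }
        for i, poly in enumerate(truth.polygons)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def write_raster(path: str | Path, raster: DensityRaster) -> None:
    """Single-band float TIFF plus a JSON sidecar with origin/cell size."""
    path = Path(path)
    tifffile.imwrite(path, raster.values.astype(np.float32))
    sidecar = {
        "origin": list(raster.origin),
        "cell_size": raster.cell_size,
        "units": raster.units,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_raster(path: str | Path) -> DensityRaster:
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return DensityRaster(
        origin=tuple(meta["origin"]), cell_size=meta["cell_size"], values=values, units=meta["units"]
    )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes × stages matrix from TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    """Gene annotations from TSV: columns gene, keywords, dv_asymmetric."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")
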