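"""End-to-end pipeline orchestration with explicit seeds and a run manifest.

One run synthesizes embryos per genotype, segments their nuclear stacks,
registers the centroids onto the first embryo's landmark frame, builds
kernel-density rasters and genotype-average heatmaps, classifies hot/cold
spots, and computes midline ROI counts with the D/V difference statistics.
Every artifact is written under the output directory; the manifest records
the config hash, seeds and module version so a rerun reproduces every
numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .datatypes import UM_PER_PX
from .density import LandmarkSet, average_rasters, fit_landmark_transform, kernel_density, surface_mask
from .hotspots import DISTANCE_BAND_DORSAL, DISTANCE_BAND_VENTRAL, GRID_EDGE, hotspot_analysis
from .presets import get_preset
from .roi import ROISpec, dv_difference, mann_whitney, roi_count
from .segmentation import (
    FilterParams,
    SegmentationParams,
    match_to_truth,
    preprocess_stack,
    segment_nuclei,
)
from .synthetic import generate_nuclear_stack


@dataclass
class RunConfig:
    """Validated pipeline configuration (explicit seeds; no wall-clock seeding)."""

    genotypes: list[str]
    n_embryos: int = 3
    seed: int = 1
    sides: list[str] = field(default_factory=lambda: ["dorsal", "ventral"])
    field_px: tuple[int, int] = (220, 220)
    n_slices: int = 12
    cell_size: float = 4.0
    out_dir: str = "runs/out"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genotypes:
            get_preset(g)  # raises for unknown presets
        if self.n_embryos < 0:
            raise ValueError("n_embryos must be non-negative")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an explicit integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "field_px" in raw:
            raw["field_px"] = tuple(raw["field_px"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _embryo_seed(base_seed: int, genotype: str, side: str, index: int) -> int:
    """Deterministic per-embryo seed below 2^31."""
    h = hashlib.sha256(f"{base_seed}:{genotype}:{side}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _field_landmarks(field_um: tuple[float, float], rng: np.random.Generator) -> LandmarkSet:
    """Embryo landmarks of a mounted surface view, with placement jitter."""
    w, h = field_um
    j = lambda: rng.normal(0.0, 0.01 * min(w, h))
    return LandmarkSet(
        anterior_pole=(0.04 * w + j(), h / 2 + j()),
        posterior_pole=(0.96 * w + j(), h / 2 + j()),
        lateral_left=(w / 2 + j(), 0.06 * h + j()),
        lateral_right=(w / 2 + j(), 0.94 * h + j()),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute synthesize → segment → register → density/hotspot → counts.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    Any stage failure aborts with the failing stage named; artifacts written
    so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "outputs": [],
        "stats": {},
    }
    stage = "init"

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["outputs"].append(str(path))
        return path

    try:
        counts: dict[str, dict[str, list[int]]] = {}
        for genotype in config.genotypes:
            preset = get_preset(genotype)
            per_side_rasters: dict[str, list] = {s: [] for s in config.sides}
            ref_landmarks: dict[str, LandmarkSet] = {}
            counts[genotype] = {s: [] for s in config.sides}
            for side in config.sides:
                fp = FilterParams.dorsal() if side == "dorsal" else FilterParams.ventral()
                sp = SegmentationParams.dorsal() if side == "dorsal" else SegmentationParams.ventral()
                band = DISTANCE_BAND_DORSAL if side == "dorsal" else DISTANCE_BAND_VENTRAL
                for i in range(config.n_embryos):
                    seed = _embryo_seed(config.seed, genotype, side, i)
                    stage = f"synthesize[{genotype}/{side}/{i}]"
                    stack, truth = generate_nuclear_stack(
                        preset, side=side, field_px=config.field_px,
                        n_slices=config.n_slices, seed=seed,
                    )
                    stage = f"segment[{genotype}/{side}/{i}]"
                    records = segment_nuclei(preprocess_stack(stack, fp), sp)
                    recall, precision, _ = match_to_truth(records, truth)
                    df = io.records_to_frame(records)
                    _write(f"{genotype}_{side}_{i}_centroids.csv", lambda p, df=df: df.to_csv(p, index=False))
                    stage = f"register[{genotype}/{side}/{i}]"
                    rng = np.random.default_rng([seed, 99])
                    field_um = (config.field_px[0] * UM_PER_PX, config.field_px[1] * UM_PER_PX)
                    lms = _field_landmarks(field_um, rng)
                    if i == 0:
                        ref_landmarks[side] = lms
                        tf = None
                    else:
                        tf = fit_landmark_transform(lms, ref_landmarks[side])
                    xy = df[["x_um", "y_um"]].to_numpy() if len(df) else np.empty((0, 2))
                    if tf is not None and len(xy):
                        xy = tf.apply(xy)
                    stage = f"density[{genotype}/{side}/{i}]"
                    mask = surface_mask(xy, aggregation_distance=30.0 * UM_PER_PX) if len(xy) else None
                    raster = kernel_density(
                        xy, mask=mask, cell_size=config.cell_size,
                        origin=(0.0, 0.0),
                        shape=(
                            int(np.ceil(field_um[1] / config.cell_size)),
                            int(np.ceil(field_um[0] / config.cell_size)),
                        ),
                    )
                    per_side_rasters[side].append(raster)
                    stage = f"counts[{genotype}/{side}/{i}]"
                    if len(xy):
                        counts[genotype][side].append(roi_count(xy, ROISpec.midline(xy)))
                    else:
                        counts[genotype][side].append(0)
                    manifest["stats"].setdefault("segmentation", []).append(
                        {
                            "genotype": genotype, "side": side, "embryo": i,
                            "n_truth": len(truth), "n_detected": len(records),
                            "recall": recall, "precision": precision,
                        }
                    )
                    stage = f"hotspot[{genotype}/{side}/{i}]"
                    if len(xy) >= 2:
                        pts_px = xy / UM_PER_PX  # raster units (px) as banded distances
                        grid_origin = tuple(np.floor(pts_px.min(axis=0) / GRID_EDGE) * GRID_EDGE)
                        hmap = hotspot_analysis(
                            pts_px, cell_edge=GRID_EDGE, distance_band=band, origin=grid_origin
                        )
                        hot = int(np.sum(np.char.startswith(hmap.category.astype(str), "hot")))
                        cold = int(np.sum(np.char.startswith(hmap.category.astype(str), "cold")))
                        manifest["stats"].setdefault("hotspots", []).append(
                            {"genotype": genotype, "side": side, "embryo": i, "hot": hot, "cold": cold}
                        )
                stage = f"average[{genotype}/{side}]"
                if per_side_rasters[side]:
                    avg = average_rasters(per_side_rasters[side])
                    _write(f"{genotype}_{side}_avg_density.tif", lambda p, avg=avg: io.write_raster(p, avg))
        stage = "dv_statistics"
        dv_stats = {}
        for genotype, side_counts in counts.items():
            if "dorsal" in side_counts and "ventral" in side_counts and side_counts["dorsal"]:
                diffs = [
                    dv_difference(d, v)
                    for d, v in zip(side_counts["dorsal"], side_counts["ventral"])
                ]
                dv_stats[genotype] = {
                    "dorsal_counts": side_counts["dorsal"],
                    "ventral_counts": side_counts["ventral"],
                    "dv_differences": diffs,
                }
        genos = [g for g in dv_stats if dv_stats[g]["dv_differences"]]
        for i in range(len(genos)):
            for j in range(i + 1, len(genos)):
                a, b = genos[i], genos[j]
                if len(dv_stats[a]["dv_differences"]) and len(dv_stats[b]["dv_differences"]):
                    res = mann_whitney(dv_stats[a]["dv_differences"], dv_stats[b]["dv_differences"])
                    dv_stats[f"mw_{a}_vs_{b}"] = {"U": res.statistic, "p": res.p, "method": res.method}
        manifest["stats"]["dv"] = dv_stats
    except Exception as exc:  # persist partial outputs, name the stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
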