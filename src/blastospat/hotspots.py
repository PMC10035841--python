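"""Getis–Ord Gi* hot/cold-spot classification of gridded nuclear centroids.

Centroids are binned into square grid cells (default edge 20 raster units);
for each cell i, with binary weights w_ij = 1 iff the centroid-to-centroid
distance is within a fixed band d (self included — Gi*, not Gi):

    z_i = [Σ_j w_ij x_j − X̄ W_i] / ( S · sqrt((n Σ_j w_ij² − W_i²) / (n−1)) )

where X̄ and S are the global mean and *population* SD of the cell counts,
W_i = Σ_j w_ij and n the number of grid cells (the standard 1995 local
statistic).  Cells are classed hot/cold at the 90/95/99% two-sided normal
confidence levels.  The documented band defaults are 50 (denser dorsal
surface) and 120 (ventral) in raster units; no multiplicity correction is
applied by default, matching the GIS tool's raw confidence classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import false_discovery_control, norm

DISTANCE_BAND_DORSAL = 50.0
DISTANCE_BAND_VENTRAL = 120.0
GRID_EDGE = 20.0

#: two-sided standard-normal quantiles for the three confidence tiers.
Z_90, Z_95, Z_99 = 1.645, 1.960, 2.576

CATEGORIES = ("cold99", "cold95", "cold90", "NS", "hot90", "hot95", "hot99")


@dataclass
class GridCounts:
    """Point counts on a square grid; ``counts[iy, ix]``."""

    origin: tuple[float, float]
    cell_edge: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.size)

    @property
    def cell_centers(self) -> np.ndarray:
        ny, nx = self.counts.shape
        iy, ix = np.mgrid[0:ny, 0:nx]
        x = self.origin[0] + (ix + 0.5) * self.cell_edge
        y = self.origin[1] + (iy + 0.5) * self.cell_edge
        return np.column_stack([x.ravel(), y.ravel()])


@dataclass
class HotspotMap:
    """Per-grid-cell Gi* z-scores and confidence-class labels."""

    grid: GridCounts
    z: np.ndarray
    distance_band: float
    category: np.ndarray | None = None
    p: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.distance_band <= 0:
            raise ValueError("distance band must be positive")


def grid_bin(
    points: np.ndarray,
    cell_edge: float = GRID_EDGE,
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
) -> GridCounts:
    """Bin points into half-open square cells ``[k·e, (k+1)·e)`` by floor division.

    A point exactly on a cell boundary belongs to the higher-index cell.  When
    ``shape`` is omitted the grid tightly covers the points (all-zero 1×1 grid
    for an empty set).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) if np.size(points) else np.empty((0, 2))
    ix = np.floor((pts[:, 0] - origin[0]) / cell_edge).astype(int) if len(pts) else np.empty(0, int)
    iy = np.floor((pts[:, 1] - origin[1]) / cell_edge).astype(int) if len(pts) else np.empty(0, int)
    if shape is None:
        nx = int(ix.max()) + 1 if len(pts) else 1
        ny = int(iy.max()) + 1 if len(pts) else 1
        if len(pts) and (ix.min() < 0 or iy.min() < 0):
            raise ValueError("points fall below the grid origin")
    else:
        ny, nx = shape
        keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ix, iy = ix[keep], iy[keep]
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    return GridCounts(origin=origin, cell_edge=cell_edge, counts=counts)


def gi_star(grid: GridCounts, distance_band: float = DISTANCE_BAND_DORSAL) -> HotspotMap:
    """Gi* z-score per grid cell with binary fixed-distance-band weights."""
    x = grid.counts.ravel().astype(float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 grid cells")
    if not np.any(x):
        raise ValueError("need at least one non-zero count")
    xbar = x.mean()
    s = float(np.sqrt((x**2).mean() - xbar**2))  # population SD
    centers = grid.cell_centers
    w = (cdist(centers, centers) <= distance_band).astype(float)  # includes self
    if s == 0.0:
        warnings.warn("all grid counts equal; Gi* undefined, z set to 0", stacklevel=2)
        z = np.zeros(n)
    else:
        wx = w @ x
        wsum = w.sum(axis=1)
        w2sum = (w**2).sum(axis=1)
        denom = s * np.sqrt((n * w2sum - wsum**2) / (n - 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(denom > 0, (wx - xbar * wsum) / denom, 0.0)
    return HotspotMap(grid=grid, z=z.reshape(grid.counts.shape), distance_band=distance_band)


def classify(hmap: HotspotMap, fdr: bool = False) -> HotspotMap:
    """Fill confidence-class labels from the z-scores.

    |z| ≥ 2.576 → 99%, ≥ 1.960 → 95%, ≥ 1.645 → 90%, else NS; the sign gives
    hot vs cold.  ``fdr=True`` applies a Benjamini–Hochberg correction to the
    two-sided p-values before classing (off by default: the raw confidence
    classes are reported, as in the source tool).
    """
    z = hmap.z.ravel()
    p = 2.0 * norm.sf(np.abs(z))
    if fdr:
        p_eff = false_discovery_control(p, method="bh")
    else:
        p_eff = p
    cat = np.full(z.shape, "NS", dtype=object)
    tiers = ((0.01, "99"), (0.05, "95"), (0.10, "90"))
    assigned = np.zeros(z.shape, dtype=bool)
    for alpha, label in tiers:
        sel = (~assigned) & (p_eff <= alpha)
        cat[sel & (z > 0)] = f"hot{label}"
        cat[sel & (z < 0)] = f"cold{label}"
        assigned |= sel
    return HotspotMap(
        grid=hmap.grid,
        z=hmap.z,
        distance_band=hmap.distance_band,
        category=cat.reshape(hmap.z.shape),
        p=p.reshape(hmap.z.shape),
    )


def hotspot_analysis(
    points: np.ndarray,
    cell_edge: float = GRID_EDGE,
    distance_band: float = DISTANCE_BAND_DORSAL,
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
    fdr: bool = False,
) -> HotspotMap:
    """Convenience chain: grid_bin → gi_star → classify."""
    return classify(gi_star(grid_bin(points, cell_edge, origin, shape), distance_band), fdr=fdr)
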