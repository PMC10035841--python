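"""Landmark registration, kernel-density heatmaps, contours and raster averaging.

Embryos are registered into a common frame by a least-squares similarity
transform over four landmarks (anterior/posterior poles and the two
lateral-most points).  Densities are quartic-kernel (GIS-style) surfaces
rasterized on a fixed grid, masked to the aggregated point footprint, and
averaged cellwise per genotype.  The display stretch bounds (0.002 / 0.0105)
and the contour interval (0.0005) are configuration constants for rendering,
not physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint
from shapely.ops import unary_union

from .datatypes import DensityRaster

#: default display-stretch bounds and contour interval (densities per raster unit²).
STRETCH_LOW = 0.002
STRETCH_HIGH = 0.0105
CONTOUR_INTERVAL = 0.0005

#: default aggregation distance for the surface mask, raster units.
AGGREGATION_DISTANCE = 30.0


@dataclass(frozen=True)
class LandmarkSet:
    """Four registration landmarks, (x, y) μm."""

    anterior_pole: tuple[float, float]
    posterior_pole: tuple[float, float]
    lateral_left: tuple[float, float]
    lateral_right: tuple[float, float]

    def __post_init__(self) -> None:
        pts = self.as_array()
        if len(np.unique(pts, axis=0)) != 4:
            raise ValueError("landmarks must be 4 distinct points")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.anterior_pole, self.posterior_pole, self.lateral_left, self.lateral_right],
            dtype=float,
        )


@dataclass(frozen=True)
class SimilarityTransform:
    """p' = scale · R(rotation) · p + (tx, ty); no shear, no reflection."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]
    residual: float = 0.0  # RMS landmark misfit after alignment

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        m_inv = np.linalg.inv(self.matrix)
        t = -m_inv @ np.asarray(self.translation)
        return SimilarityTransform(
            scale=1.0 / self.scale, rotation=-self.rotation, translation=(t[0], t[1])
        )


class DegenerateLandmarksError(ValueError):
    pass


def fit_landmark_transform(moving: LandmarkSet, reference: LandmarkSet) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``moving`` onto ``reference``.

    Umeyama-style closed form over the 4 correspondences.  Raises
    :class:`DegenerateLandmarksError` for collinear landmarks or when the
    optimal map would require a reflection (not in the transform family).
    """
    a = moving.as_array()
    b = reference.as_array()
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - mu_a, b - mu_b
    var_a = (ac**2).sum() / len(a)
    cov = bc.T @ ac / len(a)
    u, d, vt = np.linalg.svd(cov)
    if d[-1] / max(d[0], 1e-300) < 1e-9:
        raise DegenerateLandmarksError("landmarks are (near-)collinear")
    sign = np.sign(np.linalg.det(u @ vt))
    if sign < 0:
        raise DegenerateLandmarksError("best landmark fit requires a reflection")
    rot_mat = u @ vt
    scale = float(d.sum() / var_a)
    rotation = math.atan2(rot_mat[1, 0], rot_mat[0, 0])
    t = mu_b - scale * rot_mat @ mu_a
    tf = SimilarityTransform(scale=scale, rotation=rotation, translation=(float(t[0]), float(t[1])))
    resid = float(np.sqrt(((tf.apply(a) - b) ** 2).sum(axis=1).mean()))
    return SimilarityTransform(
        scale=tf.scale, rotation=tf.rotation, translation=tf.translation, residual=resid
    )


def surface_mask(points: np.ndarray, aggregation_distance: float = AGGREGATION_DISTANCE):
    """Dissolved union of point buffers; the embryo-surface footprint polygon."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        return MultiPoint([]).buffer(0)
    return unary_union(MultiPoint(pts).buffer(aggregation_distance))


def silverman_bandwidth(points: np.ndarray) -> float:
    """Rule-of-thumb kernel radius: 0.9 · min(SD, IQR/1.34) · n^(-1/5) per axis, pooled."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n < 2:
        return 1.0
    sd = pts.std(axis=0, ddof=1).mean()
    q75, q25 = np.percentile(pts, [75, 25], axis=0)
    iqr = (q75 - q25).mean()
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return max(0.9 * spread * n ** (-1 / 5), 1e-6)


def kernel_density(
    points: np.ndarray,
    mask="auto",
    cell_size: float = 2.0,
    bandwidth: float | None = None,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> DensityRaster:
    """Quartic-kernel density raster of a point set, clipped to a mask.

    The kernel is ``K(d) = (3 / (π R²)) (1 - (d/R)²)²`` for ``d < R`` (unit
    mass), summed over points and evaluated at cell centres; values are points
    per unit area.  ``mask`` is a shapely geometry, ``"auto"`` (aggregate the
    points at the default aggregation distance) or ``None`` (unmasked).  The
    grid either spans the mask/point bounds or is pinned by an explicit
    ``origin``/``shape`` (for cross-embryo averaging).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) if np.size(points) else np.empty((0, 2))
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts) if len(pts) else 1.0
    r = float(bandwidth)
    if isinstance(mask, str) and mask == "auto":
        mask = surface_mask(pts) if len(pts) else None
    if origin is None or shape is None:
        if mask is not None and not mask.is_empty:
            minx, miny, maxx, maxy = mask.bounds
        elif len(pts):
            minx, miny = pts.min(axis=0) - r
            maxx, maxy = pts.max(axis=0) + r
        else:
            minx = miny = 0.0
            maxx = maxy = cell_size
        origin = (minx, miny)
        shape = (
            int(math.ceil((maxy - miny) / cell_size)),
            int(math.ceil((maxx - minx) / cell_size)),
        )
    ny, nx = shape
    values = np.zeros((ny, nx), dtype=float)
    xc = origin[0] + (np.arange(nx) + 0.5) * cell_size
    yc = origin[1] + (np.arange(ny) + 0.5) * cell_size
    norm = 3.0 / (math.pi * r**2)
    for px, py in pts:
        ix0 = max(0, int((px - r - origin[0]) / cell_size))
        ix1 = min(nx, int((px + r - origin[0]) / cell_size) + 1)
        iy0 = max(0, int((py - r - origin[1]) / cell_size))
        iy1 = min(ny, int((py + r - origin[1]) / cell_size) + 1)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        d2 = ((xc[ix0:ix1][None, :] - px) ** 2 + (yc[iy0:iy1][:, None] - py) ** 2) / r**2
        contrib = np.where(d2 < 1.0, norm * (1.0 - d2) ** 2, 0.0)
        values[iy0:iy1, ix0:ix1] += contrib
    if mask is not None and not mask.is_empty:
        xx, yy = np.meshgrid(xc, yc)
        inside = shapely.contains_xy(mask, xx.ravel(), yy.ravel()).reshape(ny, nx)
        values = np.where(inside, values, np.nan)
    return DensityRaster(origin=origin, cell_size=cell_size, values=values, mask=mask)


def contour_raster(raster: DensityRaster, interval: float = CONTOUR_INTERVAL) -> dict[float, list[np.ndarray]]:
    """Iso-density polylines at integer multiples of ``interval``.

    Returns a mapping level → list of (k, 2) arrays of (x, y) coordinates in
    the raster's frame.  A constant raster yields no contours.
    """
    from skimage import measure

    vals = raster.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return {}
    lo, hi = float(finite.min()), float(finite.max())
    if hi <= lo:
        return {}
    levels = np.arange(math.floor(lo / interval) + 1, math.ceil(hi / interval)) * interval
    work = np.where(np.isfinite(vals), vals, lo - interval)  # mask edge closes contours
    out: dict[float, list[np.ndarray]] = {}
    for lev in levels:
        if lev <= lo or lev >= hi:
            continue
        lines = measure.find_contours(work, lev)
        if not lines:
            continue
        converted = []
        for ln in lines:
            x = raster.origin[0] + (ln[:, 1] + 0.5) * raster.cell_size
            y = raster.origin[1] + (ln[:, 0] + 0.5) * raster.cell_size
            converted.append(np.column_stack([x, y]))
        out[float(lev)] = converted
    return out


def average_rasters(rasters: list[DensityRaster]) -> DensityRaster:
    """Cellwise mean of co-registered rasters; mask = intersection of masks."""
    if not rasters:
        raise ValueError("need at least one raster")
    first = rasters[0]
    for r in rasters[1:]:
        if r.values.shape != first.values.shape or r.cell_size != first.cell_size:
            raise ValueError("rasters must share an identical grid")
        if not np.allclose(r.origin, first.origin):
            raise ValueError("rasters must share an identical origin")
    stack = np.stack([r.values for r in rasters])
    defined = np.all(np.isfinite(stack), axis=0)
    mean = np.where(defined, np.nanmean(stack, axis=0), np.nan)
    mask = first.mask
    for r in rasters[1:]:
        if mask is not None and r.mask is not None:
            mask = mask.intersection(r.mask)
    return DensityRaster(origin=first.origin, cell_size=first.cell_size, values=mean, mask=mask)
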