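"""Synthetic blastoderm-embryo generator.

Produces every input the analysis pipeline consumes, with exact ground truth:

* 3D nuclear z-stacks of one mounted embryo surface (dorsal or ventral), with
  nuclei from an inhomogeneous hard-core point process on an ellipsoid-cap
  height field, rendered as 3D Gaussian blobs with Poisson + Gaussian noise;
* 2D membrane-labelled images of polygonal apical cells (Voronoi tessellation
  of variable-radius hard-core seeds) with optional junctional gaps;
* cross-section images with nuclei around an annulus carrying a Gaussian
  D/V intensity gradient (DL ventrally, pMAD dorsally);
* developmental expression time-course matrices with planted genes similar to
  a reference receptor profile.

Determinism: every generator derives all randomness from
``np.random.default_rng([seed, STREAM_ID])`` so that identical (preset, seed)
pairs are bit-identical and the component streams are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry import box as shapely_box

from .datatypes import UM_PER_PX, Z_STEP_UM, MembraneTruth, NucleusTruth, VoxelStack, shoelace_area
from .presets import GenotypePreset

# documented seed-splitting rule: rng = default_rng([seed, STREAM[component]])
STREAM = {"nuclei": 1, "membrane": 2, "section": 3, "timecourse": 4}

#: minimum distance between nucleus centres, μm (approximate blastoderm
#: internuclear spacing; a generator constant, not a measured value).  On top
#: of this floor the sampler enforces non-interpenetration of the rendered
#: nuclei: centres of nuclei with radii r_i, r_j stay at least
#: ``max(HARD_CORE_UM, 0.95 * (r_i + r_j))`` apart, since nuclei are solid.
HARD_CORE_UM = 2.5
NUCLEUS_OVERLAP_SLACK = 0.95

#: mean nuclear radius and its SD, μm.
NUCLEUS_RADIUS_UM = 2.1
NUCLEUS_RADIUS_SD = 0.12

#: axial elongation of blastoderm nuclei: at cellularization they are columnar,
#: roughly 2.5x longer along the apical-basal (z) axis than wide.
NUCLEUS_Z_ELONGATION = 2.5

#: rendering photometry (12-bit counts) and noise model: Poisson shot noise on
#: the rendered signal plus additive Gaussian read noise.
BACKGROUND = 60.0
NUCLEUS_AMPLITUDE = 1100.0
READ_NOISE_SD = 15.0

#: A/P positions (normalized u) of the seven ftz stripes used as landmarks.
FTZ_STRIPES = np.linspace(0.18, 0.86, 7)
FTZ_STRIPE_HALFWIDTH = 0.025


class GenerationError(RuntimeError):
    """Raised when a preset's density cannot be realized."""


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), STREAM[component]])


# ---------------------------------------------------------------------------
# nuclear stacks
# ---------------------------------------------------------------------------


def _sample_hardcore_points(
    density: "callable",
    width_um: float,
    height_um: float,
    rng: np.random.Generator,
    radii: "callable" = None,
    hard_core: float = HARD_CORE_UM,
    oversample: int = 10,
    preset_name: str = "?",
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing sampler for an inhomogeneous hard-core process.

    ``density(u, v)`` is in points per 100 μm²; u = x / width, v = 2y/height - 1.
    ``radii(n)`` draws nucleus radii; accepted nuclei keep centre distance
    ≥ ``max(hard_core, NUCLEUS_OVERLAP_SLACK * (r_i + r_j))``.  Raises
    :class:`GenerationError` if the expected count cannot be placed within
    ``oversample`` times as many proposals.  Returns (points, radii).
    """
    if radii is None:
        radii = lambda n: np.clip(rng.normal(NUCLEUS_RADIUS_UM, NUCLEUS_RADIUS_SD, size=n), 1.7, 2.6)
    # expected count from the intensity integral (midpoint rule on a fine grid)
    gu = np.linspace(0.0, 1.0, 101)
    gv = np.linspace(-1.0, 1.0, 101)
    uu, vv = np.meshgrid(gu, gv)
    dens = density(uu, vv) / 100.0  # per μm²
    lam_max = float(dens.max())
    expected = float(dens.mean()) * width_um * height_um
    if expected <= 0 or lam_max <= 0:
        return np.empty((0, 2)), np.empty(0)
    n_target = int(rng.poisson(expected))
    if n_target == 0:
        return np.empty((0, 2)), np.empty(0)

    r_draw = radii(n_target)
    accepted: list[tuple[float, float]] = []
    acc_r: list[float] = []
    pts = np.empty((0, 2))
    tries = 0
    max_tries = oversample * max(n_target, 1)
    while len(accepted) < n_target and tries < max_tries:
        tries += 1
        x = rng.uniform(0.0, width_um)
        y = rng.uniform(0.0, height_um)
        if rng.uniform() * lam_max > float(density(x / width_um, 2.0 * y / height_um - 1.0)) / 100.0:
            continue
        r = float(r_draw[len(accepted)])
        if accepted:
            d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
            lim = np.maximum(hard_core, NUCLEUS_OVERLAP_SLACK * (np.asarray(acc_r) + r))
            if np.any(d2 < lim**2):
                continue
        accepted.append((x, y))
        acc_r.append(r)
        pts = np.asarray(accepted)
    if len(accepted) < n_target:
        raise GenerationError(
            f"preset {preset_name!r}: could not place {n_target} nuclei with "
            f"hard core {hard_core} μm within {max_tries} proposals"
        )
    return pts, np.asarray(acc_r)


def _cap_depth(x_um: np.ndarray, y_um: np.ndarray, width_um: float, height_um: float, depth_um: float) -> np.ndarray:
    """Depth below the top of the stack of the ellipsoid-cap surface.

    The mounted surface is the upper cap of an ellipsoid seen in the image
    plane: shallow at the field centre, receding toward the field borders.
    ``depth_um`` is the depth reached at the field corners.
    """
    xn = (x_um - width_um / 2.0) / (0.78 * width_um)
    yn = (y_um - height_um / 2.0) / (0.78 * height_um)
    r2 = np.clip(xn**2 + yn**2, 0.0, 1.0)
    corner = math.sqrt(min(1.0, (0.5 / 0.78) ** 2 * 2.0))
    scale = 1.0 - math.sqrt(1.0 - min(1.0, corner**2))
    return depth_um * (1.0 - np.sqrt(1.0 - r2)) / max(scale, 1e-9)


def generate_nuclear_stack(
    preset: GenotypePreset,
    side: str = "dorsal",
    field_px: tuple[int, int] = (220, 220),
    n_slices: int = 12,
    seed: int | None = None,
    voxel_size: tuple[float, float, float] = (UM_PER_PX, UM_PER_PX, Z_STEP_UM),
) -> tuple[VoxelStack, list[NucleusTruth]]:
    """Render a nuclear z-stack of one embryo surface plus ground truth.

    Nuclei are placed by an inhomogeneous hard-core point process following
    the preset's density field for ``side``, sit on an ellipsoid-cap height
    map, and are rendered as 3D Gaussian blobs (σ ≈ radius/2) on a noisy
    background.  Returns the calibrated stack and one
    :class:`~blastospat.datatypes.NucleusTruth` per rendered nucleus.
    """
    w_px, h_px = field_px
    if w_px > 1024 or h_px > 1024:
        raise ValueError("field_px must be at most 1024×1024")
    if n_slices < 1:
        raise ValueError("n_slices must be ≥ 1")
    dx, dy, dz = voxel_size
    rng = _rng(preset.seed if seed is None else seed, "nuclei")
    width_um, height_um = w_px * dx, h_px * dy
    depth_um = n_slices * dz

    xy, radii = _sample_hardcore_points(
        preset.density(side), width_um, height_um, rng, preset_name=preset.name
    )
    n = len(xy)
    truths: list[NucleusTruth] = []
    img = np.full((n_slices, h_px, w_px), BACKGROUND, dtype=float)

    if n:
        depth = _cap_depth(xy[:, 0], xy[:, 1], width_um, height_um, 0.55 * depth_um)
        z_um = np.clip(depth + rng.normal(0.0, 0.35, size=n) + 2.4, 1.0, depth_um - 1.0)
        amps = rng.normal(NUCLEUS_AMPLITUDE, 80.0, size=n)
        u = xy[:, 0] / width_um
        ftz = np.min(np.abs(u[:, None] - FTZ_STRIPES[None, :]), axis=1) <= FTZ_STRIPE_HALFWIDTH

        zz = (np.arange(n_slices) + 0.5) * dz
        for i in range(n):
            x, y = xy[i]
            sx = sy = radii[i] / 2.0
            sz = NUCLEUS_Z_ELONGATION * radii[i] / 2.0
            # render within ±3σ
            ix0 = max(0, int((x - 3 * sx) / dx))
            ix1 = min(w_px, int((x + 3 * sx) / dx) + 1)
            iy0 = max(0, int((y - 3 * sy) / dy))
            iy1 = min(h_px, int((y + 3 * sy) / dy) + 1)
            iz0 = max(0, int((z_um[i] - 3 * sz) / dz))
            iz1 = min(n_slices, int((z_um[i] + 3 * sz) / dz) + 1)
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
            gx = np.exp(-(((np.arange(ix0, ix1) + 0.5) * dx - x) ** 2) / (2 * sx**2))
            gy = np.exp(-(((np.arange(iy0, iy1) + 0.5) * dy - y) ** 2) / (2 * sy**2))
            gz = np.exp(-((zz[iz0:iz1] - z_um[i]) ** 2) / (2 * sz**2))
            img[iz0:iz1, iy0:iy1, ix0:ix1] += amps[i] * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            truths.append(
                NucleusTruth(
                    id=i,
                    center=(float(x), float(y), float(z_um[i])),
                    radius=float(radii[i]),
                    markers={"ftz_positive": bool(ftz[i])},
                )
            )

    noisy = rng.poisson(np.clip(img, 0, None)).astype(float) + rng.normal(0.0, READ_NOISE_SD, size=img.shape)
    values = np.clip(np.round(noisy), 0, 4095).astype(np.uint16)
    stack = VoxelStack(values=values, voxel_size=voxel_size, channel="nuclei")
    return stack, truths


def paint_marker_stack(
    stack: VoxelStack,
    truths: list[NucleusTruth],
    marker: str = "ftz_positive",
    intensity: float = 200.0,
    background: float = 5.0,
) -> VoxelStack:
    """Render a marker channel: bright prolate nuclei where the marker is on.

    The painted ellipsoid matches the rendered nuclear shape (z semi-axis
    elongated by :data:`NUCLEUS_Z_ELONGATION`) so that segmented voxel sets
    sample mostly marker signal for positive nuclei.
    """
    nz, ny, nx = stack.shape
    dx, dy, dz = stack.voxel_size
    img = np.full((nz, ny, nx), background, dtype=float)
    zz = (np.arange(nz) + 0.5) * dz
    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    for t in truths:
        if not t.markers.get(marker, False):
            continue
        x, y, z = t.center
        r = t.radius
        rz = NUCLEUS_Z_ELONGATION * r
        mask = (
            ((zz[:, None, None] - z) / rz) ** 2
            + ((yy[None, :, None] - y) / r) ** 2
            + ((xx[None, None, :] - x) / r) ** 2
        ) <= 1.0
        img[mask] = intensity
    return VoxelStack(values=img, voxel_size=stack.voxel_size, channel=marker)


# ---------------------------------------------------------------------------
# membrane images
# ---------------------------------------------------------------------------


def _membrane_seeds(
    n: int, width_um: float, height_um: float, areas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Variable-radius dart throwing: local spacing tracks each cell's target area.

    The exclusion factor sits safely below the random-sequential-adsorption
    jamming limit; subsequent Lloyd iterations regularize the tessellation.
    """
    radii = 0.67 * np.sqrt(areas / math.pi)
    order = rng.permutation(n)
    cell = 2.0 * float(radii.max())
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    rr = np.empty(n)
    max_tries = 800 * n
    tries = 0
    i = 0
    while i < n and tries < max_tries:
        tries += 1
        x = rng.uniform(0.0, width_um)
        y = rng.uniform(0.0, height_um)
        r = radii[order[i]]
        gx, gy = int(x / cell), int(y / cell)
        clash = False
        for dgx in (-1, 0, 1):
            for dgy in (-1, 0, 1):
                for j in grid.get((gx + dgx, gy + dgy), ()):
                    if (pts[j, 0] - x) ** 2 + (pts[j, 1] - y) ** 2 < (rr[j] + r) ** 2:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if clash:
            continue
        pts[i] = (x, y)
        rr[i] = r
        grid.setdefault((gx, gy), []).append(i)
        i += 1
    if i < n:
        raise GenerationError(f"could not place {n} membrane seeds (target areas too large for field)")
    return pts[:n]


def _lloyd_relax(seeds: np.ndarray, width_um: float, height_um: float, iterations: int = 2) -> np.ndarray:
    """Move each seed to its clipped-Voronoi-cell centroid (centroidal tessellation)."""
    pts = seeds.copy()
    for _ in range(iterations):
        cells = _voronoi_cells(pts, width_um, height_um)
        if len(cells) != len(pts):  # degenerate clipping; keep previous layout
            break
        new = np.array([ShapelyPolygon(c).centroid.coords[0] for c in cells])
        pts = new
    return pts


def _voronoi_cells(seeds: np.ndarray, width_um: float, height_um: float) -> list[np.ndarray]:
    """Clipped Voronoi tessellation of the field via boundary mirroring."""
    mirrored = [seeds]
    for ax, lim in ((0, 0.0), (0, width_um), (1, 0.0), (1, height_um)):
        m = seeds.copy()
        m[:, ax] = 2.0 * lim - m[:, ax]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    field = shapely_box(0.0, 0.0, width_um, height_um)
    cells: list[np.ndarray] = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # cannot occur with mirroring; guard anyway
            continue
        poly = ShapelyPolygon(vor.vertices[region])
        poly = poly.intersection(field)
        if poly.is_empty or poly.geom_type != "Polygon":
            continue
        cells.append(np.asarray(poly.exterior.coords[:-1]))
    return cells


def generate_membrane_image(
    preset: GenotypePreset,
    side: str = "dorsal",
    stage: str = "late",
    field_px: tuple[int, int] = (260, 260),
    seed: int | None = None,
    um_per_px: float = UM_PER_PX,
    gap_prob: float | None = None,
) -> tuple[np.ndarray, MembraneTruth]:
    """Render a membrane-labelled apical view plus ground-truth polygons.

    Cells are a Voronoi tessellation whose mean area equals the preset target
    for ``(side, stage)`` with approximately lognormal scatter (CV ≈ area_cv);
    membranes are bright anti-aliased ridges with junctional gaps dropped at
    rate ``membrane_gap_prob`` (override with ``gap_prob``).
    """
    w_px, h_px = field_px
    rng = _rng(preset.seed if seed is None else seed, "membrane")
    width_um, height_um = w_px * um_per_px, h_px * um_per_px
    target = preset.target_area(side, stage)
    field_area = width_um * height_um
    n = int(round(field_area / target))
    if n < 4:
        raise GenerationError("target mean area too large for the field")
    cv = preset.area_cv
    sigma_ln = math.sqrt(math.log(1.0 + cv**2))
    areas = target * np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln, size=n))
    seeds = _membrane_seeds(n, width_um, height_um, areas, rng)
    seeds = _lloyd_relax(seeds, width_um, height_um, iterations=1)
    polygons = _voronoi_cells(seeds, width_um, height_um)
    truth = MembraneTruth(
        polygons=polygons,
        areas=np.array([shoelace_area(p) for p in polygons]),
        group=side,
    )

    p_gap = preset.membrane_gap_prob if gap_prob is None else gap_prob
    edge = np.zeros((h_px, w_px), dtype=float)
    from skimage.draw import line_aa

    drawn: set[tuple[int, int, int, int]] = set()
    for poly in polygons:
        k = len(poly)
        for j in range(k):
            a = poly[j] / um_per_px
            b = poly[(j + 1) % k] / um_per_px
            key = (int(round(a[0] * 8)), int(round(a[1] * 8)), int(round(b[0] * 8)), int(round(b[1] * 8)))
            rkey = key[2:] + key[:2]
            if key in drawn or rkey in drawn:
                continue
            drawn.add(key)
            rr, cc, val = line_aa(
                int(np.clip(round(a[1]), 0, h_px - 1)),
                int(np.clip(round(a[0]), 0, w_px - 1)),
                int(np.clip(round(b[1]), 0, h_px - 1)),
                int(np.clip(round(b[0]), 0, w_px - 1)),
            )
            if p_gap > 0:
                drop = rng.uniform(size=len(rr)) < p_gap
                # widen drops into contiguous junctional gaps
                drop = ndi.binary_dilation(drop, iterations=2)
                keep = ~drop
                rr, cc, val = rr[keep], cc[keep], val[keep]
            np.maximum.at(edge, (rr, cc), val)

    img = BACKGROUND + 160.0 * ndi.gaussian_filter(edge, 0.8)
    noisy = rng.poisson(np.clip(img, 0, None)).astype(float) + rng.normal(0.0, READ_NOISE_SD, size=img.shape)
    image = np.clip(np.round(noisy), 0, 4095).astype(np.uint16)
    return image, truth


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------


def generate_cross_section(
    preset: GenotypePreset,
    channel: str = "dl",
    n_nuclei_per_arc: int = 40,
    seed: int | None = None,
    radius_um: float = 60.0,
    um_per_px: float = UM_PER_PX,
    noise_frac: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an embryo cross-section with a nuclear D/V intensity gradient.

    Nuclei sit around an annulus; each nucleus' intensity is the preset's
    ``dl`` or ``pmad`` Gaussian gradient evaluated at its arc position ``v``
    (0 at the relevant midline: ventral for DL, dorsal for pMAD) times
    ``1 + noise_frac·ε``.  Returns the image and a truth table with columns
    ``v, x_um, y_um, true_mean, rendered_mean``.
    """
    grad = preset.dl_gradient if channel == "dl" else preset.pmad_gradient
    rng = _rng(preset.seed if seed is None else seed, "section")
    n = int(n_nuclei_per_arc)
    # nuclei tile the annulus: evenly spaced arc positions with small jitter,
    # v ∈ (-1, 1] measured from the relevant midline
    spacing = 2.0 / n
    v = -1.0 + (np.arange(n) + 0.5) * spacing + rng.uniform(-0.15, 0.15, size=n) * spacing
    v = np.sort(v)
    # angle: v=0 at the midline (bottom of the image for both channels)
    theta = v * math.pi
    size_um = 2.0 * radius_um + 24.0
    npx = int(round(size_um / um_per_px))
    cx = cy = size_um / 2.0
    x = cx + radius_um * np.sin(theta)
    y = cy + radius_um * np.cos(theta)
    true_mean = grad(v)
    amp = true_mean * (1.0 + (noise_frac * rng.standard_normal(n) if noise_frac > 0 else 0.0))

    # nuclei rendered as flat-intensity disks so that a fixed-area ROI well
    # inside a nucleus measures its intensity exactly
    img = np.full((npx, npx), 2.0, dtype=float)
    r_nuc = NUCLEUS_RADIUS_UM + 0.4
    for i in range(n):
        ix0 = max(0, int((x[i] - r_nuc) / um_per_px) - 1)
        ix1 = min(npx, int((x[i] + r_nuc) / um_per_px) + 2)
        iy0 = max(0, int((y[i] - r_nuc) / um_per_px) - 1)
        iy1 = min(npx, int((y[i] + r_nuc) / um_per_px) + 2)
        xs = (np.arange(ix0, ix1) + 0.5) * um_per_px - x[i]
        ys = (np.arange(iy0, iy1) + 0.5) * um_per_px - y[i]
        disk = (ys[:, None] ** 2 + xs[None, :] ** 2) <= r_nuc**2
        sub = img[iy0:iy1, ix0:ix1]
        np.maximum(sub, np.where(disk, amp[i], sub), out=sub)

    truth = pd.DataFrame(
        {"v": v, "x_um": x, "y_um": y, "true_mean": true_mean, "rendered_mean": amp}
    )
    return img, truth


# ---------------------------------------------------------------------------
# expression time courses
# ---------------------------------------------------------------------------

KEYWORDS_RELEVANT = ("cell migration", "cell adhesion", "cytoskeleton regulation")
KEYWORDS_DECOY = ("metabolism", "chromatin", "proteolysis", "transport", "splicing")


def default_reference_profile(n_stages: int = 30) -> np.ndarray:
    """A receptor-like developmental profile: embryonic peak plus pupal shoulder."""
    s = np.linspace(0.0, 1.0, n_stages)
    return 25.0 + 260.0 * np.exp(-(((s - 0.22) / 0.16) ** 2)) + 140.0 * np.exp(-(((s - 0.72) / 0.18) ** 2))


@dataclass
class TimecourseTruth:
    similar: np.ndarray  # boolean per gene
    annotations: pd.DataFrame  # gene, keywords (";"-joined), dv_asymmetric


def generate_expression_timecourse(
    n_genes: int = 101,
    n_stages: int = 30,
    reference_profile: np.ndarray | None = None,
    n_planted_similar: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
    frac_planted_annotated: float = 1.0,
) -> tuple[pd.DataFrame, TimecourseTruth]:
    """Expression matrix (genes × stages) with planted reference-like genes.

    Planted genes are the reference profile times a random positive scale plus
    relative Gaussian noise of SD ``noise_sd``; decoys are independent smooth
    random profiles.  The reference itself is included as gene ``"ref"``.
    Returns the matrix and per-gene truth (similar flag, keyword annotations,
    D/V-asymmetry flag).
    """
    rng = _rng(seed, "timecourse")
    ref = default_reference_profile(n_stages) if reference_profile is None else np.asarray(reference_profile, float)
    n_stages = len(ref)
    stages = [f"stage_{i:02d}" for i in range(n_stages)]
    if n_planted_similar > n_genes - 1:
        raise ValueError("cannot plant more similar genes than decoy slots")

    rows: dict[str, np.ndarray] = {"ref": ref.copy()}
    similar_flags = {"ref": False}
    n_decoys = n_genes - 1 - n_planted_similar
    for i in range(n_planted_similar):
        scale = float(np.exp(rng.normal(0.0, 0.3)))
        prof = scale * ref * (1.0 + noise_sd * rng.standard_normal(n_stages))
        rows[f"planted_{i:03d}"] = np.clip(prof, 0.0, None)
        similar_flags[f"planted_{i:03d}"] = True
    for i in range(n_decoys):
        knots = rng.uniform(5.0, 300.0, size=5)
        prof = np.interp(np.linspace(0, 4, n_stages), np.arange(5), knots)
        prof = prof * (1.0 + 0.05 * rng.standard_normal(n_stages))
        rows[f"decoy_{i:03d}"] = np.clip(prof, 0.0, None)
        similar_flags[f"decoy_{i:03d}"] = False

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    genes = matrix.index.to_numpy()
    similar = np.array([similar_flags[g] for g in genes])

    kw: list[str] = []
    dv: list[bool] = []
    for g, sim in zip(genes, similar):
        if sim and rng.uniform() < frac_planted_annotated:
            picks = rng.choice(len(KEYWORDS_RELEVANT), size=rng.integers(1, 3), replace=False)
            kw.append(";".join(KEYWORDS_RELEVANT[int(j)] for j in sorted(picks)))
            dv.append(True)
        else:
            picks = rng.choice(len(KEYWORDS_DECOY), size=2, replace=False)
            # a minority of decoys carry relevant-looking annotation
            words = [KEYWORDS_DECOY[int(j)] for j in sorted(picks)]
            if rng.uniform() < 0.15:
                words.append(KEYWORDS_RELEVANT[int(rng.integers(0, 3))])
            kw.append(";".join(words))
            dv.append(bool(rng.uniform() < 0.3))
    ann = pd.DataFrame({"gene": genes, "keywords": kw, "dv_asymmetric": dv}).set_index("gene")
    ann.loc["ref", ["keywords", "dv_asymmetric"]] = [";".join(KEYWORDS_RELEVANT), True]
    return matrix, TimecourseTruth(similar=similar, annotations=ann)
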