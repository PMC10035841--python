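"""Midline ROI cell counts and the two nonparametric tests used throughout.

The canonical midline ROI is a 300 × 100-pixel rectangle (156.14 × 52.04 μm at
0.5205 μm/px) centred on the projected surface centroid and aligned with the
A/P axis.  ROI inclusion is half-open (a point on the maximum edge is outside)
so that disjoint tilings partition points exactly.

Both rank tests are exact by total enumeration whenever that is feasible
(≤ 10⁶ arrangements for Mann–Whitney, n ≤ 20 pairs for Wilcoxon) and fall
back to the tie- and continuity-corrected normal approximation otherwise.
Two-tailed exact p = 2 · min(P(T ≤ t), P(T ≥ t)), capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .datatypes import UM_PER_PX

#: default midline ROI, μm (300 × 100 px at 0.5205 μm/px).
ROI_WIDTH_UM = 156.14
ROI_HEIGHT_UM = 52.04

MAX_EXACT_ARRANGEMENTS = 1_000_000
MAX_EXACT_WILCOXON_N = 20


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle: ``center`` (x, y) μm, ``width`` along A/P."""

    center: tuple[float, float]
    width: float = ROI_WIDTH_UM
    height: float = ROI_HEIGHT_UM

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI dimensions must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        return (cx - self.width / 2, cy - self.height / 2, cx + self.width / 2, cy + self.height / 2)

    @classmethod
    def midline(cls, points: np.ndarray, **kw) -> "ROISpec":
        """Default ROI centred on the centroid of a projected point set."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = pts.mean(axis=0)
        return cls(center=(float(c[0]), float(c[1])), **kw)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # U (Mann–Whitney) or W+ (Wilcoxon)
    p: float  # two-tailed
    method: str  # "exact" | "normal-approx"
    n1: int
    n2: int | None = None  # None for paired tests

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def roi_count(centroids: np.ndarray, roi: ROISpec) -> int:
    """Number of centroids inside the rectangle (half-open on the max edges)."""
    pts = np.atleast_2d(np.asarray(centroids, dtype=float)) if np.size(centroids) else np.empty((0, 2))
    if len(pts) == 0:
        return 0
    x0, y0, x1, y1 = roi.bounds
    inside = (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
    return int(inside.sum())


def dv_difference(dorsal_count: int, ventral_count: int) -> int:
    """Dorsal minus ventral midline cell count."""
    return int(dorsal_count) - int(ventral_count)


def _two_tailed(cdf_le: float, cdf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def mann_whitney(a, b) -> RankTestResult:
    """Two-tailed Mann–Whitney U test (midrank ties; exact when feasible)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u = min(u1, n1 * n2 - u1)  # reported statistic: smaller U
    has_ties = len(np.unique(pooled)) < n1 + n2

    if not has_ties and n1 + n2 <= 60:
        # exact tie-free null distribution of U by rank-sum counting
        # (coefficients of the Gaussian binomial polynomial)
        m = n1 + n2
        max_u = n1 * n2
        f = np.zeros((n1 + 1, max_u + 1))
        f[0, 0] = 1.0
        for rank in range(1, m + 1):
            for k in range(min(rank, n1), 0, -1):
                # adding pooled rank ``rank`` as the k-th member of sample 1
                # raises U by rank - k
                shift = rank - k
                if shift == 0:
                    f[k] += f[k - 1]
                elif shift <= max_u:
                    f[k, shift:] += f[k - 1, : max_u + 1 - shift]
        dist = f[n1] / f[n1].sum()
        t = int(round(u1))
        p = _two_tailed(dist[: t + 1].sum(), dist[t:].sum())
        return RankTestResult(statistic=float(u), p=p, method="exact", n1=n1, n2=n2)

    if math.comb(n1 + n2, n1) <= MAX_EXACT_ARRANGEMENTS:
        # enumerate which pooled positions form sample 1; midranks fixed,
        # so ties are handled exactly
        total = 0
        le = 0
        ge = 0
        const = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - const
            total += 1
            if u_perm <= u1:
                le += 1
            if u_perm >= u1:
                ge += 1
        p = _two_tailed(le / total, ge / total)
        return RankTestResult(statistic=float(u), p=p, method="exact", n1=n1, n2=n2)

    # normal approximation with tie and continuity corrections
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(statistic=float(u), p=1.0, method="normal-approx", n1=n1, n2=n2)
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankTestResult(statistic=float(u), p=p, method="normal-approx", n1=n1, n2=n2)


def wilcoxon_signed_rank(pairs) -> RankTestResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    ``pairs`` is either an (n, 2) array of pairs or a 1D array of differences.
    Zero differences are dropped; W = sum of positive ranks.  Exact p by
    enumerating all 2ⁿ sign assignments (dynamic program over doubled
    midranks) for n ≤ 20, else normal approximation.
    """
    arr = np.asarray(pairs, dtype=float)
    d = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= MAX_EXACT_WILCOXON_N:
        # distribution of 2·W over sign assignments: polynomial product DP
        r2 = np.round(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        dist /= dist.sum()
        t = int(round(2 * w_pos))
        p = _two_tailed(dist[: t + 1].sum(), dist[t:].sum())
        return RankTestResult(statistic=w_pos, p=p, method="exact", n1=n)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankTestResult(statistic=w_pos, p=p, method="normal-approx", n1=n)


def domain_width_counts(
    centroids: np.ndarray, positive: np.ndarray, strip: ROISpec
) -> int:
    """Marker-positive centroids inside a D/V-oriented strip (one embryo).

    ``positive`` is a boolean flag per centroid (e.g. from marker-channel
    intensity redirection); the count feeds per-genotype Mann–Whitney
    comparisons of expression-domain widths.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float)) if np.size(centroids) else np.empty((0, 2))
    pos = np.asarray(positive, dtype=bool)
    if len(pos) != len(pts):
        raise ValueError("positive flags must match centroids")
    if len(pts) == 0:
        return 0
    return roi_count(pts[pos], strip)


def px_to_um(px: float) -> float:
    """Convert a pixel length to μm at the fixed 0.5205 μm/px calibration."""
    return px * UM_PER_PX
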