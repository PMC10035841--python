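"""Morphogen-gradient quantification along the D/V axis.

Nuclear intensity profiles are extracted from cross-section (or projected)
images by averaging a fixed-area ROI inside each nucleus, ordered from the
relevant midline — by default the 30 ventral-most nuclei for the DL gradient
(~10 μm² ROIs) and the 18 dorsal-most cells for pMAD (10.4 μm² ROIs).
Profiles are fit with a four-parameter Gaussian ``a + b·exp(−(x−c)²/2σ²)``
(nonlinear least squares, moment-based initialization) or, for E-CAD, an
ordinary linear model; normalized profiles use the fitted baseline and
amplitude so single-nucleus outliers cannot distort the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .datatypes import UM_PER_PX

DL_N_NUCLEI = 30
DL_ROI_AREA_UM2 = 10.0
PMAD_N_CELLS = 18
PMAD_ROI_AREA_UM2 = 10.4


@dataclass
class IntensityProfile:
    """Mean nuclear intensity versus position along the D/V axis."""

    positions: np.ndarray  # arc position / cell index from the midline, strictly ordered
    means: np.ndarray
    sds: np.ndarray | None = None
    n_per_position: int = 1
    channel: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.positions) != len(self.means):
            raise ValueError("positions and means must align")


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    center: float
    sigma: float
    baseline: float
    r_squared: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.baseline + self.amplitude * np.exp(-((x - self.center) ** 2) / (2 * self.sigma**2))


def extract_profile(
    image: np.ndarray,
    positions_um: np.ndarray,
    arc_positions: np.ndarray,
    n_cells: int = DL_N_NUCLEI,
    roi_area_um2: float = DL_ROI_AREA_UM2,
    um_per_px: float = UM_PER_PX,
    channel: str = "dl",
) -> IntensityProfile:
    """Mean intensity in a fixed-area circular ROI inside each selected nucleus.

    ``positions_um`` are nucleus centres (x, y) μm in the image frame;
    ``arc_positions`` their signed arc positions from the relevant midline.
    The ``n_cells`` nuclei nearest the midline (smallest |arc|) are measured,
    ordered by arc position.
    """
    img = np.asarray(image, dtype=float)
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    arc = np.asarray(arc_positions, dtype=float)
    if len(pos) != len(arc):
        raise ValueError("positions and arc positions must align")
    sel = np.argsort(np.abs(arc))[: int(n_cells)]
    sel = sel[np.argsort(arc[sel])]
    r_px = np.sqrt(roi_area_um2 / np.pi) / um_per_px
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    means = np.empty(len(sel))
    sds = np.empty(len(sel))
    for i, j in enumerate(sel):
        cx, cy = pos[j] / um_per_px
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        vals = img[m]
        means[i] = vals.mean() if vals.size else np.nan
        sds[i] = vals.std() if vals.size else np.nan
    arcs = arc[sel]
    # guard against exact duplicates breaking strict ordering
    arcs = arcs + np.arange(len(arcs)) * 1e-12
    return IntensityProfile(positions=arcs, means=means, sds=sds, channel=channel)


def fit_gaussian(profile: IntensityProfile, maxfev: int = 10_000) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit of an intensity profile.

    Initialization: baseline = min, amplitude = max − min, center = argmax,
    sigma = FWHM / 2.355 (robust for unimodal profiles).  A failed or
    non-converged optimization returns the moment initialization flagged
    ``converged=False``.
    """
    x = profile.positions
    y = profile.means
    if len(x) < 5:
        raise ValueError("need at least 5 positions to fit a Gaussian")
    base0 = float(y.min())
    amp0 = float(y.max() - y.min())
    c0 = float(x[np.argmax(y)])
    above = x[y >= base0 + amp0 / 2.0]
    fwhm = float(above.max() - above.min()) if len(above) > 1 else float(x.max() - x.min()) / 4.0
    sig0 = max(fwhm / 2.355, 1e-3 * (x.max() - x.min() + 1e-9), 1e-9)

    def model(xx, a, b, c, s):
        return a + b * np.exp(-((xx - c) ** 2) / (2 * s**2))

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[base0, amp0 if amp0 > 0 else 1e-6, c0, sig0], maxfev=maxfev
        )
        a, b, c, s = popt
        converged = True
    except RuntimeError:
        a, b, c, s = base0, amp0, c0, sig0
        converged = False
    resid = y - model(x, a, b, c, s)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return GaussianFit(
        amplitude=float(b), center=float(c), sigma=abs(float(s)), baseline=float(a),
        r_squared=r2, converged=converged,
    )


def normalize_profile(profile: IntensityProfile, fit: GaussianFit | None = None) -> IntensityProfile:
    """Scale a profile to [0, 1] using the *fitted* baseline and amplitude.

    ``(I − baseline) / amplitude`` — affine-transformed copies of a profile
    normalize to identical curves, and normalizing twice equals normalizing
    once (the refit of a normalized profile has baseline ≈ 0, amplitude ≈ 1).
    """
    if fit is None:
        fit = fit_gaussian(profile)
    if fit.amplitude == 0:
        raise ValueError("zero fitted amplitude; cannot normalize")
    means = (profile.means - fit.baseline) / fit.amplitude
    sds = None if profile.sds is None else profile.sds / abs(fit.amplitude)
    return replace(profile, means=means, sds=sds)


def fit_linear(positions, intensities) -> tuple[float, float, float]:
    """Ordinary least squares line fit: returns (slope, intercept, R²)."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def membrane_intensity_transect(
    image: np.ndarray,
    start_um: tuple[float, float],
    end_um: tuple[float, float],
    n_samples: int = 200,
    um_per_px: float = UM_PER_PX,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated intensity along a line segment crossing a cell.

    Returns (distance along the segment in μm, intensity).  A transect from
    one side of a cell to the other shows two membrane peaks flanking the
    cytoplasmic trough.
    """
    img = np.asarray(image, dtype=float)
    p0 = np.asarray(start_um, dtype=float) / um_per_px
    p1 = np.asarray(end_um, dtype=float) / um_per_px
    t = np.linspace(0.0, 1.0, n_samples)
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    vals = ndi.map_coordinates(img, np.vstack([ys, xs]), order=1, mode="nearest")
    dist = t * np.linalg.norm(np.asarray(end_um) - np.asarray(start_um))
    return dist, vals
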