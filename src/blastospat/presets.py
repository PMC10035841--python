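"""Genotype presets driving the synthetic-embryo generator.

Each preset bundles the surface cell-density fields, apical-area targets,
membrane integrity and morphogen-gradient parameters that emulate one genotype
of the cellularizing Drosophila blastoderm:

* ``wt_early`` / ``wt_late`` — wild type at early/late cellularization. The
  dorsal density field has a midline maximum that strengthens with stage; in
  the late stage dorsal apical areas are 66% of ventral ones (dorsal cells 34%
  smaller).
* ``gd7`` — dorsalized mutant without a Dorsal (DL) nuclear gradient: flat
  density fields, no DL gradient, ubiquitous-DPP-like pMAD.
* ``dpp_minus`` — no DPP: the dorsal density increase and the pMAD gradient
  are absent, dorsal cells do not constrict.
* ``dpp_st2`` — dpp- rescued by an ectopic stripe of dpp expression: adds a
  density stripe around the eve-stripe-2 A/P position.
* ``fra`` / ``gukh`` — effector mutants: dorsal constriction is lost (dorsal
  apical areas 26% / 40% larger than wild-type dorsal), the dorsal density
  maximum is weakened, and membranes show fra-like junctional gaps.

Density magnitudes are anchored to the display range of the cell-density
heatmaps (0.002–0.0105 points per px² ≈ 0.7–3.9 nuclei per 100 μm²) and are
otherwise qualitative: only orderings (midline > poles, wt dorsal > mutant
dorsal, ...) are contractual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DensityField:
    """Surface density of nuclei, expected count per 100 μm².

    The field is evaluated at normalized A/P position ``u ∈ [0, 1]`` and D/V
    arc position ``v ∈ [-1, 1]`` (0 = the midline of the mounted surface):

    ``d(u, v) = (base + bump * exp(-(v/width)^2) + stripe(u)) * axial(u)``

    with ``axial(u) = 1 - axial_falloff * (2u - 1)^2`` modelling the drop of
    apparent density toward the embryo poles.
    """

    base: float
    bump: float = 0.0
    bump_width: float = 0.45
    axial_falloff: float = 0.3
    stripe_amp: float = 0.0
    stripe_center: float = 0.35
    stripe_width: float = 0.06

    def __call__(self, u, v):
        import numpy as np

        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        d = self.base + self.bump * np.exp(-((v / self.bump_width) ** 2))
        if self.stripe_amp:
            d = d + self.stripe_amp * np.exp(-(((u - self.stripe_center) / self.stripe_width) ** 2))
        d = d * (1.0 - self.axial_falloff * (2.0 * u - 1.0) ** 2)
        return np.maximum(d, 0.0)


@dataclass(frozen=True)
class GradientParams:
    """Gaussian morphogen gradient over D/V arc position ``v`` from its midline.

    ``I(v) = baseline + amplitude * exp(-(v - center)^2 / (2 sigma^2))``
    in arbitrary intensity units.
    """

    amplitude: float
    center: float
    sigma: float
    baseline: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, v):
        import numpy as np

        v = np.asarray(v, dtype=float)
        return self.baseline + self.amplitude * np.exp(-((v - self.center) ** 2) / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class GenotypePreset:
    name: str
    dorsal_density: DensityField
    ventral_density: DensityField
    area_dorsal_mean: float  # μm², late-stage dorsal apical area
    area_ventral_mean: float  # μm², ventral apical area (stage-constant)
    area_cv: float = 0.22
    membrane_gap_prob: float = 0.0
    dl_gradient: GradientParams = GradientParams(150.0, 0.0, 0.35, 20.0)
    pmad_gradient: GradientParams = GradientParams(120.0, 0.0, 0.18, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_dorsal_mean <= 0 or self.area_ventral_mean <= 0:
            raise ValueError("apical area means must be positive")
        if not (0.0 <= self.membrane_gap_prob <= 1.0):
            raise ValueError("membrane_gap_prob must lie in [0, 1]")

    def density(self, side: str) -> DensityField:
        if side == "dorsal":
            return self.dorsal_density
        if side == "ventral":
            return self.ventral_density
        raise ValueError(f"unknown side {side!r}")

    def target_area(self, side: str, stage: str = "late") -> float:
        """Target mean apical area (μm²) for a surface and stage.

        Ventral areas are stage-constant.  Dorsal cells constrict from the
        ventral-sized early value to ``area_dorsal_mean`` at the late stage,
        passing through their geometric mean at mid-stage.
        """
        if side == "ventral":
            return self.area_ventral_mean
        if side != "dorsal":
            raise ValueError(f"unknown side {side!r}")
        if stage == "late":
            return self.area_dorsal_mean
        if stage == "early":
            return self.area_ventral_mean
        if stage == "mid":
            return math.sqrt(self.area_dorsal_mean * self.area_ventral_mean)
        raise ValueError(f"unknown stage {stage!r}")


# Wild-type late-stage anchors: ventral apical area 40 μm²; the dorsal/ventral
# ratio is 0.66 so that dorsal cells are 34% smaller.  Mutant dorsal areas
# scale the wild-type late dorsal value (fra ×1.26, gukh ×1.40).
_WT_VENTRAL_AREA = 40.0
_WT_DORSAL_LATE_AREA = 0.66 * _WT_VENTRAL_AREA

PRESETS: dict[str, GenotypePreset] = {}


def _register(p: GenotypePreset) -> GenotypePreset:
    PRESETS[p.name] = p
    return p


WT_EARLY = _register(
    GenotypePreset(
        name="wt_early",
        dorsal_density=DensityField(base=1.8, bump=0.6, bump_width=0.5),
        ventral_density=DensityField(base=1.8),
        area_dorsal_mean=_WT_VENTRAL_AREA,  # not yet constricted
        area_ventral_mean=_WT_VENTRAL_AREA,
    )
)

WT_LATE = _register(
    GenotypePreset(
        name="wt_late",
        dorsal_density=DensityField(base=1.8, bump=1.6, bump_width=0.45),
        ventral_density=DensityField(base=1.5),
        area_dorsal_mean=_WT_DORSAL_LATE_AREA,
        area_ventral_mean=_WT_VENTRAL_AREA,
    )
)

GD7 = _register(
    GenotypePreset(
        name="gd7",
        dorsal_density=DensityField(base=2.4),
        ventral_density=DensityField(base=2.4),
        area_dorsal_mean=_WT_VENTRAL_AREA,
        area_ventral_mean=_WT_VENTRAL_AREA,
        dl_gradient=GradientParams(0.0, 0.0, 0.35, 20.0),
        pmad_gradient=GradientParams(60.0, 0.0, 0.9, 15.0),  # broad, DL-independent
    )
)

DPP_MINUS = _register(
    GenotypePreset(
        name="dpp_minus",
        dorsal_density=DensityField(base=2.0, bump=0.2, bump_width=0.5),
        ventral_density=DensityField(base=1.8),
        area_dorsal_mean=_WT_VENTRAL_AREA,  # no dorsal constriction without DPP
        area_ventral_mean=_WT_VENTRAL_AREA,
        pmad_gradient=GradientParams(0.0, 0.0, 0.18, 15.0),
    )
)

DPP_ST2 = _register(
    replace(
        DPP_MINUS,
        name="dpp_st2",
        dorsal_density=DensityField(base=2.0, bump=0.2, bump_width=0.5, stripe_amp=1.2),
    )
)

FRA = _register(
    GenotypePreset(
        name="fra",
        dorsal_density=DensityField(base=1.7, bump=0.5, bump_width=0.5),
        ventral_density=DensityField(base=1.8),
        area_dorsal_mean=1.26 * _WT_DORSAL_LATE_AREA,
        area_ventral_mean=_WT_VENTRAL_AREA,
        membrane_gap_prob=0.15,
        dl_gradient=GradientParams(110.0, 0.0, 0.50, 20.0),  # flattened, broader peak
    )
)

GUKH = _register(
    GenotypePreset(
        name="gukh",
        dorsal_density=DensityField(base=1.7, bump=0.5, bump_width=0.5),
        ventral_density=DensityField(base=1.8),
        area_dorsal_mean=1.40 * _WT_DORSAL_LATE_AREA,
        area_ventral_mean=_WT_VENTRAL_AREA,
        membrane_gap_prob=0.08,
        dl_gradient=GradientParams(115.0, 0.0, 0.45, 20.0),
    )
)


def get_preset(name: str, seed: int | None = None) -> GenotypePreset:
    """Look up a preset by name, optionally rebinding its seed."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    if seed is not None:
        p = replace(p, seed=seed)
    return p
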