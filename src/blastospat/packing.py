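"""Hexagonal-packing displacement calculus.

Links the apical-area shrinkage of a row of regularly packed hexagonal cells
to the distance it pulls its neighbours.  A regular hexagon that loses a
fraction ``s`` of its area scales every linear dimension by ``√(1−s)``, so a
single constricting row dislodges

    f_v = 1 − √(1−s)          (fraction of an unshrunk, ventral-sized diameter)
    f_d = f_v / √(1−s)        (fraction of the shrunken, dorsal diameter)

and ``round(1 / f_v)`` constricting rows pull one full ventral-cell diameter.
At the measured dorsal shrinkage s = 0.34 this gives f_v ≈ 0.188, f_d ≈ 0.231
and 5 rows per cell diameter.  Which linear dimension plays the role of the
"diameter" is immaterial: uniform scaling affects them all identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PackingResult:
    shrink_fraction: float
    displacement_ventral: float  # f_v, fraction of the unshrunk diameter
    displacement_dorsal: float  # f_d, fraction of the post-shrink diameter
    rows_to_one_diameter: int


def displacement_from_shrinkage(s: float) -> tuple[float, float]:
    """Row displacement fractions (f_v, f_d) for an area shrinkage ``s`` ∈ [0, 1)."""
    if not 0.0 <= s < 1.0:
        raise ValueError("shrink fraction must lie in [0, 1)")
    linear = math.sqrt(1.0 - s)
    f_v = 1.0 - linear
    f_d = f_v / linear
    return f_v, f_d


def rows_to_pull_one_diameter(s: float, rounding: str = "nearest") -> int:
    """Constricting rows needed to displace one ventral-cell diameter.

    ``rounding="nearest"`` (default, the "roughly" convention) or ``"ceil"``.
    """
    f_v, _ = displacement_from_shrinkage(s)
    if f_v <= 0.0:
        raise ValueError("zero shrinkage pulls nothing; rows undefined")
    rows = 1.0 / f_v
    if rounding == "nearest":
        return int(round(rows))
    if rounding == "ceil":
        return int(math.ceil(rows))
    raise ValueError("rounding must be 'nearest' or 'ceil'")


def packing_result(s: float, rounding: str = "nearest") -> PackingResult:
    """Full packing summary for an area shrinkage ``s``."""
    f_v, f_d = displacement_from_shrinkage(s)
    return PackingResult(
        shrink_fraction=s,
        displacement_ventral=f_v,
        displacement_dorsal=f_d,
        rows_to_one_diameter=rows_to_pull_one_diameter(s, rounding=rounding),
    )
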