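"""Heath-Carter anthropometric somatotyping and somatochart geometry.

The somatotype is a three-component description of physique: endomorphy
(relative adiposity), mesomorphy (relative musculoskeletal robustness) and
ectomorphy (relative linearity).  Each component is computed from a small
battery of anthropometric measures and floored at 0.1.  Somatotypes are
plotted on the two-dimensional somatochart via

    X = ectomorphy - endomorphy
    Y = 2 * mesomorphy - (endomorphy + ectomorphy)

and compared through two distances: the somatotype dispersion distance
SDD = sqrt(3 * dX^2 + dY^2) on the chart (the sqrt(3) weighting makes the
chart axes commensurate), and the somatotype attitudinal distance
SAD, the plain Euclidean distance in three-component space.  SDM and SAM are
their means over individuals relative to a reference (by default the group
mean somatotype).  Somatotypes are assigned to one of Carter's 13 categories
(central, three "balanced" types, six "X-ic Y" types, three edge types).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .anthropometry import AnthropometricProfile

__all__ = [
    "Somatotype",
    "SomatochartPoint",
    "DispersionSummary",
    "endomorphy",
    "mesomorphy",
    "ectomorphy",
    "compute_somatotype",
    "somatochart_xy",
    "sdd",
    "sdm",
    "sad",
    "sam",
    "dispersion_summary",
    "classify_somatotype",
    "mean_somatotype",
    "HEIGHT_CORRECTION_STATURE",
]

# Reference stature (cm) for the endomorphy height correction.
HEIGHT_CORRECTION_STATURE = 170.18

COMPONENT_FLOOR = 0.1


@dataclass(frozen=True)
class Somatotype:
    endomorphy: float
    mesomorphy: float
    ectomorphy: float

    def rounded(self, ndigits: int = 1) -> "Somatotype":
        return Somatotype(
            round(self.endomorphy, ndigits),
            round(self.mesomorphy, ndigits),
            round(self.ectomorphy, ndigits),
        )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.endomorphy, self.mesomorphy, self.ectomorphy)


@dataclass(frozen=True)
class SomatochartPoint:
    x: float
    y: float


@dataclass
class DispersionSummary:
    """Per-individual chart and component distances to a reference, plus means."""

    sdd_to_reference: list[float]
    sdm: float
    sad_to_reference: list[float]
    sam: float


def endomorphy(
    triceps_sf: float,
    subscapular_sf: float,
    supraspinale_sf: float,
    stature: float,
    height_correct: bool = True,
) -> float:
    """Endomorphy from the three-skinfold sum (mm), optionally height-corrected.

    The height correction scales the skinfold sum by 170.18 / stature-cm so
    that adiposity is rated relative to a common stature.
    """
    if stature <= 0:
        raise ValueError("stature must be positive")
    if min(triceps_sf, subscapular_sf, supraspinale_sf) <= 0:
        raise ValueError("skinfolds must be positive")
    s = triceps_sf + subscapular_sf + supraspinale_sf
    if height_correct:
        s *= HEIGHT_CORRECTION_STATURE / stature
    value = -0.7182 + 0.1451 * s - 0.00068 * s**2 + 0.0000014 * s**3
    return max(value, COMPONENT_FLOOR)


def mesomorphy(
    humerus_breadth: float,
    femur_breadth: float,
    flexed_arm_girth: float,
    triceps_sf: float,
    calf_girth: float,
    calf_sf: float,
    stature: float,
) -> float:
    """Mesomorphy from breadths and skinfold-corrected limb girths (all cm, sf mm)."""
    from .anthropometry import corrected_girth

    cag = corrected_girth(flexed_arm_girth, triceps_sf, "heath_carter")
    ccg = corrected_girth(calf_girth, calf_sf, "heath_carter")
    value = (
        0.858 * humerus_breadth
        + 0.601 * femur_breadth
        + 0.188 * cag
        + 0.161 * ccg
        - 0.131 * stature
        + 4.5
    )
    return max(value, COMPONENT_FLOOR)


def ectomorphy(body_mass: float, stature: float) -> float:
    """Ectomorphy from the height-weight ratio HWR = stature / mass^(1/3).

    Piecewise-linear in HWR; the upper branch applies for HWR >= 40.75, the
    middle branch on (38.25, 40.75), and the floor 0.1 at or below 38.25.
    """
    if body_mass <= 0 or stature <= 0:
        raise ValueError("mass and stature must be positive")
    hwr = stature / body_mass ** (1.0 / 3.0)
    if hwr >= 40.75:
        return 0.732 * hwr - 28.58
    if hwr > 38.25:
        return max(0.463 * hwr - 17.63, COMPONENT_FLOOR)
    return COMPONENT_FLOOR


def compute_somatotype(profile: "AnthropometricProfile") -> Somatotype:
    """Full Heath-Carter somatotype of a profile (height correction on)."""
    return Somatotype(
        endomorphy=endomorphy(
            profile.triceps, profile.subscapular, profile.supraspinale,
            profile.stature,
        ),
        mesomorphy=mesomorphy(
            profile.biepicondylar_humerus, profile.biepicondylar_femur,
            profile.flexed_arm, profile.triceps,
            profile.calf, profile.medial_calf,
            profile.stature,
        ),
        ectomorphy=ectomorphy(profile.body_mass, profile.stature),
    )


def somatochart_xy(s: Somatotype) -> SomatochartPoint:
    """Project a somatotype onto the somatochart plane."""
    return SomatochartPoint(
        x=s.ectomorphy - s.endomorphy,
        y=2.0 * s.mesomorphy - (s.endomorphy + s.ectomorphy),
    )


def sdd(a: SomatochartPoint, b: SomatochartPoint) -> float:
    """Somatotype dispersion distance between two somatoplots, in Y units."""
    return math.sqrt(3.0 * (a.x - b.x) ** 2 + (a.y - b.y) ** 2)


def sdm(individuals: Sequence[SomatochartPoint], reference: SomatochartPoint) -> float:
    """Somatotype dispersion mean: average SDD of each point to the reference."""
    if not individuals:
        raise ValueError("need at least one individual somatoplot")
    return sum(sdd(p, reference) for p in individuals) / len(individuals)


def sad(a: Somatotype, b: Somatotype) -> float:
    """Somatotype attitudinal distance: Euclidean in component space."""
    return math.sqrt(
        (a.endomorphy - b.endomorphy) ** 2
        + (a.mesomorphy - b.mesomorphy) ** 2
        + (a.ectomorphy - b.ectomorphy) ** 2
    )


def mean_somatotype(individuals: Iterable[Somatotype]) -> Somatotype:
    """Component-wise mean somatotype."""
    lst = list(individuals)
    if not lst:
        raise ValueError("need at least one somatotype")
    n = len(lst)
    return Somatotype(
        sum(s.endomorphy for s in lst) / n,
        sum(s.mesomorphy for s in lst) / n,
        sum(s.ectomorphy for s in lst) / n,
    )


def sam(
    individuals: Sequence[Somatotype], reference: Somatotype | None = None
) -> float:
    """Somatotype attitudinal mean: average SAD to the reference.

    The reference defaults to the component-wise mean somatotype of the list.
    """
    if not individuals:
        raise ValueError("need at least one somatotype")
    if reference is None:
        reference = mean_somatotype(individuals)
    return sum(sad(s, reference) for s in individuals) / len(individuals)


def dispersion_summary(
    individuals: Sequence[Somatotype], reference: Somatotype | None = None
) -> DispersionSummary:
    """SDD/SDM (chart) and SAD/SAM (component space) of a group vs a reference."""
    if not individuals:
        raise ValueError("need at least one somatotype")
    if reference is None:
        reference = mean_somatotype(individuals)
    ref_pt = somatochart_xy(reference)
    sdds = [sdd(somatochart_xy(s), ref_pt) for s in individuals]
    sads = [sad(s, reference) for s in individuals]
    return DispersionSummary(
        sdd_to_reference=sdds,
        sdm=sum(sdds) / len(sdds),
        sad_to_reference=sads,
        sam=sum(sads) / len(sads),
    )


_COMPONENT_NAMES = ("endomorph", "mesomorph", "ectomorph")
_ADJECTIVES = ("endomorphic", "mesomorphic", "ectomorphic")


def classify_somatotype(s: Somatotype) -> str:
    """Assign one of Carter's 13 somatotype categories.

    Decision rules operate on 1-dp rounded components, the resolution at
    which the categories are defined:

    1. *central* if no component differs from any other by more than 1.0;
    2. two highest components within 0.5 of each other and both above the
       third -> edge category "X-Y" (larger component first; exact ties
       resolve in chart order endomorph-mesomorph-ectomorph);
    3. otherwise the strictly dominant component X gives "balanced X" when
       the remaining two are within 0.5 of each other, else "Y-ic X" where
       Y is the second-ranked component.
    """
    comps = s.rounded(1).as_tuple()
    hi, lo = max(comps), min(comps)
    if hi - lo <= 1.0:
        return "central"
    # stable sort keeps chart order endo-meso-ecto on exact ties
    order = sorted(range(3), key=lambda i: -comps[i])
    first, second, third = order
    if comps[first] - comps[second] <= 0.5:
        return f"{_COMPONENT_NAMES[first]}-{_COMPONENT_NAMES[second]}"
    if comps[second] - comps[third] <= 0.5:
        return f"balanced {_COMPONENT_NAMES[first]}"
    return f"{_ADJECTIVES[second]} {_COMPONENT_NAMES[first]}"
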