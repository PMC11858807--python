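"""Anthropometric profiles and skinfold-based body composition.

Implements the derived quantities of a standard ISAK-style kinanthropometric
assessment: body mass index, body density from skinfold regression equations,
percent body fat from a density-to-fat conversion, skeletal (bone) mass from
breadth-based equations, appendicular muscle mass from the Lee et al.
anthropometric prediction equation, and the technical error of measurement
(TEM) for repeated measures.

Body density, fat conversion and bone mass equations live in small string-keyed
registries so that alternative published equations can be swapped in without
code changes; the defaults are widely used athlete-population equations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Callable

__all__ = [
    "AnthropometricProfile",
    "BodyComposition",
    "RepeatedMeasureSeries",
    "ValidationError",
    "PhysiologicRangeWarning",
    "bmi",
    "corrected_girth",
    "body_density",
    "percent_body_fat",
    "bone_mass",
    "muscle_mass_lee",
    "technical_error_of_measurement",
    "body_composition",
    "BODY_DENSITY_EQUATIONS",
    "FAT_CONVERSIONS",
    "BONE_MASS_EQUATIONS",
    "DEFAULT_BD_EQUATION",
]


class ValidationError(ValueError):
    """Raised for arithmetically impossible or structurally invalid inputs."""


class PhysiologicRangeWarning(UserWarning):
    """Emitted when a value is valid but outside typical physiologic ranges."""


SKINFOLD_SITES = (
    "pectoral",
    "triceps",
    "subscapular",
    "biceps",
    "suprailiac",
    "supraspinale",
    "abdominal",
    "front_thigh",
    "medial_calf",
)

GIRTH_SITES = (
    "neck",
    "relaxed_arm",
    "flexed_arm",
    "chest",
    "waist",
    "hip",
    "mid_thigh",
    "calf",
    "ankle",
)

BREADTH_SITES = (
    "biepicondylar_humerus",
    "bistyloid",
    "biepicondylar_femur",
    "bimalleolar",
)


@dataclass
class AnthropometricProfile:
    """The 26 raw ISAK measurements of one subject.

    Basic measures and girths/breadths are in cm, body mass in kg, skinfolds
    in mm.  Validation is warn-not-fail: values outside broad physiologic
    ranges raise :class:`PhysiologicRangeWarning` but only non-positive or
    arithmetically impossible values raise :class:`ValidationError` — athlete
    populations contain extreme but real measurements.
    """

    body_mass: float
    stature: float
    sitting_height: float
    arm_span: float
    # skinfolds, mm
    pectoral: float
    triceps: float
    subscapular: float
    biceps: float
    suprailiac: float
    supraspinale: float
    abdominal: float
    front_thigh: float
    medial_calf: float
    # girths, cm
    neck: float
    relaxed_arm: float
    flexed_arm: float
    chest: float
    waist: float
    hip: float
    mid_thigh: float
    calf: float
    ankle: float
    # breadths, cm
    biepicondylar_humerus: float
    bistyloid: float
    biepicondylar_femur: float
    bimalleolar: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{f.name} must be strictly positive, got {v!r}"
                )
        if not 100.0 <= self.stature <= 230.0:
            warnings.warn(
                f"stature {self.stature} cm outside [100, 230]",
                PhysiologicRangeWarning,
                stacklevel=2,
            )
        for site in SKINFOLD_SITES:
            v = getattr(self, site)
            if not 1.0 <= v <= 80.0:
                warnings.warn(
                    f"skinfold {site} = {v} mm outside [1, 80]",
                    PhysiologicRangeWarning,
                    stacklevel=2,
                )

    def skinfold_sum(self, sites: tuple[str, ...]) -> float:
        return float(sum(getattr(self, s) for s in sites))


@dataclass
class RepeatedMeasureSeries:
    """Two measurement passes of the same variable on the same subjects."""

    variable_id: str
    first_pass: list[float]
    second_pass: list[float]

    def __post_init__(self) -> None:
        if len(self.first_pass) != len(self.second_pass):
            raise ValidationError(
                f"{self.variable_id}: pass lengths differ "
                f"({len(self.first_pass)} vs {len(self.second_pass)})"
            )
        if len(self.first_pass) < 2:
            raise ValidationError(f"{self.variable_id}: need n >= 2 pairs")


@dataclass
class BodyComposition:
    """Derived body-composition quantities for one subject."""

    bmi: float              # kg/m^2
    body_density: float     # g/cm^3
    percent_body_fat: float  # %
    bone_mass: float        # kg
    muscle_mass: float      # kg
    equation_ids: dict[str, str] = field(default_factory=dict)


def bmi(body_mass: float, stature: float) -> float:
    """Body mass index, kg/m^2, from mass in kg and stature in cm."""
    if body_mass <= 0 or stature <= 0:
        raise ValidationError("body mass and stature must be positive")
    return body_mass / (stature / 100.0) ** 2


def corrected_girth(girth: float, skinfold: float, mode: str = "heath_carter") -> float:
    """Skinfold-corrected limb girth, cm.

    ``heath_carter`` subtracts the skinfold (converted mm -> cm) directly, as
    in the mesomorphy equation; ``lee`` subtracts pi times the skinfold,
    modelling the subcutaneous fat as an annulus around the muscle, as in the
    Lee muscle-mass equation.
    """
    sf_cm = skinfold / 10.0
    if mode == "heath_carter":
        out = girth - sf_cm
    elif mode == "lee":
        out = girth - math.pi * sf_cm
    else:
        raise ValidationError(f"unknown girth correction mode {mode!r}")
    if out <= 0:
        raise ValidationError(
            f"corrected girth non-positive ({girth} cm, {skinfold} mm, {mode})"
        )
    return out


# --- body density registry ------------------------------------------------
# Each entry maps a profile to g/cm^3.  Keys name the source population and
# skinfold battery, not a literature citation, so alternates can be registered
# at run time.

def _bd_male_athlete_7sf(profile: AnthropometricProfile) -> float:
    s7 = profile.skinfold_sum(
        ("triceps", "subscapular", "biceps", "supraspinale",
         "abdominal", "front_thigh", "medial_calf")
    )
    return 1.0988 - 0.0004 * s7


def _bd_female_athlete_4sf(profile: AnthropometricProfile) -> float:
    s4 = profile.skinfold_sum(("triceps", "subscapular", "supraspinale", "medial_calf"))
    return 1.20953 - 0.08294 * math.log10(s4)


BODY_DENSITY_EQUATIONS: dict[str, Callable[[AnthropometricProfile], float]] = {
    "male_athlete_7sf": _bd_male_athlete_7sf,
    "female_athlete_4sf_log": _bd_female_athlete_4sf,
}

DEFAULT_BD_EQUATION = {
    "male": "male_athlete_7sf",
    "female": "female_athlete_4sf_log",
}


def body_density(
    profile: AnthropometricProfile, sex: str, equation_id: str | None = None
) -> float:
    """Whole-body density, g/cm^3, from a registered skinfold equation."""
    sex = _norm_sex(sex)
    if equation_id is None:
        equation_id = DEFAULT_BD_EQUATION[sex]
    try:
        eq = BODY_DENSITY_EQUATIONS[equation_id]
    except KeyError:
        raise ValidationError(f"unknown body-density equation {equation_id!r}") from None
    return eq(profile)


# --- density -> fat conversion registry -----------------------------------

FAT_CONVERSIONS: dict[str, Callable[[float], float]] = {
    # Siri two-compartment conversion; the conventional default for both sexes
    "siri": lambda bd: 495.0 / bd - 450.0,
    # Brozek alternative, selectable per study convention
    "brozek": lambda bd: 457.0 / bd - 414.2,
}


def percent_body_fat(
    body_density: float, sex: str = "male", conversion_id: str = "siri"
) -> float:
    """Percent body fat from body density via a registered conversion."""
    _norm_sex(sex)
    if not 0.98 <= body_density <= 1.12:
        raise ValidationError(
            f"body density {body_density} g/cm^3 outside plausible [0.98, 1.12]"
        )
    try:
        conv = FAT_CONVERSIONS[conversion_id]
    except KeyError:
        raise ValidationError(f"unknown fat conversion {conversion_id!r}") from None
    return conv(body_density)


# --- bone (skeletal) mass registry ----------------------------------------

def _bone_von_dobeln_rocha(stature: float, bistyloid: float, femur: float) -> float:
    h = stature / 100.0
    r = bistyloid / 100.0
    f = femur / 100.0
    return 3.02 * (h * h * r * f * 400.0) ** 0.712


BONE_MASS_EQUATIONS: dict[str, Callable[[float, float, float], float]] = {
    "von_dobeln_rocha": _bone_von_dobeln_rocha,
}


def bone_mass(
    stature: float,
    bistyloid: float,
    biepicondylar_femur: float,
    equation_id: str = "von_dobeln_rocha",
) -> float:
    """Skeletal mass, kg, from stature and wrist/femur breadths (all cm)."""
    if min(stature, bistyloid, biepicondylar_femur) <= 0:
        raise ValidationError("bone-mass inputs must be positive")
    try:
        eq = BONE_MASS_EQUATIONS[equation_id]
    except KeyError:
        raise ValidationError(f"unknown bone-mass equation {equation_id!r}") from None
    return eq(stature, bistyloid, biepicondylar_femur)


def muscle_mass_lee(
    stature: float,
    age: float,
    sex: str,
    race_coeff: float,
    relaxed_arm_girth: float,
    triceps_sf: float,
    mid_thigh_girth: float,
    front_thigh_sf: float,
    calf_girth: float,
    calf_sf: float,
) -> float:
    """Total skeletal muscle mass, kg, from the Lee anthropometric equation.

    Limb girths (cm) are corrected by pi times the overlying skinfold (mm,
    converted to cm) to approximate the muscle circumference; stature enters
    in metres.  ``race_coeff`` is the published ethnicity adjustment and
    defaults to 0 in the pipeline.
    """
    sex_ind = 1.0 if _norm_sex(sex) == "male" else 0.0
    cag = corrected_girth(relaxed_arm_girth, triceps_sf, "lee")
    ctg = corrected_girth(mid_thigh_girth, front_thigh_sf, "lee")
    ccg = corrected_girth(calf_girth, calf_sf, "lee")
    ht_m = stature / 100.0
    return (
        ht_m * (0.00744 * cag**2 + 0.00088 * ctg**2 + 0.00441 * ccg**2)
        + 2.4 * sex_ind
        - 0.048 * age
        + race_coeff
        + 7.8
    )


def technical_error_of_measurement(
    series: RepeatedMeasureSeries,
) -> tuple[float, float]:
    """Absolute and relative (%) technical error of measurement.

    TEM = sqrt(sum(d^2) / 2n) over the paired inter-pass differences d;
    relative TEM expresses it as a percentage of the grand mean of all
    observations.
    """
    a = series.first_pass
    b = series.second_pass
    n = len(a)
    ssd = sum((x - y) ** 2 for x, y in zip(a, b))
    tem = math.sqrt(ssd / (2.0 * n))
    grand_mean = (sum(a) + sum(b)) / (2.0 * n)
    rel = 100.0 * tem / grand_mean if grand_mean != 0 else float("nan")
    return tem, rel


def body_composition(
    profile: AnthropometricProfile,
    sex: str,
    age: float,
    *,
    bd_equation_id: str | None = None,
    fat_conversion_id: str = "siri",
    bone_equation_id: str = "von_dobeln_rocha",
    race_coeff: float = 0.0,
) -> BodyComposition:
    """Full body-composition chain for one subject."""
    sex = _norm_sex(sex)
    bd = body_density(profile, sex, bd_equation_id)
    bf = percent_body_fat(bd, sex, fat_conversion_id)
    bm = bone_mass(
        profile.stature, profile.bistyloid, profile.biepicondylar_femur,
        bone_equation_id,
    )
    mm = muscle_mass_lee(
        profile.stature, age, sex, race_coeff,
        profile.relaxed_arm, profile.triceps,
        profile.mid_thigh, profile.front_thigh,
        profile.calf, profile.medial_calf,
    )
    return BodyComposition(
        bmi=bmi(profile.body_mass, profile.stature),
        body_density=bd,
        percent_body_fat=bf,
        bone_mass=bm,
        muscle_mass=mm,
        equation_ids={
            "body_density": bd_equation_id or DEFAULT_BD_EQUATION[sex],
            "fat_conversion": fat_conversion_id,
            "bone_mass": bone_equation_id,
        },
    )


def _norm_sex(sex: str) -> str:
    s = sex.strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    raise ValidationError(f"sex must be male/female, got {sex!r}")
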