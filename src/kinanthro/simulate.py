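"""Seeded synthetic athlete cohorts for end-to-end pipeline testing.

Real athlete anthropometry is rarely shareable, so the generator emulates the
statistical structure the analysis assumes: four groups (elite / non-elite x
male / female) of orienteering athletes, each raw measurement drawn as
mean + sd * z where z mixes three correlated latent factors — frame size,
adiposity, muscularity — with an independent residual.  Only raw inputs are
generated (measurements, questionnaire item responses, activity diaries);
every derived quantity (BMI, somatotype, MET scores...) must be produced by
the pipeline itself, which keeps tests non-circular.

Default group parameters are the published group means and standard
deviations of the elite/non-elite orienteering cohort the pipeline targets;
bone breadths and item-level questionnaire data, which that table does not
report, carry documented sex-typical defaults.  Out-of-bound draws are
resampled (not clipped) so configured means are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .questionnaires import DEFAULT_ANSWER_KEY, MET_WEIGHTS

__all__ = [
    "GroupSpec",
    "IPAQDomainSpec",
    "SyntheticCohort",
    "generate_cohort",
    "table1_default_specs",
    "ANTHRO_COLUMNS",
    "ANSKQ_COLUMNS",
    "IPAQ_COLUMNS",
]

ANTHRO_MEASURE_COLUMNS = [
    "mass_kg", "stature_cm", "sitting_height_cm", "arm_span_cm",
    "sf_pectoral_mm", "sf_triceps_mm", "sf_subscapular_mm", "sf_biceps_mm",
    "sf_suprailiac_mm", "sf_supraspinale_mm", "sf_abdominal_mm",
    "sf_front_thigh_mm", "sf_calf_mm",
    "g_neck_cm", "g_relaxed_arm_cm", "g_flexed_arm_cm", "g_chest_cm",
    "g_waist_cm", "g_hip_cm", "g_mid_thigh_cm", "g_calf_cm", "g_ankle_cm",
    "b_humerus_cm", "b_bistyloid_cm", "b_femur_cm", "b_bimalleolar_cm",
]
TRAINING_COLUMNS = ["age_y", "op_years", "otf_days_wk", "otq_h_wk"]
ANTHRO_COLUMNS = ["id", "sex", "ranking"] + TRAINING_COLUMNS + ANTHRO_MEASURE_COLUMNS
ANSKQ_COLUMNS = ["id"] + [f"q{i:02d}" for i in range(1, 36)]
IPAQ_COLUMNS = ["id", "vig_days", "vig_min", "mod_days", "mod_min",
                "walk_days", "walk_min", "sit_min"]

# Loadings of each measurement on (frame, adiposity, muscularity); the
# residual picks up the remaining unit variance.  Signs and rough magnitudes
# follow kinanthropometric common sense: skinfolds are adiposity, breadths
# and lengths are frame, limb girths mix frame/muscularity/adiposity.
_LOADINGS: dict[str, tuple[float, float, float]] = {
    "age_y": (0.0, 0.0, 0.0),
    "op_years": (0.0, 0.0, 0.0),
    "otf_days_wk": (0.0, 0.0, 0.0),
    "otq_h_wk": (0.0, 0.0, 0.0),
    "mass_kg": (0.55, 0.35, 0.35),
    "stature_cm": (0.85, 0.0, 0.0),
    "sitting_height_cm": (0.70, 0.0, 0.0),
    "arm_span_cm": (0.80, 0.0, 0.0),
    "sf_pectoral_mm": (0.0, 0.75, 0.0),
    "sf_triceps_mm": (0.0, 0.80, 0.0),
    "sf_subscapular_mm": (0.0, 0.80, 0.0),
    "sf_biceps_mm": (0.0, 0.70, 0.0),
    "sf_suprailiac_mm": (0.0, 0.75, 0.0),
    "sf_supraspinale_mm": (0.0, 0.75, 0.0),
    "sf_abdominal_mm": (0.0, 0.80, 0.0),
    "sf_front_thigh_mm": (0.0, 0.75, 0.0),
    "sf_calf_mm": (0.0, 0.70, 0.0),
    "g_neck_cm": (0.40, 0.20, 0.40),
    "g_relaxed_arm_cm": (0.25, 0.30, 0.60),
    "g_flexed_arm_cm": (0.25, 0.25, 0.65),
    "g_chest_cm": (0.40, 0.25, 0.50),
    "g_waist_cm": (0.30, 0.55, 0.25),
    "g_hip_cm": (0.35, 0.45, 0.30),
    "g_mid_thigh_cm": (0.25, 0.35, 0.55),
    "g_calf_cm": (0.25, 0.25, 0.60),
    "g_ankle_cm": (0.45, 0.10, 0.30),
    "b_humerus_cm": (0.65, 0.0, 0.20),
    "b_bistyloid_cm": (0.65, 0.0, 0.20),
    "b_femur_cm": (0.65, 0.0, 0.20),
    "b_bimalleolar_cm": (0.65, 0.0, 0.20),
}

# Resampling bounds (generator-side): hard validity limits of each input.
_BOUNDS: dict[str, tuple[float, float]] = {
    "age_y": (18.0, 65.0),
    "op_years": (0.5, 60.0),
    "otf_days_wk": (0.0, 7.0),
    "otq_h_wk": (0.0, 40.0),
    "mass_kg": (35.0, 150.0),
    "stature_cm": (100.0, 230.0),
    "sitting_height_cm": (60.0, 160.0),
    "arm_span_cm": (120.0, 230.0),
}
for _c in ANTHRO_MEASURE_COLUMNS:
    if _c.startswith("sf_"):
        _BOUNDS[_c] = (1.0, 80.0)
    elif _c.startswith("g_"):
        _BOUNDS.setdefault(_c, (10.0, 200.0))
    elif _c.startswith("b_"):
        _BOUNDS.setdefault(_c, (2.0, 20.0))


@dataclass
class IPAQDomainSpec:
    """Day-count and duration distributions for one IPAQ-SF activity domain."""

    days_mean: float
    days_sd: float
    minutes_sd: float
    met_share: float  # share of the group's target weekly MET-minutes


@dataclass
class GroupSpec:
    """Generating parameters for one sex x ranking group."""

    sex: str                      # "M" | "F"
    ranking: str                  # "elite" | "non_elite"
    n: int
    means: dict[str, float]       # raw-variable means, CSV column keys
    sds: dict[str, float]
    gnk_prob: float               # per-item correct probability, items 1-11
    snk_prob: float               # per-item correct probability, items 12-35
    met_target: float             # target mean total MET-min/week
    ipaq_domains: dict[str, IPAQDomainSpec] = field(default_factory=lambda: {
        "vigorous": IPAQDomainSpec(3.0, 1.5, 25.0, 0.50),
        "moderate": IPAQDomainSpec(2.5, 1.5, 25.0, 0.20),
        "walking": IPAQDomainSpec(5.0, 2.0, 25.0, 0.30),
    })
    sitting_mean: float = 420.0
    sitting_sd: float = 120.0
    size_adiposity_rho: float = 0.15
    size_muscularity_rho: float = 0.40

    @property
    def label(self) -> str:
        return f"{self.ranking}_{'male' if self.sex == 'M' else 'female'}"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for k in (self.gnk_prob, self.snk_prob):
            if not 0.0 <= k <= 1.0:
                raise ValueError("item probabilities must lie in [0, 1]")
        missing = [c for c in TRAINING_COLUMNS + ANTHRO_MEASURE_COLUMNS
                   if c not in self.means or c not in self.sds]
        if missing:
            raise ValueError(f"group {self.label}: missing mean/sd for {missing}")
        if any(self.sds[c] < 0 for c in self.sds):
            raise ValueError("standard deviations must be >= 0")
        for r in (self.size_adiposity_rho, self.size_muscularity_rho):
            if not -1.0 < r < 1.0:
                raise ValueError("latent correlations must lie in (-1, 1)")


@dataclass
class SyntheticCohort:
    """Generated cohort tables plus provenance; regenerable from (specs, seed)."""

    anthro: pd.DataFrame
    anskq: pd.DataFrame
    ipaq: pd.DataFrame
    seed: int
    group_labels: list[str]

    def write(self, out_dir) -> dict[str, str]:
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, df in (("anthro", self.anthro), ("anskq", self.anskq),
                         ("ipaq", self.ipaq)):
            path = os.path.join(out_dir, f"{name}.csv")
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


def _latent_cholesky(spec: GroupSpec) -> np.ndarray:
    c = np.array([
        [1.0, spec.size_adiposity_rho, spec.size_muscularity_rho],
        [spec.size_adiposity_rho, 1.0, 0.0],
        [spec.size_muscularity_rho, 0.0, 1.0],
    ])
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise ValueError("latent correlation matrix is not positive definite") from None


def _draw_measurements(spec: GroupSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Latent-factor draws with bound enforcement by resampling.

    Each variable's marginal is a truncated normal on its validity bounds
    whose location is calibrated so the *truncated* mean equals the
    configured mean (truncating an off-centre normal would otherwise bias
    it).  In-bound draws keep the latent correlation structure; out-of-bound
    draws are replaced by exact truncated-normal redraws, which is
    distributionally identical to resampling until valid.
    """
    corr = np.array([
        [1.0, spec.size_adiposity_rho, spec.size_muscularity_rho],
        [spec.size_adiposity_rho, 1.0, 0.0],
        [spec.size_muscularity_rho, 0.0, 1.0],
    ])
    chol = _latent_cholesky(spec)
    latents = rng.standard_normal((spec.n, 3)) @ chol.T
    cols = {}
    for col in TRAINING_COLUMNS + ANTHRO_MEASURE_COLUMNS:
        mean, sd = spec.means[col], spec.sds[col]
        lo, hi = _BOUNDS[col]
        if sd <= 0:
            cols[col] = np.full(spec.n, round(mean, 1))
            continue
        load = np.array(_LOADINGS[col])
        common_var = float(load @ corr @ load)
        resid_sd = math.sqrt(max(1.0 - common_var, 0.05))
        z = latents @ load + resid_sd * rng.standard_normal(spec.n)
        mu = _truncnorm_mu_for_mean(mean, sd, lo, hi)
        vals = mu + sd * z
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            a, b = (lo - mu) / sd, (hi - mu) / sd
            vals[bad] = sps.truncnorm.rvs(
                a, b, loc=mu, scale=sd, size=int(bad.sum()), random_state=rng
            )
        cols[col] = np.round(vals, 1)
    return pd.DataFrame(cols)


def _rounded_truncnorm_mean(mean: float, sd: float, lo: int, hi: int) -> float:
    """Mean of round(truncated normal on [lo-0.5, hi+0.5]) over integers lo..hi."""
    if sd <= 0:
        return float(round(mean))
    a, b = (lo - 0.5 - mean) / sd, (hi + 0.5 - mean) / sd
    dist = sps.truncnorm(a, b, loc=mean, scale=sd)
    ks = np.arange(lo, hi + 1)
    probs = dist.cdf(ks + 0.5) - dist.cdf(ks - 0.5)
    probs = probs / probs.sum()
    return float((ks * probs).sum())


def _truncnorm_mu_for_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean."""
    target = min(max(target, lo + 1e-6), hi - 1e-6)
    if sd <= 0:
        return target

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(sps.truncnorm.mean(a, b, loc=mu, scale=sd))

    lo_mu, hi_mu = lo - 10 * sd, hi + 10 * sd
    return brentq(lambda mu: trunc_mean(mu) - target, lo_mu, hi_mu, xtol=1e-6)


def _draw_int_truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    if sd <= 0:
        return np.full(n, round(mean), dtype=int)
    a, b = (lo - 0.5 - mean) / sd, (hi + 0.5 - mean) / sd
    draws = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws).astype(int), lo, hi)


_MIN_MINUTES, _MAX_MINUTES = 10, 240


def _draw_ipaq(spec: GroupSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Activity diaries whose expected total MET-min/week equals the target.

    Days are integer truncated normals; daily minutes are integer truncated
    normals on [10, 240] whose truncated mean is calibrated so that
    MET-weight x E[days] x E[minutes] hits each domain's share of the target
    (days and minutes are drawn independently, so the expectation factorises).
    """
    out = {}
    key_map = {"vigorous": "vig", "moderate": "mod", "walking": "walk"}
    for domain, d in spec.ipaq_domains.items():
        w = MET_WEIGHTS[domain]
        e_days = _rounded_truncnorm_mean(d.days_mean, d.days_sd, 0, 7)
        target_min = spec.met_target * d.met_share / (w * max(e_days, 0.1))
        mu = _truncnorm_mu_for_mean(target_min, d.minutes_sd,
                                    _MIN_MINUTES, _MAX_MINUTES)
        days = _draw_int_truncnorm(rng, spec.n, d.days_mean, d.days_sd, 0, 7)
        a = (_MIN_MINUTES - mu) / d.minutes_sd
        b = (_MAX_MINUTES - mu) / d.minutes_sd
        minutes = sps.truncnorm.rvs(a, b, loc=mu, scale=d.minutes_sd,
                                    size=spec.n, random_state=rng)
        minutes = np.clip(np.rint(minutes).astype(int), _MIN_MINUTES, _MAX_MINUTES)
        k = key_map[domain]
        out[f"{k}_days"] = days
        out[f"{k}_min"] = minutes
    out["sit_min"] = _draw_int_truncnorm(
        rng, spec.n, spec.sitting_mean, spec.sitting_sd, 0, 960
    )
    return pd.DataFrame(out)[[c for c in IPAQ_COLUMNS if c != "id"]]


_OPTIONS = "abcd"


def _draw_anskq(spec: GroupSpec, rng: np.random.Generator,
                answer_key=DEFAULT_ANSWER_KEY) -> pd.DataFrame:
    rows = []
    for _ in range(spec.n):
        answers = []
        for i in range(35):
            p = spec.gnk_prob if i < 11 else spec.snk_prob
            key = answer_key[i]
            if rng.random() < p:
                answers.append(key)
            else:
                wrong = [o for o in _OPTIONS if o != key]
                answers.append(wrong[rng.integers(len(wrong))])
        rows.append(answers)
    return pd.DataFrame(rows, columns=ANSKQ_COLUMNS[1:])


def generate_cohort(specs: list[GroupSpec], seed: int) -> SyntheticCohort:
    """Draw a full synthetic cohort; identical (specs, seed) give identical tables."""
    if not specs:
        raise ValueError("need at least one group spec")
    anthro_parts, anskq_parts, ipaq_parts = [], [], []
    for gi, spec in enumerate(specs):
        rng = np.random.default_rng((int(seed), gi))
        meas = _draw_measurements(spec, rng)
        prefix = f"{'E' if spec.ranking == 'elite' else 'N'}{spec.sex}"
        ids = [f"{prefix}{i+1:03d}" for i in range(spec.n)]
        meas.insert(0, "ranking", spec.ranking)
        meas.insert(0, "sex", spec.sex)
        meas.insert(0, "id", ids)
        anthro_parts.append(meas[ANTHRO_COLUMNS])
        nk = _draw_anskq(spec, rng)
        nk.insert(0, "id", ids)
        anskq_parts.append(nk)
        pal = _draw_ipaq(spec, rng)
        pal.insert(0, "id", ids)
        ipaq_parts.append(pal)
    return SyntheticCohort(
        anthro=pd.concat(anthro_parts, ignore_index=True),
        anskq=pd.concat(anskq_parts, ignore_index=True),
        ipaq=pd.concat(ipaq_parts, ignore_index=True),
        seed=int(seed),
        group_labels=[s.label for s in specs],
    )


# --- published default specs ----------------------------------------------
# Group means and SDs of the elite/non-elite orienteering cohort, in the
# order (elite male, non-elite male, elite female, non-elite female).
# Bone breadths are not published for this cohort; sex-typical athlete
# defaults are used (documented in the methods note).

def _spec(sex, ranking, n, values, gnk, snk, met) -> GroupSpec:
    means = {c: v[0] for c, v in values.items()}
    sds = {c: v[1] for c, v in values.items()}
    return GroupSpec(sex=sex, ranking=ranking, n=n, means=means, sds=sds,
                     gnk_prob=gnk, snk_prob=snk, met_target=met)


_MALE_BREADTHS = {
    "b_humerus_cm": (7.0, 0.4), "b_bistyloid_cm": (5.6, 0.3),
    "b_femur_cm": (9.5, 0.5), "b_bimalleolar_cm": (7.2, 0.4),
}
_FEMALE_BREADTHS = {
    "b_humerus_cm": (6.2, 0.4), "b_bistyloid_cm": (5.0, 0.3),
    "b_femur_cm": (8.8, 0.5), "b_bimalleolar_cm": (6.6, 0.4),
}


def table1_default_specs() -> list[GroupSpec]:
    """The four default group specs at the published sizes (13/17/10/18)."""
    em = {
        "age_y": (24.3, 5.0), "op_years": (12.1, 6.2),
        "otf_days_wk": (6.1, 1.3), "otq_h_wk": (8.8, 4.0),
        "mass_kg": (65.0, 5.5), "stature_cm": (175.1, 6.0),
        "sitting_height_cm": (103.0, 18.7), "arm_span_cm": (176.1, 6.2),
        "sf_pectoral_mm": (6.4, 3.4), "sf_triceps_mm": (7.0, 2.8),
        "sf_subscapular_mm": (8.4, 2.6), "sf_biceps_mm": (3.3, 1.0),
        "sf_suprailiac_mm": (11.0, 7.1), "sf_supraspinale_mm": (7.0, 3.7),
        "sf_abdominal_mm": (10.1, 6.4), "sf_front_thigh_mm": (9.2, 3.2),
        "sf_calf_mm": (5.9, 2.7),
        "g_neck_cm": (35.1, 1.8), "g_relaxed_arm_cm": (27.3, 2.4),
        "g_flexed_arm_cm": (29.1, 2.3), "g_chest_cm": (90.3, 4.5),
        "g_waist_cm": (74.2, 5.6), "g_hip_cm": (91.2, 3.4),
        "g_mid_thigh_cm": (51.0, 3.1), "g_calf_cm": (37.2, 2.1),
        "g_ankle_cm": (22.2, 0.9),
        **_MALE_BREADTHS,
    }
    nm = {
        "age_y": (37.2, 14.6), "op_years": (11.6, 7.6),
        "otf_days_wk": (3.6, 2.1), "otq_h_wk": (5.5, 5.2),
        "mass_kg": (71.5, 14.2), "stature_cm": (174.0, 8.8),
        "sitting_height_cm": (122.0, 13.6), "arm_span_cm": (183.2, 27.0),
        "sf_pectoral_mm": (10.9, 9.0), "sf_triceps_mm": (9.2, 4.4),
        "sf_subscapular_mm": (12.1, 8.2), "sf_biceps_mm": (3.9, 1.6),
        "sf_suprailiac_mm": (15.0, 8.7), "sf_supraspinale_mm": (9.9, 7.8),
        "sf_abdominal_mm": (16.8, 9.7), "sf_front_thigh_mm": (10.6, 5.8),
        "sf_calf_mm": (5.7, 2.5),
        "g_neck_cm": (37.2, 3.0), "g_relaxed_arm_cm": (28.8, 3.3),
        "g_flexed_arm_cm": (30.1, 3.1), "g_chest_cm": (96.4, 8.5),
        "g_waist_cm": (84.2, 12.1), "g_hip_cm": (95.7, 8.2),
        "g_mid_thigh_cm": (51.1, 3.8), "g_calf_cm": (37.4, 2.8),
        "g_ankle_cm": (22.6, 1.8),
        **_MALE_BREADTHS,
    }
    ef = {
        "age_y": (25.5, 6.4), "op_years": (11.3, 5.3),
        "otf_days_wk": (4.9, 1.6), "otq_h_wk": (7.7, 4.3),
        "mass_kg": (59.5, 7.7), "stature_cm": (168.1, 6.5),
        "sitting_height_cm": (100.5, 20.2), "arm_span_cm": (168.2, 5.8),
        "sf_pectoral_mm": (8.7, 4.4), "sf_triceps_mm": (15.2, 5.2),
        "sf_subscapular_mm": (9.2, 2.7), "sf_biceps_mm": (5.3, 2.3),
        "sf_suprailiac_mm": (15.7, 7.3), "sf_supraspinale_mm": (8.1, 3.4),
        "sf_abdominal_mm": (13.0, 6.0), "sf_front_thigh_mm": (23.5, 8.5),
        "sf_calf_mm": (13.4, 6.7),
        "g_neck_cm": (30.6, 1.6), "g_relaxed_arm_cm": (25.8, 1.9),
        "g_flexed_arm_cm": (26.7, 1.4), "g_chest_cm": (85.5, 4.4),
        "g_waist_cm": (67.2, 4.5), "g_hip_cm": (93.4, 10.5),
        "g_mid_thigh_cm": (50.3, 3.2), "g_calf_cm": (35.5, 2.7),
        "g_ankle_cm": (21.8, 2.5),
        **_FEMALE_BREADTHS,
    }
    nf = {
        "age_y": (41.7, 10.3), "op_years": (11.3, 9.6),
        "otf_days_wk": (3.0, 2.2), "otq_h_wk": (4.2, 3.3),
        "mass_kg": (60.6, 8.5), "stature_cm": (161.3, 11.7),
        "sitting_height_cm": (114.0, 20.3), "arm_span_cm": (163.6, 7.6),
        "sf_pectoral_mm": (7.9, 5.7), "sf_triceps_mm": (15.8, 4.9),
        "sf_subscapular_mm": (11.5, 5.0), "sf_biceps_mm": (5.6, 2.4),
        "sf_suprailiac_mm": (15.4, 5.2), "sf_supraspinale_mm": (9.6, 4.0),
        "sf_abdominal_mm": (16.3, 6.2), "sf_front_thigh_mm": (21.5, 7.3),
        "sf_calf_mm": (11.5, 4.6),
        "g_neck_cm": (31.6, 2.0), "g_relaxed_arm_cm": (27.0, 2.8),
        "g_flexed_arm_cm": (27.3, 2.1), "g_chest_cm": (88.6, 6.4),
        "g_waist_cm": (74.0, 7.4), "g_hip_cm": (96.0, 7.1),
        "g_mid_thigh_cm": (49.2, 3.5), "g_calf_cm": (36.0, 2.0),
        "g_ankle_cm": (21.5, 1.1),
        **_FEMALE_BREADTHS,
    }
    return [
        _spec("M", "elite", 13, em, 0.573, 0.404, 4451.3),
        _spec("M", "non_elite", 17, nm, 0.492, 0.267, 3727.7),
        _spec("F", "elite", 10, ef, 0.636, 0.475, 4249.5),
        _spec("F", "non_elite", 18, nf, 0.545, 0.354, 3941.2),
    ]
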