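"""Cohort CSV reading, per-athlete derivation, and study-report assembly.

The pipeline joins three per-athlete tables (anthropometry, A-NSKQ item
responses, IPAQ-SF diary) on the athlete id, derives body composition,
somatotype and questionnaire scores, and assembles a study report:
group descriptives (mean +/- SD), somatotype classification and dispersion
per sex, the factorial statistics block, per-sex correlation matrices and
the design calculations.  Derived values are carried at full precision;
rounding to 1 dp happens only at serialisation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from . import anthropometry as anth
from . import questionnaires as q
from . import somatotype as st
from . import stats as kstats
from .simulate import ANTHRO_COLUMNS, ANSKQ_COLUMNS, IPAQ_COLUMNS

logger = logging.getLogger("kinanthro")

__all__ = [
    "PipelineConfig",
    "CohortData",
    "read_cohort",
    "profile_from_row",
    "derive_athletes",
    "build_report",
    "somatochart_table",
    "write_report",
]

# CSV column -> AnthropometricProfile field
PROFILE_COLUMN_MAP = {
    "mass_kg": "body_mass",
    "stature_cm": "stature",
    "sitting_height_cm": "sitting_height",
    "arm_span_cm": "arm_span",
    "sf_pectoral_mm": "pectoral",
    "sf_triceps_mm": "triceps",
    "sf_subscapular_mm": "subscapular",
    "sf_biceps_mm": "biceps",
    "sf_suprailiac_mm": "suprailiac",
    "sf_supraspinale_mm": "supraspinale",
    "sf_abdominal_mm": "abdominal",
    "sf_front_thigh_mm": "front_thigh",
    "sf_calf_mm": "medial_calf",
    "g_neck_cm": "neck",
    "g_relaxed_arm_cm": "relaxed_arm",
    "g_flexed_arm_cm": "flexed_arm",
    "g_chest_cm": "chest",
    "g_waist_cm": "waist",
    "g_hip_cm": "hip",
    "g_mid_thigh_cm": "mid_thigh",
    "g_calf_cm": "calf",
    "g_ankle_cm": "ankle",
    "b_humerus_cm": "biepicondylar_humerus",
    "b_bistyloid_cm": "bistyloid",
    "b_femur_cm": "biepicondylar_femur",
    "b_bimalleolar_cm": "bimalleolar",
}

DESCRIPTIVE_VARIABLES = [
    "age_y", "op_years", "otf_days_wk", "otq_h_wk",
    "mass_kg", "stature_cm", "sitting_height_cm", "arm_span_cm",
    "sf_pectoral_mm", "sf_triceps_mm", "sf_subscapular_mm", "sf_biceps_mm",
    "sf_suprailiac_mm", "sf_supraspinale_mm", "sf_abdominal_mm",
    "sf_front_thigh_mm", "sf_calf_mm",
    "g_neck_cm", "g_relaxed_arm_cm", "g_flexed_arm_cm", "g_chest_cm",
    "g_waist_cm", "g_hip_cm", "g_mid_thigh_cm", "g_calf_cm", "g_ankle_cm",
    "percent_body_fat", "bone_mass", "muscle_mass", "bmi",
    "endomorphy", "mesomorphy", "ectomorphy",
    "gnk_pct", "snk_pct", "tnk_pct", "met_total", "kcal_week",
]

CORRELATION_VARIABLES = [
    "age_y", "op_years", "otf_days_wk", "otq_h_wk",
    "percent_body_fat", "bone_mass", "muscle_mass", "bmi",
    "endomorphy", "mesomorphy", "ectomorphy",
    "met_total", "kcal_week", "gnk_pct", "snk_pct", "tnk_pct",
]


@dataclass
class PipelineConfig:
    bd_equation_male: str = "male_athlete_7sf"
    bd_equation_female: str = "female_athlete_4sf_log"
    fat_conversion: str = "siri"
    bone_equation: str = "von_dobeln_rocha"
    race_coeff: float = 0.0
    ipaq_truncate_180: bool = False
    round_mode: str = "1dp"          # "1dp" | "none"
    seed: int = kstats.DEFAULT_SEED
    ks_mc_reps: int = 500            # normality-gate Monte-Carlo replicates
    alpha: float = 0.05
    # per-variable pins for the ANOVA/ART gate, e.g. {"bmi": "art_anova"}
    method_overrides: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortData:
    """Joined, validated per-athlete table plus row-level validation issues."""

    data: pd.DataFrame
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")


def _check_ids(df: pd.DataFrame, name: str) -> None:
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate ids in {name} table: {dup}")


def profile_from_row(row: pd.Series) -> anth.AnthropometricProfile:
    """Build an AnthropometricProfile from one anthropometry CSV row."""
    kwargs = {f: float(row[c]) for c, f in PROFILE_COLUMN_MAP.items()}
    return anth.AnthropometricProfile(**kwargs)


def read_cohort(
    anthro_path, anskq_path=None, ipaq_path=None
) -> CohortData:
    """Read and join the cohort CSVs; invalid rows are reported, not fatal.

    The anthropometry table is the spine.  Questionnaire tables are
    outer-joined on id: athletes missing from a questionnaire table get null
    scores with a warning.
    """
    anthro = pd.read_csv(anthro_path)
    _require_columns(anthro, ANTHRO_COLUMNS, "anthropometry")
    _check_ids(anthro, "anthropometry")

    errors, warns = [], []
    keep = []
    for i, row in anthro.iterrows():
        try:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", anth.PhysiologicRangeWarning)
                profile_from_row(row)
            if row["sex"] not in ("M", "F"):
                raise anth.ValidationError(f"sex must be M/F, got {row['sex']!r}")
            if row["ranking"] not in ("elite", "non_elite"):
                raise anth.ValidationError(
                    f"ranking must be elite/non_elite, got {row['ranking']!r}"
                )
            keep.append(i)
        except (anth.ValidationError, ValueError, TypeError) as e:
            errors.append(f"anthropometry row {i} (id={row.get('id')}): {e}")
    df = anthro.loc[keep].copy()

    if anskq_path is not None:
        nk = pd.read_csv(anskq_path, dtype={c: "string" for c in ANSKQ_COLUMNS[1:]})
        _require_columns(nk, ANSKQ_COLUMNS, "A-NSKQ")
        _check_ids(nk, "A-NSKQ")
        missing = set(df["id"]) - set(nk["id"])
        if missing:
            warns.append(f"ids missing from A-NSKQ table: {sorted(missing)}")
        df = df.merge(nk, on="id", how="left")
    if ipaq_path is not None:
        pal = pd.read_csv(ipaq_path)
        _require_columns(pal, IPAQ_COLUMNS, "IPAQ")
        _check_ids(pal, "IPAQ")
        missing = set(df["id"]) - set(pal["id"])
        if missing:
            warns.append(f"ids missing from IPAQ table: {sorted(missing)}")
        df = df.merge(pal, on="id", how="left")

    for msg in errors:
        logger.warning("rejected: %s", msg)
    for msg in warns:
        logger.warning(msg)
    return CohortData(data=df.reset_index(drop=True), errors=errors, warnings=warns)


def derive_athletes(
    cohort: CohortData, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-athlete derived table: body composition, somatotype, scores."""
    config = config or PipelineConfig()
    df = cohort.data
    out_rows = []
    has_nk = ANSKQ_COLUMNS[1] in df.columns
    has_ipaq = "vig_days" in df.columns
    for _, row in df.iterrows():
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", anth.PhysiologicRangeWarning)
            profile = profile_from_row(row)
            sex = "male" if row["sex"] == "M" else "female"
            bd_id = (config.bd_equation_male if sex == "male"
                     else config.bd_equation_female)
            comp = anth.body_composition(
                profile, sex, float(row["age_y"]),
                bd_equation_id=bd_id,
                fat_conversion_id=config.fat_conversion,
                bone_equation_id=config.bone_equation,
                race_coeff=config.race_coeff,
            )
            soma = st.compute_somatotype(profile)
        xy = st.somatochart_xy(soma)
        rec: dict[str, Any] = {
            "id": row["id"], "sex": row["sex"], "ranking": row["ranking"],
            "age_y": row["age_y"], "op_years": row["op_years"],
            "otf_days_wk": row["otf_days_wk"], "otq_h_wk": row["otq_h_wk"],
            **{c: row[c] for c in PROFILE_COLUMN_MAP},
            "bmi": comp.bmi, "body_density": comp.body_density,
            "percent_body_fat": comp.percent_body_fat,
            "bone_mass": comp.bone_mass, "muscle_mass": comp.muscle_mass,
            "endomorphy": soma.endomorphy, "mesomorphy": soma.mesomorphy,
            "ectomorphy": soma.ectomorphy,
            "chart_x": xy.x, "chart_y": xy.y,
            "somatotype_category": st.classify_somatotype(soma),
        }
        if has_nk and pd.notna(row.get(ANSKQ_COLUMNS[1])):
            answers = [
                None if pd.isna(row[c]) else str(row[c])
                for c in ANSKQ_COLUMNS[1:]
            ]
            score = q.score_anskq(q.ANSKQResponse(answers))
            rec.update(gnk_pct=score.gnk_pct, snk_pct=score.snk_pct,
                       tnk_pct=score.tnk_pct, nk_band=score.band)
        else:
            rec.update(gnk_pct=np.nan, snk_pct=np.nan, tnk_pct=np.nan,
                       nk_band=None)
        if has_ipaq and pd.notna(row.get("vig_days")):
            ipaq = q.ipaq_clean(
                q.IPAQRecord(
                    vigorous_days=float(row["vig_days"]),
                    vigorous_min=float(row["vig_min"]),
                    moderate_days=float(row["mod_days"]),
                    moderate_min=float(row["mod_min"]),
                    walking_days=float(row["walk_days"]),
                    walking_min=float(row["walk_min"]),
                    sitting_min=float(row["sit_min"]),
                    body_mass=float(row["mass_kg"]),
                ),
                truncate_180=config.ipaq_truncate_180,
            )
            pal = q.ipaq_met_minutes(ipaq)
            if pal.excluded_as_outlier:
                rec.update(met_total=np.nan, kcal_week=np.nan,
                           pal_category=None, excluded=True)
            else:
                rec.update(
                    met_walk=pal.walking_met, met_mod=pal.moderate_met,
                    met_vig=pal.vigorous_met, met_total=pal.total_met,
                    kcal_week=pal.kcal_week, pal_category=pal.category,
                    excluded=False,
                )
        else:
            rec.update(met_total=np.nan, kcal_week=np.nan,
                       pal_category=None, excluded=False)
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def somatochart_table(derived: pd.DataFrame) -> pd.DataFrame:
    """Somatochart export: id, components, chart coordinates and category."""
    tab = derived[["id", "endomorphy", "mesomorphy", "ectomorphy",
                   "chart_x", "chart_y", "somatotype_category"]].copy()
    return tab.rename(columns={
        "endomorphy": "endo", "mesomorphy": "meso", "ectomorphy": "ecto",
        "chart_x": "x", "chart_y": "y", "somatotype_category": "category",
    })


def _group_key(row) -> str:
    sex = "male" if row["sex"] == "M" else "female"
    return f"{row['ranking']}_{sex}"


def _descriptives(derived: pd.DataFrame) -> dict[str, Any]:
    out = {}
    for key, g in derived.groupby(derived.apply(_group_key, axis=1), sort=True):
        block = {"n": int(len(g))}
        for var in DESCRIPTIVE_VARIABLES:
            if var not in g.columns:
                continue
            vals = pd.to_numeric(g[var], errors="coerce").dropna()
            if len(vals) == 0:
                block[var] = None
                continue
            block[var] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        out[key] = block
    return out


def _somatotype_block(derived: pd.DataFrame) -> dict[str, Any]:
    groups = {}
    for key, g in derived.groupby(derived.apply(_group_key, axis=1), sort=True):
        somas = [st.Somatotype(e, m, c) for e, m, c in
                 zip(g["endomorphy"], g["mesomorphy"], g["ectomorphy"])]
        mean_s = st.mean_somatotype(somas)
        disp = st.dispersion_summary(somas)
        groups[key] = {
            "mean_somatotype": list(mean_s.as_tuple()),
            "classification": st.classify_somatotype(mean_s),
            "sdm": disp.sdm,
            "sam": disp.sam,
        }
    # elite vs non-elite mean-somatotype distances, per sex
    dispersion = {}
    for sex_code, sex in (("M", "male"), ("F", "female")):
        e_key, n_key = f"elite_{sex}", f"non_elite_{sex}"
        if e_key in groups and n_key in groups:
            se = st.Somatotype(*groups[e_key]["mean_somatotype"])
            sn = st.Somatotype(*groups[n_key]["mean_somatotype"])
            dispersion[sex] = {
                "sdd_elite_vs_non_elite": st.sdd(
                    st.somatochart_xy(se), st.somatochart_xy(sn)
                ),
                "sad_elite_vs_non_elite": st.sad(se, sn),
            }
    return {"groups": groups, "dispersion": dispersion}


def _one_way_ranking_effect(vals, ranking) -> dict[str, Any]:
    y = np.asarray(vals, dtype=float)
    g = np.asarray(ranking)
    levels = sorted(set(g.tolist()))
    grand = y.mean()
    ss_between = sum(
        len(y[g == lv]) * (y[g == lv].mean() - grand) ** 2 for lv in levels
    )
    ss_within = sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in levels)
    from scipy import stats as sps
    f, p = sps.f_oneway(*[y[g == lv] for lv in levels])
    eta = ss_between / (ss_between + ss_within)
    return {"F": float(f), "p": float(p), "eta_sq_p": float(eta),
            "label": kstats.effect_size_label(eta)}


def _statistics_block(
    derived: pd.DataFrame, config: PipelineConfig
) -> dict[str, Any]:
    sexes = sorted(derived["sex"].unique().tolist())
    rankings = sorted(derived["ranking"].unique().tolist())
    block: dict[str, Any] = {}
    single_sex = len(sexes) < 2
    if single_sex:
        block["notice"] = (
            "single-sex cohort: sex and interaction effects omitted; "
            "ranking effect from one-way ANOVA"
        )
    if len(rankings) < 2:
        block["notice"] = "single-ranking cohort: group comparisons omitted"
        return block
    for var in DESCRIPTIVE_VARIABLES:
        if var not in derived.columns:
            continue
        sub = derived[[var, "sex", "ranking"]].copy()
        sub[var] = pd.to_numeric(sub[var], errors="coerce")
        sub = sub.dropna()
        if len(sub) < 8:
            continue
        if single_sex:
            block[var] = {"method": "anova_one_way",
                          "effects": {"ranking": _one_way_ranking_effect(
                              sub[var], sub["ranking"])}}
            continue
        counts = sub.groupby(["sex", "ranking"]).size()
        if len(counts) < 4 or counts.min() < 2:
            continue
        res = kstats.compare_groups(
            sub[var].to_numpy(), sub["sex"].to_numpy(), sub["ranking"].to_numpy(),
            variable=var,
            method=config.method_overrides.get(var),
            alpha=config.alpha,
            seed=config.seed,
            ks_mc_reps=config.ks_mc_reps,
        )
        block[var] = {
            "method": res.method,
            "effects": {k: asdict(v) for k, v in res.effects.items()},
        }
        if res.posthoc:
            block[var]["posthoc_bonferroni"] = res.posthoc
    return block


def _correlation_block(derived: pd.DataFrame) -> dict[str, Any]:
    out = {}
    for sex_code, sex in (("M", "male"), ("F", "female")):
        g = derived[derived["sex"] == sex_code]
        if len(g) < 4:
            continue
        variables = {}
        for var in CORRELATION_VARIABLES:
            if var in g.columns:
                vals = pd.to_numeric(g[var], errors="coerce").to_numpy(dtype=float)
                if np.isfinite(vals).sum() >= 3 and np.nanstd(vals) > 0:
                    variables[var] = vals
        try:
            results = kstats.pearson_matrix(variables)
        except ValueError:
            continue
        out[sex] = [
            {"pair": list(r.pair), "r": r.r, "p": r.p, "label": r.label}
            for r in results
        ]
    return out


def build_report(
    cohort: CohortData, config: PipelineConfig | None = None
) -> dict[str, Any]:
    """Run the full pipeline and assemble the study report as a JSON-able dict.

    Stage order is fixed: derive -> somatotype -> score -> describe ->
    compare -> correlate -> design.
    """
    config = config or PipelineConfig()
    derived = derive_athletes(cohort, config)
    if derived["ranking"].nunique() < 2 and derived["sex"].nunique() < 2:
        raise ValueError("need at least two groups to build a report")
    report = {
        "n_total": int(len(derived)),
        "config": {
            "bd_equation_male": config.bd_equation_male,
            "bd_equation_female": config.bd_equation_female,
            "fat_conversion": config.fat_conversion,
            "bone_equation": config.bone_equation,
            "ipaq_truncate_180": config.ipaq_truncate_180,
            "kcal_formula": "met_min_per_week * body_mass_kg / 60",
            "seed": config.seed,
        },
        "groups": _descriptives(derived),
        "somatotype": _somatotype_block(derived),
        "statistics": _statistics_block(derived, config),
        "correlations": _correlation_block(derived),
        "design": {
            "cochran_n": kstats.cochran_sample_size(2500, 1.96, 0.8, 0.10, True),
            "achieved_power": kstats.anova_power(0.4, 0.05, 4, len(derived))
            if len(derived) > 4 else None,
        },
        "validation": {"errors": cohort.errors, "warnings": cohort.warnings},
    }
    return report


# test statistics, p values and effect sizes keep 3 dp under "1dp" rounding;
# descriptive quantities are presented at 1 dp
_PRECISE_KEYS = {"p", "r", "F", "eta_sq_p", "achieved_power", "sdd_elite_vs_non_elite",
                 "sad_elite_vs_non_elite"}


def _round_floats(obj, ndigits: int = 1, key: str | None = None):
    if isinstance(obj, float):
        return round(obj, 3 if key in _PRECISE_KEYS else ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits, k) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits, key) for v in obj]
    return obj


def write_report(report: dict, path, round_mode: str = "1dp") -> None:
    """Serialise the report as JSON, rounding floats only at this boundary."""
    if round_mode == "1dp":
        report = _round_floats(report, 1)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
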