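# kinanthro

Kinanthropometric profiling of athlete cohorts: Heath–Carter somatotyping
with somatochart dispersion statistics, skinfold-based body composition,
nutrition-knowledge (A-NSKQ) and physical-activity (IPAQ-SF) questionnaire
scoring, and a factorial group-comparison statistics layer — plus a seeded
synthetic cohort generator so the whole pipeline is testable without access
to real athlete data.

It is aimed at sports scientists and kinanthropometrists who collect ISAK
measurement batteries on athlete groups (e.g. elite vs non-elite, male vs
female) and want a reproducible route from raw measurement CSVs to a full
study report.

## The quantities it computes

**Somatotype.** The Heath–Carter anthropometric somatotype rates a physique
as three components — endomorphy (relative adiposity), mesomorphy
(musculoskeletal robustness), ectomorphy (linearity):

- endomorphy: `−0.7182 + 0.1451·S − 0.00068·S² + 0.0000014·S³`, with `S`
  the triceps + subscapular + supraspinale skinfold sum (mm), height-corrected
  by `170.18 / stature`;
- mesomorphy: `0.858·HB + 0.601·FB + 0.188·CAG + 0.161·CCG − 0.131·stature + 4.5`
  with humerus/femur breadths and skinfold-corrected arm/calf girths;
- ectomorphy: piecewise-linear in the height–weight ratio
  `HWR = stature / ∛mass` (upper branch `0.732·HWR − 28.58` for HWR ≥ 40.75).

Somatotypes project onto the somatochart through `X = ecto − endo`,
`Y = 2·meso − (endo + ecto)`, and groups are compared with the dispersion
distance `SDD = √(3ΔX² + ΔY²)`, the attitudinal distance `SAD`
(3-D Euclidean in component space) and their means SDM / SAM. Each
somatotype is named by Carter's 13-category scheme (central, balanced X,
Y-ic X, X–Y edges).

**Body composition.** BMI; body density from pluggable skinfold regression
equations (athlete-population defaults per sex); percent body fat via the
Siri conversion `495/BD − 450`; skeletal mass from stature and wrist/femur
breadths; muscle mass from the Lee equation on π-corrected limb girths; and
the technical error of measurement `TEM = √(Σd²/2n)` for repeated measures.

**Questionnaires.** A-NSKQ: percent-correct scores for the 11 general and
24 sports-nutrition items, combined total, and poor/average/good/excellent
bands. IPAQ-SF: MET-min/week per domain (walking 3.3, moderate 4.0,
vigorous 8.0 METs), kcal/week, the official low/moderate/high category, the
sub-10-minute recode and the 960 min/day outlier rule.

**Statistics.** Per variable: a Lilliefors-corrected Kolmogorov–Smirnov
normality gate (seeded Monte-Carlo null) routes to either a two-way
Type-III ANOVA (sex × ranking, sum-to-zero contrasts) or an Aligned Rank
Transform factorial ANOVA; effects carry partial eta squared
(`η²p = SS_effect/(SS_effect+SS_error)`) with the 0.01/0.06/0.14 bands;
significant interactions get Bonferroni-adjusted pairwise Welch t-tests.
Pearson correlation matrices per sex, Cochran sample-size and noncentral-F
power calculations complete the layer.

## Worked example

```python
from kinanthro.somatotype import (Somatotype, classify_somatotype,
                                  ectomorphy, endomorphy, mesomorphy,
                                  somatochart_xy)
from kinanthro.anthropometry import muscle_mass_lee

endo = endomorphy(7.0, 8.4, 7.0, stature=175.1)          # skinfolds in mm
meso = mesomorphy(7.0, 9.5, 29.1, 7.0, 37.2, 5.9, 175.1)
ecto = ectomorphy(body_mass=65.0, stature=175.1)
s = Somatotype(round(endo, 1), round(meso, 1), round(ecto, 1))
print(s.as_tuple(), "->", classify_somatotype(s))
p = somatochart_xy(s)
print(f"chart: x={p.x:.1f}, y={p.y:.1f}")
print(f"muscle mass: {muscle_mass_lee(175.1, 24.3, 'male', 0, 27.3, 7.0, 51.0, 9.2, 37.2, 5.9):.1f} kg")
```

prints

```
(2.1, 4.5, 3.3) -> ectomorphic mesomorph
chart: x=1.2, y=3.6
muscle mass: 30.5 kg
```

i.e. an elite-male orienteer with these group-mean measurements is a lean,
muscular "ectomorphic mesomorph" plotting in the upper-right of the
somatochart, with an estimated 30.5 kg of skeletal muscle.

The full pipeline runs from the shell:

```bash
kinanthro simulate --seed 7 --out cohort/          # synthetic 4-group cohort
kinanthro report cohort/anthro.csv --anskq cohort/anskq.csv \
    --ipaq cohort/ipaq.csv --out results/          # full study report JSON
kinanthro somatotype cohort/anthro.csv --out chart.csv
```

`report.json` contains per-group descriptives (mean ± SD), the somatotype
classification and dispersion block, the per-variable ANOVA/ART statistics
with effect sizes, per-sex correlation matrices, and the design block
(Cochran n = 61 at N = 2500, z = 1.96, p = 0.8, ±10 % margin; achieved
power 0.69 at the generated cohort size of 58).

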