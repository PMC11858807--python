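# Methods

This note documents the models, scoring rules, numerical choices and known
limitations of the `kinanthro` pipeline, in the order the pipeline runs:
body composition → somatotype → questionnaires → statistics, then the
synthetic cohort generator that stands in for real athlete data.

## Body composition

BMI is mass (kg) over stature (m) squared. Body density, the
density-to-fat conversion, and skeletal (bone) mass are computed through
string-keyed equation registries rather than hard-wired formulas: published
skinfold equations differ by population and laboratory, and a cohort
re-analysis must be able to swap them without code changes. The defaults
are:

- male body density: `1.0988 − 0.0004·Σ7SF` over the triceps, subscapular,
  biceps, supraspinale, abdominal, front-thigh and medial-calf skinfolds
  (mm) — a male-athlete regression;
- female body density: `1.20953 − 0.08294·log10(Σ4SF)` over triceps,
  subscapular, supraspinale and medial calf — a female-athlete regression;
- fat conversion: Siri `%BF = 495/BD − 450` for both sexes (Brozek is
  registered as an alternative);
- bone mass: `3.02·(h²·R·F·400)^0.712` with stature, bistyloid breadth and
  biepicondylar femur breadth in metres.

Because the registry choice materially changes %BF and bone-mass group
means, downstream consumers should treat those outputs as
equation-conditional; the report JSON records the equation ids used.

Muscle mass uses the Lee anthropometric prediction:
`Ht·(0.00744·CAG² + 0.00088·CTG² + 0.00441·CCG²) + 2.4·sex − 0.048·age +
race + 7.8`, with stature in metres and limb girths corrected by
`girth − π·skinfold` — the skinfold annulus model of the subcutaneous ring
around the muscle. The Heath–Carter girth correction, by contrast,
subtracts the bare skinfold; both corrections live in one helper with an
explicit mode flag because confusing them is a classic implementation bug.
The race coefficient defaults to 0 (no ethnicity adjustment).

Skinfolds are stored in mm (as ISAK reports them) and converted to cm
inside the girth corrections. Validation is warn-not-fail inside broad
physiologic ranges (stature 100–230 cm, skinfolds 1–80 mm): athlete
populations contain extreme but genuine values, so only non-positive or
arithmetically impossible inputs are hard errors.

TEM is `sqrt(Σd²/2n)` over paired inter-pass differences, with the relative
form scaled by the grand mean of all observations; it is invariant to
exchanging passes and to shifting both passes by a constant.

## Somatotype engine

Component formulas are as in the README. Numerical decisions:

- the endomorphy height correction is fixed at `170.18/stature` (the
  standard reference stature in cm);
- all components are floored at 0.1;
- the ectomorphy branch boundary at HWR = 40.75 belongs to the *upper*
  branch (the two branch formulas disagree there, 1.249 vs 1.237, so the
  boundary assignment is covered by an explicit test);
- components are carried at full precision; rounding to 1 dp happens at the
  reporting boundary and inside classification only.

Classification implements Carter's 13 categories on 1-dp rounded
components, in this precedence order: (1) *central* when no component
differs from any other by more than 1.0 — checked first, because a
somatotype such as (3.3, 3.5, 3.0) is central even though mesomorphy is
nominally dominant; (2) an *X–Y edge* category when the top two components
are within 0.5 of each other; (3) otherwise *balanced X* when the two
non-dominant components are within 0.5 of each other, else *Y-ic X*.
Exact ties resolve deterministically in chart order
endomorph–mesomorph–ectomorph (a stable sort).

Dispersion statistics: SDD is the somatochart distance
`sqrt(3ΔX² + ΔY²)` (the √3 weight makes X and Y units commensurate on the
chart), SAD the Euclidean distance in component space; SDM and SAM are
their means over individuals against a reference that defaults to the
component-wise group mean somatotype and can be overridden. Both pairwise
and per-individual-list forms are exposed, since published analyses
sometimes report a single between-group value (distance between group mean
somatoplots) and sometimes per-individual dispersions. Note that
recomputing a between-group SDD from *rounded* group means will generally
not reproduce a value computed from unrounded means — a 0.1–0.2 discrepancy
is expected and not a defect.

## Questionnaire scoring

A-NSKQ: 35 multiple-choice items, items 1–11 general (GNK), 12–35 sports
nutrition (SNK). Scores are percent correct per subsection; the total TNK
is percent correct over all 35 items, identically equal to
`(11·GNK% + 24·SNK%)/35`. Unanswered items score as incorrect (the
denominator is fixed by the instrument). Bands are implemented as the
half-open partition [0,50) poor, [50,66) average, [66,76) good, [76,100]
excellent — the integer band edges usually quoted (0–49, 50–65, …) leave
non-integer scores unassigned, and the half-open form is the unique
total partition consistent with them. The shipped answer key is an
explicit placeholder (the instrument is copyrighted); deployments supply
their own via `ANSKQResponse(answer_key=...)`.

IPAQ-SF: domain score = MET weight × days/week × min/day (walking 3.3,
moderate 4.0, vigorous 8.0), summed to the weekly total. Cleaning recodes
daily bouts under 10 min to zero and flags records whose three domains sum
to more than 960 min/day (16 h) as outliers; the rule is applied to the
daily sum across domains. The official 180 min/day per-domain truncation
is available behind a flag, default off. Categories follow the standard
low/moderate/high rules (see the code docstring for the exact predicates).
kcal/week uses the 60-kg-reference convention `MET-min × kg/60`; this
convention is recorded in the report metadata because other conversions
exist. Missing body mass omits kcal rather than defaulting.

## Statistics layer

Normality gate: Kolmogorov–Smirnov with mean and SD estimated from the
sample. Because estimation makes the textbook KS null anticonservative,
the p value comes from a seeded Monte-Carlo null (Lilliefors correction):
the same statistic on standard-normal samples of the same size, vectorised;
2000 replicates by default (500 inside report assembly). The default seed
is 20230714; every Monte-Carlo component takes an explicit seed.

Normal variables go to a two-way Type-III ANOVA (statsmodels OLS with
sum-to-zero contrasts — Type-III partial SS are contrast-dependent and
sum-to-zero is the convention under which they are standard). Non-normal
variables go to the Aligned Rank Transform: for each effect, subtract every
cell-mean-estimated effect *except* the effect of interest from the
responses, mid-rank the aligned values, run the full factorial ANOVA on the
ranks, and read off only that effect. Partial eta squared is
`SS_effect/(SS_effect + SS_error)` (on rank-model SS for ART) with labels
small/medium/large at 0.01/0.06/0.14. The gate is automatic but can be
pinned per variable — reproducing a published table can require pinning
when the gate is borderline.

Post hoc: when the sex × ranking interaction reaches α = 0.05, pairwise
Welch t-tests across the four cells with Bonferroni adjustment
`p_adj = min(1, m·p)`. Welch is used because the design is unbalanced.

Design utilities: Cochran `n0 = z²p(1−p)/e²` with the finite-population
correction `n0/(1+(n0−1)/N)`, ceiling applied at the end; ANOVA power from
the noncentral F distribution with `λ = f²N`. The power function returns
the exact value and leaves per-group rounding to the caller, since software
packages disagree on whether a target power of 0.80 at f = 0.4 and 4 groups
needs 18 or 19 per group.

## Synthetic cohort generator

The generator emulates a four-group (elite/non-elite × male/female) athlete
cohort with the published group means and SDs as default parameters
(group sizes 13/17/10/18). Only *raw* inputs are generated — measurements,
item responses, diaries — never derived quantities, so every pipeline stage
is exercised end-to-end and tests cannot be circular.

Correlation structure comes from three latent factors — frame size,
adiposity, muscularity — with two spec-level correlation knobs
(frame–adiposity, default 0.15; frame–muscularity, default 0.40). Each
variable mixes the latents through fixed loadings (skinfolds on adiposity,
lengths/breadths on frame, limb girths on all three) plus an independent
residual scaled to unit marginal variance. A full 26×26 covariance would
be unidentifiable from published summary tables; three interpretable knobs
produce realistic structure.

Bounds are enforced by resampling, not clipping, and each variable's
marginal is a truncated normal whose *location* is calibrated (root-finding
on the truncated mean) so that the truncated mean equals the configured
mean — naive truncation of an off-centre normal visibly biases variables
like training frequency (6.1 ± 1.3 days/week against the 7-day cap).
Out-of-bound draws are replaced by exact truncated-normal redraws, which is
distributionally identical to resampling until valid; those entries lose
their latent-factor correlation, a deliberate tradeoff in the tails.
The calibration preserves means exactly but shrinks the realised SD where
truncation binds.

A-NSKQ items are independent Bernoulli draws at the group's per-item
correct probability (GNK and SNK probabilities set to the published group
mean percentages / 100); wrong answers are uniform over the remaining
options. IPAQ days are integer truncated normals on 0–7; minutes are
integer truncated normals on 10–240 whose location is calibrated so that
`MET weight × E[days] × E[minutes]` hits each domain's share (vigorous
50 %, moderate 20 %, walking 30 %) of the group's MET-min/week target —
days and minutes are independent, so the expectation factorises. The
10–240 bounds also guarantee generated diaries never trigger the cleaning
rules, keeping mean recovery exact through the scoring stage.

Bone breadths are not published for the reference cohort; the defaults are
sex-typical athlete values (humerus 7.0/6.2, bistyloid 5.6/5.0, femur
9.5/8.8, bimalleolar 7.2/6.6 cm, SDs 0.3–0.5) chosen so group-mean
mesomorphy lands in the published range.

What the generator does *not* emulate: within-group skew (only M ± SD are
published, so marginals are symmetric truncated normals), cross-domain
covariances between anthropometry, knowledge and activity (each block draws
independently), measurement error structure, and any longitudinal
dependence. Consequently, passing recovery tests shows the pipeline
arithmetic is right under the published first- and second-moment structure;
it does not validate the pipeline against the idiosyncrasies of real
cohorts, and published cross-domain correlation tables cannot be
reproduced from synthetic data.

## Problem sizes and determinism

Simulation-based tests use: parameter recovery at 5000 per group; Type-I
error calibration at 1000 null replicates of 15 per cell for both engines;
ART rank-invariance at 40 per cell; correlation recovery at n = 10 000.
These sizes put Monte-Carlo noise well inside the asserted tolerances
(e.g. binomial SD ≈ 0.007 for a 5 % rate at 1000 replicates, against a
± 2-point band). All randomness flows through explicit seeds; cohorts are
byte-identical for identical (spec, seed) and the report JSON is
reproducible for identical inputs and config.

## Known limitations

- Body density, fat conversion and bone mass defaults are plausible
  athlete equations but equation-conditional; swap registry entries to
  match a specific laboratory protocol.
- The A-NSKQ key is a placeholder; scoring real responses requires the
  licensed key.
- The ART alignment zero-sum property holds exactly on balanced designs;
  on unbalanced designs alignment uses cell-mean-estimated effects and the
  within-level sums are only approximately zero.
- The statistics layer assumes a complete 2×2 design with ≥ 2 observations
  per cell; single-sex cohorts fall back to a one-way ranking comparison
  with an explicit notice in the report.
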