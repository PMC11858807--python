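"""Group-comparison and correlation statistics for 2x2 factorial cohorts.

The inference layer mirrors a common sports-science workflow: each outcome is
gated through a normality test (Lilliefors-corrected Kolmogorov-Smirnov with a
seeded Monte-Carlo null), then analysed with a two-way Type-III ANOVA
(sex x ranking, sum-to-zero contrasts) when normal, or the Aligned Rank
Transform (ART) factorial ANOVA otherwise.  Effects carry partial eta squared
with the conventional small / medium / large bands; a significant interaction
triggers Bonferroni-adjusted pairwise Welch t-tests.  Pearson correlation
matrices with |r|-based effect labels, and the standard design calculations
(Cochran sample size with finite-population correction, noncentral-F ANOVA
power) round out the layer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "EffectResult",
    "GroupComparisonResult",
    "CorrelationResult",
    "ks_normality",
    "anova_two_way_type3",
    "art_anova",
    "compare_groups",
    "posthoc_pairwise_bonferroni",
    "pearson_matrix",
    "effect_size_label",
    "pearson_label",
    "cochran_sample_size",
    "anova_power",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20230714
EFFECTS = ("sex", "ranking", "interaction")


@dataclass
class EffectResult:
    F: float
    p: float
    eta_sq_p: float
    label: str


@dataclass
class GroupComparisonResult:
    variable: str
    method: str  # "anova_type3" | "art_anova"
    effects: dict[str, EffectResult]
    posthoc: dict[str, float] | None = None


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    label: str


# --- normality gate -------------------------------------------------------

def ks_normality(
    sample, alpha: float = 0.05, n_mc: int = 2000, seed: int = DEFAULT_SEED
) -> tuple[str, float, float]:
    """Lilliefors-corrected KS normality decision.

    The KS statistic is computed against a normal with mean and SD estimated
    from the sample; because the parameters are estimated, the naive KS null
    is anticonservative, so the p value comes from a seeded Monte-Carlo null
    (``n_mc`` replicates of the same statistic on standard-normal samples of
    the same size).  Returns (decision, statistic, p).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for the normality gate")
    sd = x.std(ddof=1)
    if sd == 0:
        return "non_normal", 1.0, 0.0
    d_obs = _ks_stat_rows((x - x.mean())[None, :] / sd)[0]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, x.size))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    null = _ks_stat_rows(z)
    p = (1.0 + np.sum(null >= d_obs)) / (n_mc + 1.0)
    return ("normal" if p > alpha else "non_normal"), float(d_obs), float(p)


def _ks_stat_rows(z: np.ndarray) -> np.ndarray:
    """Row-wise KS distance of sorted samples from the standard normal CDF."""
    n = z.shape[1]
    cdf = sps.norm.cdf(np.sort(z, axis=1))
    grid = np.arange(1, n + 1) / n
    d_plus = (grid - cdf).max(axis=1)
    d_minus = (cdf - (grid - 1.0 / n)).max(axis=1)
    return np.maximum(d_plus, d_minus)


# --- factorial ANOVA ------------------------------------------------------

def _frame(values, sex, ranking) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "sex": pd.Categorical(sex),
            "ranking": pd.Categorical(ranking),
        }
    )
    counts = df.groupby(["sex", "ranking"], observed=False).size()
    empty = counts[counts < 2]
    if len(empty):
        cells = ", ".join(f"{s}/{r}" for s, r in empty.index)
        raise ValueError(f"cells with fewer than 2 observations: {cells}")
    return df


_FORMULA = "y ~ C(sex, Sum) * C(ranking, Sum)"
_TERMS = {
    "sex": "C(sex, Sum)",
    "ranking": "C(ranking, Sum)",
    "interaction": "C(sex, Sum):C(ranking, Sum)",
}


def _type3_effects(df: pd.DataFrame) -> dict[str, EffectResult]:
    fit = smf.ols(_FORMULA, data=df).fit()
    tbl = anova_lm(fit, typ=3)
    ss_err = float(tbl.loc["Residual", "sum_sq"])
    out = {}
    for name, term in _TERMS.items():
        ss = float(tbl.loc[term, "sum_sq"])
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        out[name] = EffectResult(
            F=float(tbl.loc[term, "F"]),
            p=float(tbl.loc[term, "PR(>F)"]),
            eta_sq_p=eta,
            label=effect_size_label(eta),
        )
    return out


def anova_two_way_type3(values, sex, ranking, variable: str = "y") -> GroupComparisonResult:
    """Two-way Type-III (partial SS) ANOVA under sum-to-zero contrasts.

    Partial eta squared per effect is SS_effect / (SS_effect + SS_error).
    """
    df = _frame(values, sex, ranking)
    return GroupComparisonResult(variable, "anova_type3", _type3_effects(df))


def aligned_responses(df: pd.DataFrame, effect: str) -> np.ndarray:
    """ART alignment: residual plus the cell-mean estimate of one effect.

    Cell means estimate the full factorial model; the response is stripped of
    every estimated effect except the effect of interest, so that ranks of
    the aligned values carry only that effect.
    """
    cell = df.groupby(["sex", "ranking"], observed=False)["y"].transform("mean")
    mean_sex = df.groupby("sex", observed=False)["y"].transform("mean")
    mean_rank = df.groupby("ranking", observed=False)["y"].transform("mean")
    grand = df["y"].mean()
    resid = df["y"] - cell
    if effect == "sex":
        est = mean_sex - grand
    elif effect == "ranking":
        est = mean_rank - grand
    elif effect == "interaction":
        est = cell - mean_sex - mean_rank + grand
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return (resid + est).to_numpy()


def art_anova(values, sex, ranking, variable: str = "y") -> GroupComparisonResult:
    """Aligned Rank Transform factorial ANOVA.

    For each effect the responses are aligned (all other estimated effects
    subtracted), mid-ranked, and submitted to the full factorial ANOVA on
    ranks; only the aligned-for effect is read off.  Partial eta squared is
    computed on the rank-model sums of squares.
    """
    df = _frame(values, sex, ranking)
    effects = {}
    for effect in EFFECTS:
        rdf = df.copy()
        rdf["y"] = sps.rankdata(aligned_responses(df, effect))
        effects[effect] = _type3_effects(rdf)[effect]
    return GroupComparisonResult(variable, "art_anova", effects)


def compare_groups(
    values,
    sex,
    ranking,
    variable: str = "y",
    method: str | None = None,
    alpha: float = 0.05,
    seed: int = DEFAULT_SEED,
    ks_mc_reps: int = 2000,
) -> GroupComparisonResult:
    """Normality-gated factorial comparison with interaction post hoc.

    ``method`` pins the analysis ("anova_type3" or "art_anova"), overriding
    the Kolmogorov-Smirnov gate; by default the gate chooses.  When the
    interaction term reaches ``alpha``, Bonferroni-adjusted pairwise Welch
    t-tests across the four sex-ranking cells are attached.
    """
    if method is None:
        decision, _, _ = ks_normality(values, alpha=alpha, n_mc=ks_mc_reps, seed=seed)
        method = "anova_type3" if decision == "normal" else "art_anova"
    if method == "anova_type3":
        res = anova_two_way_type3(values, sex, ranking, variable)
    elif method == "art_anova":
        res = art_anova(values, sex, ranking, variable)
    else:
        raise ValueError(f"unknown method {method!r}")
    if res.effects["interaction"].p <= alpha:
        groups = [f"{s}:{r}" for s, r in zip(sex, ranking)]
        res.posthoc = posthoc_pairwise_bonferroni(values, groups)
    return res


def posthoc_pairwise_bonferroni(
    values, group, m: int | None = None
) -> dict[str, float]:
    """Bonferroni-adjusted pairwise Welch t-tests: adjusted p = min(1, m*p).

    ``m`` defaults to the number of pairwise comparisons performed.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for pairwise comparisons")
    pairs = list(itertools.combinations(levels, 2))
    if m is None:
        m = len(pairs)
    out = {}
    for a, b in pairs:
        ya, yb = y[g == a], y[g == b]
        if len(ya) < 2 or len(yb) < 2:
            raise ValueError(f"singleton group in pair {a} vs {b}")
        p = sps.ttest_ind(ya, yb, equal_var=False).pvalue
        out[f"{a} vs {b}"] = min(1.0, m * float(p))
    return out


# --- correlations ---------------------------------------------------------

def pearson_label(r: float) -> str:
    """Effect-size label for a Pearson r: 0.10 / 0.30 / 0.50 thresholds."""
    a = abs(r)
    if a >= 0.50:
        return "large"
    if a >= 0.30:
        return "medium"
    if a >= 0.10:
        return "small"
    return "below-small"


def pearson_matrix(variables: dict[str, "np.ndarray"]) -> list[CorrelationResult]:
    """All pairwise Pearson correlations with two-sided p and effect labels.

    Complete-case: rows with a missing value in either variable of a pair are
    dropped for that pair.  Zero-variance variables are rejected.
    """
    names = list(variables)
    arrays = {k: np.asarray(v, dtype=float) for k, v in variables.items()}
    out = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = arrays[a], arrays[b]
        mask = np.isfinite(xa) & np.isfinite(xb)
        if mask.sum() < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 complete cases")
        va, vb = xa[mask], xb[mask]
        if va.std() == 0 or vb.std() == 0:
            raise ValueError(f"zero variance in pair ({a}, {b})")
        r, p = sps.pearsonr(va, vb)
        out.append(CorrelationResult((a, b), float(r), float(p), pearson_label(r)))
    return out


def effect_size_label(eta_sq_p: float) -> str:
    """Partial-eta-squared bands: small [0.01, 0.06), medium [0.06, 0.14), large >= 0.14."""
    if not 0.0 <= eta_sq_p <= 1.0:
        raise ValueError(f"partial eta squared must be in [0, 1], got {eta_sq_p}")
    if eta_sq_p >= 0.14:
        return "large"
    if eta_sq_p >= 0.06:
        return "medium"
    if eta_sq_p >= 0.01:
        return "small"
    return "below-small"


# --- design calculations --------------------------------------------------

def cochran_sample_size(
    population: float | None,
    z: float = 1.96,
    p: float = 0.5,
    margin: float = 0.05,
    fpc: bool = True,
) -> int:
    """Cochran required sample size, optionally finite-population corrected.

    n0 = z^2 p (1-p) / margin^2; with the correction
    n = n0 / (1 + (n0 - 1)/N).  Returns the ceiling.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if margin <= 0:
        raise ValueError("margin must be positive")
    n0 = z * z * p * (1.0 - p) / (margin * margin)
    if fpc:
        if population is None or population <= 0:
            raise ValueError("finite-population correction needs a population size")
        n0 = n0 / (1.0 + (n0 - 1.0) / population)
    return max(1, math.ceil(n0))


def anova_power(
    effect_f: float, alpha: float, groups: int, total_n: int
) -> float:
    """Power of the one-way omnibus F test via the noncentral F distribution.

    lambda = f^2 N, df1 = k-1, df2 = N-k;
    power = P(F'(df1, df2, lambda) > F_crit(1 - alpha)).
    """
    if total_n <= groups:
        raise ValueError("total_n must exceed the number of groups")
    df1 = groups - 1
    df2 = total_n - groups
    if df1 < 1:
        raise ValueError("need at least 2 groups")
    nc = effect_f**2 * total_n
    f_crit = sps.f.ppf(1.0 - alpha, df1, df2)
    if nc == 0:
        return float(alpha)
    return float(sps.ncf.sf(f_crit, df1, df2, nc))
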