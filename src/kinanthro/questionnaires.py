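"""Scoring of the A-NSKQ nutrition-knowledge and IPAQ-SF activity instruments.

A-NSKQ: 35 multiple-choice items, 11 on general nutrition knowledge (GNK) and
24 on sports nutrition knowledge (SNK).  Scores are percentages of correct
answers per subsection; the total (TNK) is the percentage over all 35 items,
i.e. the 11/24-weighted combination of the subsection percentages.  Knowledge
is banded poor / average / good / excellent.

IPAQ-SF: days per week and minutes per day of vigorous activity, moderate
activity and walking, plus sitting time.  Domain energy scores are
MET-weight x days x min/day (walking 3.3, moderate 4.0, vigorous 8.0 METs),
summed into a weekly MET-min total, optionally converted to kcal/week, and
categorised low / moderate / high by the standard scoring rules.  Cleaning
recodes sub-10-minute daily bouts to zero and flags records whose summed
daily activity exceeds 960 min (16 h) as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "ANSKQResponse",
    "NKScore",
    "IPAQRecord",
    "PALScore",
    "ExcludedRecordError",
    "DEFAULT_ANSWER_KEY",
    "GNK_ITEMS",
    "SNK_ITEMS",
    "MET_WEIGHTS",
    "score_anskq",
    "classify_nk",
    "ipaq_clean",
    "ipaq_met_minutes",
    "ipaq_category",
    "ipaq_kcal",
]

N_ITEMS = 35
GNK_ITEMS = tuple(range(0, 11))    # items 1-11 (0-based indices)
SNK_ITEMS = tuple(range(11, 35))   # items 12-35

# Placeholder answer key: the instrument's items are copyrighted and the key
# is not public, so deployments must supply their own.  The synthetic pipeline
# only needs *a* fixed key.
DEFAULT_ANSWER_KEY: tuple[str, ...] = tuple("abcd"[i % 4] for i in range(N_ITEMS))

MET_WEIGHTS = {"walking": 3.3, "moderate": 4.0, "vigorous": 8.0}

MIN_BOUT_MIN = 10.0       # daily bouts below this are recoded to zero
OUTLIER_DAILY_MIN = 960.0  # summed daily activity above 16 h is an outlier
TRUNCATE_DAILY_MIN = 180.0  # optional per-domain 3 h/day truncation rule


class ExcludedRecordError(ValueError):
    """Raised when a record flagged as an outlier reaches a scoring step."""


@dataclass
class ANSKQResponse:
    """One subject's 35 selected options; ``None`` marks an unanswered item."""

    item_answers: Sequence[str | None]
    answer_key: Sequence[str] = DEFAULT_ANSWER_KEY

    def __post_init__(self) -> None:
        if len(self.item_answers) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} answers, got {len(self.item_answers)}")
        if len(self.answer_key) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} key entries, got {len(self.answer_key)}")


@dataclass
class NKScore:
    gnk_pct: float
    snk_pct: float
    tnk_pct: float
    band: str


@dataclass
class IPAQRecord:
    vigorous_days: float
    vigorous_min: float
    moderate_days: float
    moderate_min: float
    walking_days: float
    walking_min: float
    sitting_min: float = 0.0
    body_mass: float | None = None
    excluded_as_outlier: bool = False

    def __post_init__(self) -> None:
        for name in ("vigorous_days", "moderate_days", "walking_days"):
            d = getattr(self, name)
            if not 0 <= d <= 7:
                raise ValueError(f"{name} must be in [0, 7], got {d}")
        for name in ("vigorous_min", "moderate_min", "walking_min", "sitting_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PALScore:
    walking_met: float
    moderate_met: float
    vigorous_met: float
    total_met: float
    category: str | None = None
    kcal_week: float | None = None
    excluded_as_outlier: bool = False


def score_anskq(r: ANSKQResponse) -> NKScore:
    """Percent-correct scores per subsection and overall; unanswered counts wrong."""
    def _correct(idx: tuple[int, ...]) -> int:
        return sum(
            1 for i in idx
            if r.item_answers[i] is not None
            and str(r.item_answers[i]).strip().lower() == str(r.answer_key[i]).strip().lower()
        )

    gnk = _correct(GNK_ITEMS)
    snk = _correct(SNK_ITEMS)
    gnk_pct = 100.0 * gnk / len(GNK_ITEMS)
    snk_pct = 100.0 * snk / len(SNK_ITEMS)
    tnk_pct = 100.0 * (gnk + snk) / N_ITEMS
    return NKScore(gnk_pct, snk_pct, tnk_pct, classify_nk(tnk_pct))


def classify_nk(score_pct: float) -> str:
    """Band a percent score: poor [0,50), average [50,66), good [66,76), excellent [76,100]."""
    if not 0.0 <= score_pct <= 100.0:
        raise ValueError(f"score must be in [0, 100], got {score_pct}")
    if score_pct < 50.0:
        return "poor"
    if score_pct < 66.0:
        return "average"
    if score_pct < 76.0:
        return "good"
    return "excellent"


def ipaq_clean(r: IPAQRecord, truncate_180: bool = False) -> IPAQRecord:
    """Apply the scoring-protocol cleaning rules; idempotent.

    Daily bouts shorter than 10 min are recoded to zero.  Records whose
    summed daily minutes across the three domains exceed 960 (16 h/day) are
    flagged as outliers.  ``truncate_180`` additionally caps each domain at
    180 min/day (the official long-protocol truncation), off by default.
    """
    vig = 0.0 if r.vigorous_min < MIN_BOUT_MIN else r.vigorous_min
    mod = 0.0 if r.moderate_min < MIN_BOUT_MIN else r.moderate_min
    walk = 0.0 if r.walking_min < MIN_BOUT_MIN else r.walking_min
    excluded = (vig + mod + walk) > OUTLIER_DAILY_MIN
    if truncate_180 and not excluded:
        vig = min(vig, TRUNCATE_DAILY_MIN)
        mod = min(mod, TRUNCATE_DAILY_MIN)
        walk = min(walk, TRUNCATE_DAILY_MIN)
    return replace(
        r,
        vigorous_min=vig,
        moderate_min=mod,
        walking_min=walk,
        excluded_as_outlier=excluded,
    )


def ipaq_met_minutes(r: IPAQRecord) -> PALScore:
    """Weekly MET-minutes per domain and total for a cleaned record."""
    walk = MET_WEIGHTS["walking"] * r.walking_days * r.walking_min
    mod = MET_WEIGHTS["moderate"] * r.moderate_days * r.moderate_min
    vig = MET_WEIGHTS["vigorous"] * r.vigorous_days * r.vigorous_min
    score = PALScore(
        walking_met=walk,
        moderate_met=mod,
        vigorous_met=vig,
        total_met=walk + mod + vig,
        excluded_as_outlier=r.excluded_as_outlier,
    )
    if not r.excluded_as_outlier:
        score.category = ipaq_category(score, r)
    if r.body_mass is not None:
        score.kcal_week = ipaq_kcal(score.total_met, r.body_mass)
    return score


def ipaq_category(score: PALScore, r: IPAQRecord) -> str:
    """Low / moderate / high physical-activity category.

    high: vigorous activity on >= 3 days with total >= 1500 MET-min/week, or
    >= 7 active days of any combination with total >= 3000.  moderate:
    >= 3 days vigorous >= 20 min/day, or >= 5 days of moderate activity or
    walking >= 30 min/day, or >= 5 active days of any combination with total
    >= 600.  Otherwise low.
    """
    if r.excluded_as_outlier or score.excluded_as_outlier:
        raise ExcludedRecordError("record excluded as an activity outlier")
    active_days = (
        (r.vigorous_days if r.vigorous_min > 0 else 0)
        + (r.moderate_days if r.moderate_min > 0 else 0)
        + (r.walking_days if r.walking_min > 0 else 0)
    )
    vig_active = r.vigorous_days if r.vigorous_min > 0 else 0
    if vig_active >= 3 and score.total_met >= 1500:
        return "high"
    if active_days >= 7 and score.total_met >= 3000:
        return "high"
    if r.vigorous_days >= 3 and r.vigorous_min >= 20:
        return "moderate"
    if (r.moderate_days >= 5 and r.moderate_min >= 30) or (
        r.walking_days >= 5 and r.walking_min >= 30
    ):
        return "moderate"
    if active_days >= 5 and score.total_met >= 600:
        return "moderate"
    return "low"


def ipaq_kcal(total_met: float, body_mass: float) -> float:
    """kcal/week from MET-min/week: MET-min x kg / 60 (the 60-kg-reference convention)."""
    if total_met < 0:
        raise ValueError("total MET-minutes must be >= 0")
    if body_mass is None or body_mass <= 0:
        raise ValueError("body mass in kg required for kcal conversion")
    return total_met * body_mass / 60.0
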