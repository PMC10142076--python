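"""Guideline-anchored per-food-group scoring and status levels.

Each food group carries a recommended weekly serving interval taken from the
"Small changes to eat better" dietary guide (Public Health Agency of
Catalonia) and a piecewise-constant score table over servings/week.  The
score is an integer distance-from-recommendation measure: 0 inside the
recommended interval, growing as consumption moves away from it, saturating
at the group's maximum.  Group importance is encoded in the maximum score:
10 for the groups with the strongest evidence of health impact (vegetables,
water, sugary foods, red meat, processed meat, ultra-processed foods), 9 for
fruits, 8 for every other group.

Scores are collapsed onto a three-level adherence status per group —
1 = poor, 2 = average, 3 = good — via score bands (default: score > 5 is
poor, 3–5 average, < 3 good).  The status level is what the gamification
layer surfaces as the user's mission level.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError
from .ffq import UserProfile

__all__ = [
    "MAX_SCORE_10_GROUPS",
    "MAX_SCORE_9_GROUPS",
    "DEFAULT_LEVEL_BANDS",
    "ScoreBand",
    "LevelBands",
    "GuidelineEntry",
    "Score",
    "ScoreBoard",
    "score_food_group",
    "assign_status_level",
    "score_profile",
    "validate_guidelines",
    "load_guidelines",
]

#: Groups considered most health-relevant and therefore scored out of 10.
MAX_SCORE_10_GROUPS = frozenset(
    {"vegetables", "water", "sugary_foods", "red_meat", "processed_meat",
     "ultraprocessed"}
)
#: Fruits are scored out of 9; every remaining group out of 8.
MAX_SCORE_9_GROUPS = frozenset({"fruits"})

STATUS_LABELS = {1: "poor", 2: "average", 3: "good"}


@dataclass(frozen=True)
class ScoreBand:
    """One row of a score table: servings in (prev_upto, upto] -> score.

    The first row of a table covers [0, upto]; ``upto is None`` means +inf.
    Upper-inclusive rows make guideline phrasings like "more than seven
    servings/week" exact: the extreme band starts strictly above 7.
    """

    upto: float | None
    score: int


@dataclass(frozen=True)
class LevelBands:
    """Score cutoffs for the three-level adherence status.

    Defaults: score > ``poor_above`` -> level 1 (poor);
    ``average_from`` <= score <= ``poor_above`` -> level 2 (average);
    score < ``average_from`` -> level 3 (good).
    """

    poor_above: int = 5
    average_from: int = 3

    def level(self, score: int) -> int:
        if score > self.poor_above:
            return 1
        if score >= self.average_from:
            return 2
        return 3


DEFAULT_LEVEL_BANDS = LevelBands()


@dataclass(frozen=True)
class GuidelineEntry:
    """Scoring configuration for one food group."""

    food_group_id: str
    direction: str  # "encourage" | "limit"
    recommended_lo: float
    recommended_hi: float | None  # None = unbounded above
    max_score: int
    score_table: tuple[ScoreBand, ...]
    level_bands: LevelBands = field(default_factory=LevelBands)

    def __post_init__(self):
        if self.direction not in ("encourage", "limit"):
            raise ConfigurationError(
                f"{self.food_group_id}: direction must be encourage|limit"
            )
        if not self.score_table:
            raise ConfigurationError(f"{self.food_group_id}: empty score table")
        if self.score_table[-1].upto is not None:
            raise ConfigurationError(
                f"{self.food_group_id}: last score band must be unbounded"
            )

    def lookup(self, servings: float) -> int:
        prev = -math.inf
        for band in self.score_table:
            hi = math.inf if band.upto is None else band.upto
            if prev < servings <= hi or (servings == 0 and prev == -math.inf):
                return band.score
            prev = hi
        raise ConfigurationError(  # unreachable with a well-formed table
            f"{self.food_group_id}: score table not total at {servings}"
        )

    def in_recommended(self, servings: float) -> bool:
        hi = math.inf if self.recommended_hi is None else self.recommended_hi
        return self.recommended_lo <= servings <= hi


@dataclass(frozen=True)
class Score:
    food_group_id: str
    value: int

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError(f"score must be >= 0, got {self.value}")


@dataclass(frozen=True)
class ScoreBoard:
    """Per-group (score, status level) snapshot for one user."""

    user_id: str
    entries: dict[str, tuple[Score, int]]
    assessed_on: _dt.date | None = None

    def score_of(self, group: str) -> int:
        return self.entries[group][0].value

    def level_of(self, group: str) -> int:
        return self.entries[group][1]


def score_food_group(servings: float, entry: GuidelineEntry) -> Score:
    """Score one food group's weekly servings against its guideline.

    0 inside the recommended interval; the configured maximum at the
    saturating extreme.
    """
    if servings < 0:
        raise ValidationError(
            f"{entry.food_group_id}: servings must be >= 0, got {servings}"
        )
    value = entry.lookup(servings)
    if value > entry.max_score:
        raise ConfigurationError(
            f"{entry.food_group_id}: table score {value} exceeds max "
            f"{entry.max_score}"
        )
    return Score(food_group_id=entry.food_group_id, value=value)


def assign_status_level(score: Score, entry: GuidelineEntry) -> int:
    """Map a score onto the three-level status (1 poor, 2 average, 3 good)."""
    if score.food_group_id != entry.food_group_id:
        raise ValidationError(
            f"score for {score.food_group_id!r} applied to entry "
            f"{entry.food_group_id!r}"
        )
    if score.value > entry.max_score:
        raise ValidationError(
            f"{entry.food_group_id}: score {score.value} > max {entry.max_score}"
        )
    return entry.level_bands.level(score.value)


def score_profile(
    profile: UserProfile, guidelines: list[GuidelineEntry]
) -> ScoreBoard:
    """Score every configured food group of a profile."""
    missing = sorted(
        e.food_group_id
        for e in guidelines
        if e.food_group_id not in profile.weekly_servings
    )
    if missing:
        raise ValidationError(
            f"profile {profile.user_id!r} missing food groups: {missing}",
            details=missing,
        )
    entries: dict[str, tuple[Score, int]] = {}
    for entry in sorted(guidelines, key=lambda e: e.food_group_id):
        sc = score_food_group(profile.weekly_servings[entry.food_group_id], entry)
        entries[entry.food_group_id] = (sc, assign_status_level(sc, entry))
    return ScoreBoard(
        user_id=profile.user_id, entries=entries, assessed_on=profile.last_assessed
    )


# ---------------------------------------------------------------------------
# Config validation


def _distance(servings: float, entry: GuidelineEntry) -> float:
    hi = math.inf if entry.recommended_hi is None else entry.recommended_hi
    if servings < entry.recommended_lo:
        return entry.recommended_lo - servings
    if servings > hi:
        return servings - hi
    return 0.0


def validate_guidelines(
    guidelines: list[GuidelineEntry], *, grid_step: float = 0.25
) -> list[str]:
    """Check a guideline set against the printed scoring constraints.

    Returns a (possibly empty) list of human-readable violations covering:
    the 10/9/8 maximum-score assignment, table totality and saturation,
    zero-score inside the recommended interval, monotone non-decreasing score
    with distance from the recommendation (grid scan), and the nuts serving
    bands (0/1/2 servings -> status 1; > 3 servings -> status 3).
    """
    violations: list[str] = []
    for e in guidelines:
        expected_max = (
            10 if e.food_group_id in MAX_SCORE_10_GROUPS
            else 9 if e.food_group_id in MAX_SCORE_9_GROUPS
            else 8
        )
        if e.max_score != expected_max:
            violations.append(
                f"{e.food_group_id}: max_score {e.max_score}, expected {expected_max}"
            )
        table_max = max(b.score for b in e.score_table)
        if table_max != e.max_score:
            violations.append(
                f"{e.food_group_id}: table maximum {table_max} != max_score "
                f"{e.max_score}"
            )
        # grid scan: totality, zero-inside-recommendation, monotonicity
        top = max(
            (b.upto for b in e.score_table if b.upto is not None), default=10.0
        )
        grid = [i * grid_step for i in range(int((top + 5) / grid_step) + 1)]
        below: list[tuple[float, int]] = []
        above: list[tuple[float, int]] = []
        for s in grid:
            try:
                v = e.lookup(s)
            except ConfigurationError:
                violations.append(f"{e.food_group_id}: table not total at {s}")
                continue
            d = _distance(s, e)
            if d == 0.0 and v != 0:
                violations.append(
                    f"{e.food_group_id}: score {v} != 0 at recommended {s}"
                )
            if s < e.recommended_lo:
                below.append((d, v))
            elif d > 0:
                above.append((d, v))
        for side, pts in (("below", below), ("above", above)):
            pts.sort()
            for (d1, v1), (d2, v2) in zip(pts, pts[1:]):
                if d2 > d1 and v2 < v1:
                    violations.append(
                        f"{e.food_group_id}: score decreases with distance "
                        f"{side} recommendation ({v1}@{d1} -> {v2}@{d2})"
                    )
                    break
    # nuts bands must match the published mission eligibility cutoffs
    nuts = next((e for e in guidelines if e.food_group_id == "nuts"), None)
    if nuts is not None:
        for s in (0.0, 1.0, 2.0):
            lvl = nuts.level_bands.level(nuts.lookup(s))
            if lvl != 1:
                violations.append(
                    f"nuts: {s} servings/week -> status {lvl}, expected 1 (poor)"
                )
        for s in (3.5, 4.0, 5.0, 6.0, 7.0):
            lvl = nuts.level_bands.level(nuts.lookup(s))
            if lvl != 3:
                violations.append(
                    f"nuts: {s} servings/week -> status {lvl}, expected 3 (good)"
                )
    return violations


# ---------------------------------------------------------------------------
# Config loading


def load_guidelines(doc: dict) -> list[GuidelineEntry]:
    """Parse a guideline config document (parsed YAML/JSON)."""
    entries: list[GuidelineEntry] = []
    seen: set[str] = set()
    for g in doc["food_groups"]:
        gid = g["food_group_id"]
        if gid in seen:
            raise ConfigurationError(f"duplicate food group {gid!r}")
        seen.add(gid)
        bands_cfg = g.get("level_bands", {})
        table = tuple(
            ScoreBand(
                upto=None if row["upto"] is None else float(row["upto"]),
                score=int(row["score"]),
            )
            for row in g["score_table"]
        )
        rec = g["recommended_weekly"]
        entries.append(
            GuidelineEntry(
                food_group_id=gid,
                direction=g["direction"],
                recommended_lo=float(rec["lo"]),
                recommended_hi=None if rec["hi"] is None else float(rec["hi"]),
                max_score=int(g["max_score"]),
                score_table=table,
                level_bands=LevelBands(
                    poor_above=int(bands_cfg.get("poor_above", 5)),
                    average_from=int(bands_cfg.get("average_from", 3)),
                ),
            )
        )
    return entries
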