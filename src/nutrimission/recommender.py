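"""Motivational repository and the notification scheduler.

The repository holds three kinds of motivational content:

* ``did_you_know`` tips — educational statements about a food group, sent
  once when a mission starts (risk perception / education);
* ``general`` — healthy-eating advice not tied to any mission, sent weekly
  (outcome expectancies);
* ``mission_linked`` — practical tips, ideas and recipes for one specific
  mission, sent on an every-two-days cadence in a curated order
  (self-efficacy).  The shipped repository carries 10 per mission over the
  39 missions (390 entries) and more than 500 entries in total.

Every entry is tagged for dietary suitability; a user only ever receives
content compatible with their restrictions (coeliac, vegan,
ovo-/lacto-ovo-vegetarian).

Scheduling cadence (per active mission, one notification per day at most):
a tip on day 0, mission-linked content on even days from day 2, and one
general recommendation per 7-day block on the block's fifth day (shifted a
day forward when it would collide).  Weeks after the first deliver 3-4
notifications; the onboarding week carries one extra (the day-0 tip).
"""

from __future__ import annotations

import datetime as _dt
import logging
import random
from dataclasses import dataclass

from .errors import StateError, ValidationError
from .ffq import DietaryPreferences
from .missions import MissionInstance, MissionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "REC_TYPES",
    "DIETARY_TAGS",
    "ALL_TAGS",
    "Recommendation",
    "Repository",
    "ScheduledNotification",
    "SchedulerConfig",
    "load_repository",
    "build_default_repository",
    "required_tags",
    "eligible",
    "build_schedule",
    "coping_notice",
]

REC_TYPES = ("did_you_know", "general", "mission_linked")
DIETARY_TAGS = (
    "vegan",
    "ovo_vegetarian",
    "lacto_ovo_vegetarian",
    "gluten_free",
    "omnivore",
)
ALL_TAGS = frozenset(DIETARY_TAGS)
TIME_SLOTS = ("morning", "midday", "evening")


@dataclass(frozen=True)
class Recommendation:
    rec_id: str
    rec_type: str
    title: str
    sentence: str
    food_group_id: str | None = None
    mission_id: str | None = None
    order_index: int | None = None
    dietary_tags: frozenset[str] = ALL_TAGS
    time_slot: str | None = None

    def __post_init__(self):
        if self.rec_type not in REC_TYPES:
            raise ValidationError(f"{self.rec_id}: unknown rec_type {self.rec_type!r}")
        if self.rec_type == "mission_linked" and not self.mission_id:
            raise ValidationError(f"{self.rec_id}: mission_linked needs mission_id")
        if self.rec_type == "did_you_know" and not self.food_group_id:
            raise ValidationError(f"{self.rec_id}: did_you_know needs food_group_id")
        if self.order_index is not None and self.rec_type != "mission_linked":
            raise ValidationError(
                f"{self.rec_id}: order_index only applies to mission_linked"
            )
        unknown = set(self.dietary_tags) - ALL_TAGS
        if unknown:
            raise ValidationError(f"{self.rec_id}: unknown dietary tags {unknown}")
        if self.time_slot is not None and self.time_slot not in TIME_SLOTS:
            raise ValidationError(f"{self.rec_id}: unknown time_slot {self.time_slot!r}")


@dataclass(frozen=True)
class Repository:
    recommendations: tuple[Recommendation, ...]

    def of_type(self, rec_type: str) -> tuple[Recommendation, ...]:
        return tuple(r for r in self.recommendations if r.rec_type == rec_type)

    def for_mission(self, mission_id: str) -> tuple[Recommendation, ...]:
        return tuple(
            r
            for r in self.recommendations
            if r.rec_type == "mission_linked" and r.mission_id == mission_id
        )

    def tips_for_group(self, food_group_id: str) -> tuple[Recommendation, ...]:
        return tuple(
            r
            for r in self.recommendations
            if r.rec_type == "did_you_know" and r.food_group_id == food_group_id
        )


@dataclass(frozen=True)
class ScheduledNotification:
    """One delivery slot; ``rec_id`` is None for engine-generated notices."""

    date: _dt.date
    reason: str  # mission_start_tip | mission_cadence | weekly_general | coping | congratulation
    rec_id: str | None = None
    message: str = ""
    alternatives: tuple[str, ...] = ()


@dataclass(frozen=True)
class SchedulerConfig:
    """Cadence constants (kept explicit, not hard-coded in the algorithm)."""

    tip_day: int = 0
    mission_start_day: int = 2
    mission_every_days: int = 2
    general_block_days: int = 7
    general_day_in_block: int = 5
    collision_shift_days: int = 1
    max_per_block: int = 4  # steady-state weekly ceiling (3-4 per week)


def validate_repository(
    repo: Repository,
    *,
    mission_ids: set[str] | None = None,
    food_groups: set[str] | None = None,
    min_total: int = 501,
) -> list[str]:
    """Composition checks; returns violations (empty when valid)."""
    violations: list[str] = []
    counts = {t: len(repo.of_type(t)) for t in REC_TYPES}
    total = len(repo.recommendations)
    if total < min_total:
        violations.append(
            f"repository has {total} entries, needs more than {min_total - 1} "
            f"(by type: {counts})"
        )
    ids = [r.rec_id for r in repo.recommendations]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        violations.append(f"duplicate rec_ids: {dupes[:10]}")
    if mission_ids is not None:
        uncovered = sorted(
            m for m in mission_ids if not repo.for_mission(m)
        )
        if uncovered:
            violations.append(
                f"missions without mission_linked recommendations: {uncovered}"
            )
    if food_groups is not None:
        uncovered = sorted(
            g for g in food_groups if not repo.tips_for_group(g)
        )
        if uncovered:
            violations.append(
                f"food groups without did_you_know tips: {uncovered}"
            )
    return violations


def load_repository(
    doc: dict | list,
    *,
    mission_ids: set[str] | None = None,
    food_groups: set[str] | None = None,
) -> Repository:
    """Parse a repository JSON document and enforce composition invariants."""
    records = doc["recommendations"] if isinstance(doc, dict) else doc
    recs = tuple(
        Recommendation(
            rec_id=r["rec_id"],
            rec_type=r["rec_type"],
            title=r["title"],
            sentence=r["sentence"],
            food_group_id=r.get("food_group_id"),
            mission_id=r.get("mission_id"),
            order_index=r.get("order_index"),
            dietary_tags=frozenset(r.get("dietary_tags", DIETARY_TAGS)),
            time_slot=r.get("time_slot"),
        )
        for r in records
    )
    repo = Repository(recommendations=recs)
    violations = validate_repository(
        repo, mission_ids=mission_ids, food_groups=food_groups
    )
    if violations:
        raise ValidationError(
            "repository composition invalid: " + "; ".join(violations),
            details=violations,
        )
    return repo


# ---------------------------------------------------------------------------
# Default repository (placeholder prose; composition counts are normative)

_GROUP_FACTS = (
    "is linked to better long-term health markers in observational cohorts",
    "is one of the focus points of current dietary guidelines",
    "can be adjusted with small, concrete weekly habits",
    "influences satiety and the overall quality of your diet",
    "is easier to improve when you plan your shopping ahead",
)

_GENERAL_THEMES = (
    "Plan your weekly menu before you shop",
    "Cook once, eat twice: batch-cook staples",
    "Eat slowly and without screens",
    "Keep healthy snacks visible and ready",
    "Read labels: shorter ingredient lists are usually better",
    "Season with herbs and spices instead of salt",
    "Choose seasonal and locally grown produce",
    "Keep a fruit bowl on the kitchen counter",
    "Drink a glass of water before every meal",
    "Make half your plate vegetables",
)

#: Per-mission tag pattern: seven universal entries, one vegetarian-specific,
#: one omnivore-specific, one gluten-free-and-omnivore entry, so every
#: dietary-preference combination keeps eligible content for every mission.
_MISSION_TAG_PATTERN: tuple[frozenset[str], ...] = (
    ALL_TAGS, ALL_TAGS, ALL_TAGS, ALL_TAGS, ALL_TAGS, ALL_TAGS, ALL_TAGS,
    frozenset({"vegan", "ovo_vegetarian", "lacto_ovo_vegetarian", "gluten_free"}),
    frozenset({"omnivore"}),
    frozenset({"gluten_free", "omnivore"}),
)

RECS_PER_MISSION = len(_MISSION_TAG_PATTERN)
TIPS_PER_GROUP = 5
N_GENERAL = 50


def build_default_repository(
    mission_specs: list[MissionSpec] | tuple[MissionSpec, ...],
    food_groups: list[str] | tuple[str, ...],
) -> Repository:
    """Generate the shipped default repository.

    10 mission-linked entries per mission (= 390 for the full catalogue),
    5 tips per food group, and 50 general recommendations; text is
    programmatically generated placeholder prose — the composition counts
    and dietary tagging are the normative parts.
    """
    recs: list[Recommendation] = []
    for spec in mission_specs:
        for i, tags in enumerate(_MISSION_TAG_PATTERN, start=1):
            recs.append(
                Recommendation(
                    rec_id=f"ml_{spec.mission_id}_{i:02d}",
                    rec_type="mission_linked",
                    title=f"Step {i} towards '{spec.title}'",
                    sentence=(
                        f"Practical idea #{i} for the mission "
                        f"'{spec.title}': a concrete tip, swap or recipe to "
                        f"move your {spec.food_group_id.replace('_', ' ')} "
                        f"habits forward this week."
                    ),
                    food_group_id=spec.food_group_id,
                    mission_id=spec.mission_id,
                    order_index=i,
                    dietary_tags=tags,
                    time_slot="midday" if i % 3 == 0 else None,
                )
            )
    for group in food_groups:
        for i, fact in enumerate(_GROUP_FACTS[:TIPS_PER_GROUP], start=1):
            recs.append(
                Recommendation(
                    rec_id=f"dyk_{group}_{i:02d}",
                    rec_type="did_you_know",
                    title=f"Did you know...? About {group.replace('_', ' ')}",
                    sentence=(
                        f"Did you know that your intake of "
                        f"{group.replace('_', ' ')} {fact}?"
                    ),
                    food_group_id=group,
                    time_slot="morning",
                )
            )
    for i in range(1, N_GENERAL + 1):
        theme = _GENERAL_THEMES[(i - 1) % len(_GENERAL_THEMES)]
        recs.append(
            Recommendation(
                rec_id=f"gen_{i:03d}",
                rec_type="general",
                title=theme,
                sentence=(
                    f"General healthy-eating advice #{i}: {theme.lower()} — "
                    f"a small routine that supports every mission."
                ),
            )
        )
    return Repository(recommendations=tuple(recs))


# ---------------------------------------------------------------------------
# Dietary-preference filtering


def required_tags(prefs: DietaryPreferences) -> list[set[str]]:
    """Tag requirements implied by preferences.

    Returns a list of acceptable-tag sets; a recommendation is eligible iff
    for every requirement its tags intersect the acceptable set.  Vegan
    content is acceptable to ovo- and lacto-ovo-vegetarians.
    """
    reqs: list[set[str]] = []
    if prefs.coeliac:
        reqs.append({"gluten_free"})
    if prefs.vegetarian_type == "vegan":
        reqs.append({"vegan"})
    elif prefs.vegetarian_type == "ovo_vegetarian":
        reqs.append({"ovo_vegetarian", "vegan"})
    elif prefs.vegetarian_type == "lacto_ovo_vegetarian":
        reqs.append({"lacto_ovo_vegetarian", "vegan"})
    return reqs


def eligible(
    repo: Repository, prefs: DietaryPreferences
) -> tuple[Recommendation, ...]:
    """Subset of the repository compatible with the user's dietary needs."""
    reqs = required_tags(prefs)
    return tuple(
        r
        for r in repo.recommendations
        if all(r.dietary_tags & req for req in reqs)
    )


# ---------------------------------------------------------------------------
# Scheduling


class _Rotation:
    """Seeded no-repeat rotation over a pool of recommendations.

    Mission-linked pools are ordered by ascending ``order_index``; entries
    sharing an index (and untyped pools) are permuted by the seeded RNG.
    The pool is fully consumed before any entry repeats; each new cycle is
    re-permuted.
    """

    def __init__(self, pool: tuple[Recommendation, ...], rng: random.Random):
        self._pool = list(pool)
        self._rng = rng
        self._queue: list[Recommendation] = []

    def _refill(self) -> None:
        groups: dict[int, list[Recommendation]] = {}
        for r in self._pool:
            groups.setdefault(
                r.order_index if r.order_index is not None else 0, []
            ).append(r)
        out: list[Recommendation] = []
        for idx in sorted(groups):
            batch = sorted(groups[idx], key=lambda r: r.rec_id)
            self._rng.shuffle(batch)
            out.extend(batch)
        self._queue = out

    def next(self) -> Recommendation | None:
        if not self._pool:
            return None
        if not self._queue:
            self._refill()
        return self._queue.pop(0)


def _mission_days(horizon_days: int, cfg: SchedulerConfig) -> list[int]:
    """Mission-cadence days, capped so steady-state weeks stay at 3-4.

    Nominally every other day from day 2; in 7-day blocks (after the first)
    that would otherwise receive five notifications, the block's first slot
    is dropped.
    """
    nominal = list(
        range(cfg.mission_start_day, horizon_days, cfg.mission_every_days)
    )
    days: list[int] = []
    block_len = cfg.general_block_days
    for block_start in range(0, horizon_days, block_len):
        block = [d for d in nominal if block_start <= d < block_start + block_len]
        # the weekly general takes one slot of every block after the first
        if block_start > 0 and len(block) + 1 > cfg.max_per_block:
            block = block[len(block) + 1 - cfg.max_per_block:]
        days.extend(block)
    return days


def build_schedule(
    instance: MissionInstance,
    mission_spec: MissionSpec,
    prefs: DietaryPreferences,
    repo: Repository,
    horizon_days: int,
    seed: int,
    *,
    config: SchedulerConfig = SchedulerConfig(),
    start_date: _dt.date | None = None,
) -> list[ScheduledNotification]:
    """Plan the notification calendar for an active mission.

    Day 0 carries the mission's *Did you know...?* tip; mission-linked
    content follows every other day; one general recommendation lands in
    every 7-day block (on its fifth day, shifted forward a day on
    collision).  At most one notification per day.
    """
    if instance.state != "active":
        raise StateError("build_schedule requires an active mission instance")
    if horizon_days < 1:
        raise ValidationError(f"horizon_days must be >= 1, got {horizon_days}")
    if mission_spec.mission_id != instance.mission_id:
        raise ValidationError("mission spec does not match the instance")
    anchor = start_date or instance.started_on or _dt.date.today()
    rng = random.Random(seed)
    pool = eligible(repo, prefs)
    tips = _Rotation(
        tuple(
            r for r in pool
            if r.rec_type == "did_you_know"
            and r.food_group_id == mission_spec.food_group_id
        ),
        rng,
    )
    linked = _Rotation(
        tuple(
            r for r in pool
            if r.rec_type == "mission_linked"
            and r.mission_id == mission_spec.mission_id
        ),
        rng,
    )
    generals = _Rotation(
        tuple(r for r in pool if r.rec_type == "general"), rng
    )

    slots: list[tuple[int, str, _Rotation]] = []
    if config.tip_day < horizon_days:
        slots.append((config.tip_day, "mission_start_tip", tips))
    mission_days = _mission_days(horizon_days, config)
    for d in mission_days:
        slots.append((d, "mission_cadence", linked))
    taken = {d for d, _, _ in slots}
    for block_start in range(0, horizon_days, config.general_block_days):
        g = block_start + config.general_day_in_block
        while g in taken:
            g += config.collision_shift_days
        if g < horizon_days and g < block_start + 2 * config.general_block_days:
            slots.append((g, "weekly_general", generals))
            taken.add(g)

    out: list[ScheduledNotification] = []
    for day, reason, rotation in sorted(slots, key=lambda s: (s[0], s[1])):
        rec = rotation.next()
        if rec is None:
            logger.warning(
                "no eligible recommendation for %s slot on day %d "
                "(mission %s); slot skipped",
                reason, day, mission_spec.mission_id,
            )
            continue
        out.append(
            ScheduledNotification(
                date=anchor + _dt.timedelta(days=day),
                reason=reason,
                rec_id=rec.rec_id,
                message=rec.sentence,
            )
        )
    dates = [n.date for n in out]
    assert len(dates) == len(set(dates)), "one-per-day invariant violated"
    return out


def coping_notice(
    instance: MissionInstance, alternatives: list[MissionSpec], on: _dt.date
) -> ScheduledNotification:
    """Coping-planning notification for a stuck mission.

    Offers at least one alternative mission drawn from the current proposal.
    """
    if instance.state != "stuck":
        raise StateError("coping_notice requires a stuck mission instance")
    if not alternatives:
        raise ValidationError("coping notice needs at least one alternative")
    titles = "; ".join(s.title for s in alternatives)
    return ScheduledNotification(
        date=on,
        reason="coping",
        message=(
            "You seem stuck on your current mission — that happens! "
            f"You could switch to one of these instead: {titles}"
        ),
        alternatives=tuple(s.mission_id for s in alternatives),
    )
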