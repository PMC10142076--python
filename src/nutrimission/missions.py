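"""Mission catalogue, ranked proposal, and the mission lifecycle.

A mission is a gamified dietary goal tied to one food group at one of three
levels (1 beginner, 2 advanced, 3 expert).  The shipped catalogue holds
exactly 13 food groups x 3 levels = 39 missions.  Users work on one mission
at a time; compliance is self-reported through button presses, progress is
evaluated daily, and completing a mission promotes the user to the next
level of the same food group (or, at expert level, to the next-ranked food
group).

The lifecycle state machine::

    proposed -> active -> {completed, stuck, abandoned}
                stuck  -> {active, abandoned}

Stuck and expired missions are both handled by coping planning (alternative
missions are offered); they are never treated as failures.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

from .errors import ConfigurationError, StateError, ValidationError
from .ffq import UserProfile
from .scoring import (
    GuidelineEntry,
    ScoreBoard,
    Score,
    assign_status_level,
    score_food_group,
    score_profile,
)

__all__ = [
    "LEVELS",
    "MissionSpec",
    "MissionCatalogue",
    "MissionInstance",
    "RankedCandidate",
    "load_catalogue",
    "mission_level_for",
    "rank_candidates",
    "propose_missions",
    "start_mission",
    "switch_mission",
    "log_compliance",
    "evaluate_progress",
    "apply_evaluation",
    "on_completion",
]

LEVELS = (1, 2, 3)
LEVEL_NAMES = {1: "beginner", 2: "advanced", 3: "expert"}

#: Legal state transitions of a mission instance.
_TRANSITIONS = {
    "proposed": {"active"},
    "active": {"completed", "stuck", "abandoned"},
    "stuck": {"active", "abandoned"},
    "completed": set(),
    "abandoned": set(),
}


@dataclass(frozen=True)
class MissionSpec:
    """Catalogue entry: one food group at one level."""

    mission_id: str
    food_group_id: str
    level: int
    title: str
    description: str
    eligibility_min: float = 0.0
    eligibility_max: float | None = None  # None = unbounded
    requires: str | None = None  # prerequisite mission_id (level below)
    target_count: int = 3
    time_limit_days: int = 7

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ConfigurationError(f"{self.mission_id}: level must be 1..3")
        if self.target_count < 1 or self.time_limit_days < 1:
            raise ConfigurationError(
                f"{self.mission_id}: target_count and time_limit_days must be >= 1"
            )

    def band_contains(self, servings: float) -> bool:
        hi = float("inf") if self.eligibility_max is None else self.eligibility_max
        return self.eligibility_min <= servings <= hi


@dataclass(frozen=True)
class MissionCatalogue:
    specs: tuple[MissionSpec, ...]
    food_groups: tuple[str, ...]

    def __post_init__(self):
        problems: list[str] = []
        if len(self.food_groups) != 13:
            problems.append(
                f"expected 13 food groups, got {len(self.food_groups)}"
            )
        pairs = {(s.food_group_id, s.level) for s in self.specs}
        if len(pairs) != len(self.specs):
            seen: set[tuple[str, int]] = set()
            for s in self.specs:
                key = (s.food_group_id, s.level)
                if key in seen:
                    problems.append(f"duplicate (group, level): {key}")
                seen.add(key)
        expected = {(g, lvl) for g in self.food_groups for lvl in LEVELS}
        missing = sorted(expected - pairs)
        extra = sorted(pairs - expected)
        if missing:
            problems.append(f"missing (group, level) pairs: {missing}")
        if extra:
            problems.append(f"unexpected (group, level) pairs: {extra}")
        if len(self.specs) != 39:
            problems.append(f"expected 39 missions, got {len(self.specs)}")
        if problems:
            raise ValidationError(
                "mission catalogue invalid: " + "; ".join(problems),
                details=problems,
            )

    def get(self, food_group_id: str, level: int) -> MissionSpec:
        for s in self.specs:
            if s.food_group_id == food_group_id and s.level == level:
                return s
        raise ValidationError(f"no mission for ({food_group_id!r}, {level})")

    def by_id(self, mission_id: str) -> MissionSpec:
        for s in self.specs:
            if s.mission_id == mission_id:
                return s
        raise ValidationError(f"unknown mission {mission_id!r}")


@dataclass(frozen=True)
class MissionInstance:
    """Live state of one user's mission."""

    instance_id: str
    mission_id: str
    user_id: str
    state: str = "proposed"
    started_on: _dt.date | None = None
    compliance_log: tuple[_dt.date, ...] = ()
    progress: int = 0

    def __post_init__(self):
        if self.state not in _TRANSITIONS:
            raise ValidationError(f"unknown mission state {self.state!r}")
        if self.progress != len(self.compliance_log):
            raise ValidationError(
                f"progress {self.progress} != compliance log length "
                f"{len(self.compliance_log)}"
            )

    def _transition(self, new_state: str) -> "MissionInstance":
        if new_state not in _TRANSITIONS[self.state]:
            raise StateError(
                f"illegal mission transition {self.state} -> {new_state} "
                f"({self.mission_id})"
            )
        return replace(self, state=new_state)


@dataclass(frozen=True)
class RankedCandidate:
    food_group_id: str
    level: int
    score: Score
    rank: int


def load_catalogue(doc: dict) -> MissionCatalogue:
    """Parse and validate a mission-catalogue document (parsed YAML/JSON)."""
    target_default = int(doc.get("target_count_default", 3))
    limit_default = int(doc.get("time_limit_days_default", 7))
    specs = []
    for m in doc["missions"]:
        elig = m.get("eligibility", {})
        specs.append(
            MissionSpec(
                mission_id=m["mission_id"],
                food_group_id=m["food_group_id"],
                level=int(m["level"]),
                title=m["title"],
                description=m.get("description", ""),
                eligibility_min=float(elig.get("min", 0)),
                eligibility_max=(
                    None if elig.get("max") is None else float(elig["max"])
                ),
                requires=elig.get("requires"),
                target_count=int(m.get("target_count", target_default)),
                time_limit_days=int(m.get("time_limit_days", limit_default)),
            )
        )
    groups = tuple(dict.fromkeys(s.food_group_id for s in specs))
    return MissionCatalogue(specs=tuple(specs), food_groups=groups)


def mission_level_for(
    food_group_id: str,
    servings: float,
    history: frozenset[str] | set[str],
    catalogue: MissionCatalogue,
    guidelines: list[GuidelineEntry],
) -> int:
    """Mission level for a food group: status banding plus level promotion.

    The base level is the adherence status of the group's score; whenever the
    mission at that level has already been completed, the user is promoted one
    level (prerequisite semantics), never beyond level 3.
    """
    if food_group_id not in catalogue.food_groups:
        raise ValidationError(f"unknown food group {food_group_id!r}")
    entry = next(
        (e for e in guidelines if e.food_group_id == food_group_id), None
    )
    if entry is None:
        raise ValidationError(f"no guideline for food group {food_group_id!r}")
    score = score_food_group(servings, entry)
    level = assign_status_level(score, entry)
    while level < 3 and catalogue.get(food_group_id, level).mission_id in history:
        level += 1
    return level


def rank_candidates(
    board: ScoreBoard,
    profile: UserProfile,
    catalogue: MissionCatalogue,
    guidelines: list[GuidelineEntry],
) -> list[RankedCandidate]:
    """Rank food groups by need: the ranked "Food Group + Level" list.

    Sort key: score descending; ties broken by the group's maximum possible
    score descending (more health-relevant groups first), then groups the
    user marked as liked, then the configured catalogue order.  Groups whose
    expert (level 3) mission is already completed are excluded.
    """
    missing = sorted(set(catalogue.food_groups) - set(board.entries))
    if missing:
        raise ValidationError(f"scoreboard missing groups: {missing}")
    max_by_group = {e.food_group_id: e.max_score for e in guidelines}
    order = {g: i for i, g in enumerate(catalogue.food_groups)}
    eligible = [
        g
        for g in catalogue.food_groups
        if catalogue.get(g, 3).mission_id not in profile.completed_missions
    ]
    eligible.sort(
        key=lambda g: (
            -board.score_of(g),
            -max_by_group.get(g, 0),
            0 if g in profile.liked_groups else 1,
            order[g],
        )
    )
    return [
        RankedCandidate(
            food_group_id=g,
            level=mission_level_for(
                g,
                profile.weekly_servings[g],
                profile.completed_missions,
                catalogue,
                guidelines,
            ),
            score=board.entries[g][0],
            rank=i + 1,
        )
        for i, g in enumerate(eligible)
    ]


def propose_missions(
    ranked: list[RankedCandidate], catalogue: MissionCatalogue
) -> list[MissionSpec]:
    """The top-3 proposal shown to the user (fewer if fewer candidates)."""
    return [
        catalogue.get(c.food_group_id, c.level) for c in ranked[:3]
    ]


# ---------------------------------------------------------------------------
# Lifecycle


def start_mission(
    spec: MissionSpec,
    user_id: str,
    start_date: _dt.date,
    existing: list[MissionInstance] = (),
    *,
    instance_id: str | None = None,
) -> MissionInstance:
    """Activate a mission; at most one active mission per user."""
    for inst in existing:
        if inst.user_id == user_id and inst.state in ("active", "stuck"):
            raise StateError(
                f"user {user_id!r} already has mission {inst.mission_id!r} "
                f"in state {inst.state!r}; users work on one mission at a time"
            )
    return MissionInstance(
        instance_id=instance_id or f"{user_id}:{spec.mission_id}:{start_date}",
        mission_id=spec.mission_id,
        user_id=user_id,
        state="active",
        started_on=start_date,
    )


def switch_mission(
    instance: MissionInstance,
    new_spec: MissionSpec,
    switch_date: _dt.date,
) -> tuple[MissionInstance, MissionInstance]:
    """Abandon the current mission and activate another.

    Returns ``(old_abandoned, new_active)``; callers emit a
    ``mission_switched`` event.
    """
    if instance.state not in ("active", "stuck"):
        raise StateError(
            f"cannot switch from mission in state {instance.state!r}"
        )
    old = instance._transition("abandoned")
    new = start_mission(new_spec, instance.user_id, switch_date, existing=[old])
    return old, new


def log_compliance(
    instance: MissionInstance, date: _dt.date
) -> MissionInstance:
    """Record one compliance button press."""
    if instance.state != "active":
        raise StateError(
            f"cannot log compliance on mission in state {instance.state!r}"
        )
    return replace(
        instance,
        compliance_log=instance.compliance_log + (date,),
        progress=instance.progress + 1,
    )


def evaluate_progress(
    instance: MissionInstance,
    spec: MissionSpec,
    today: _dt.date,
    *,
    stuck_after_days: int = 3,
) -> str:
    """Daily checkpoint: ``completed``, ``stuck``, ``expired`` or ``ongoing``.

    Completed once the target count is reached; expired once the time limit
    has passed without completion; stuck after ``stuck_after_days`` days with
    no compliance activity (counted from the last button press, or from the
    start date if there is none).
    """
    if instance.state != "active":
        raise StateError(
            f"cannot evaluate mission in state {instance.state!r}"
        )
    if instance.progress >= spec.target_count:
        return "completed"
    assert instance.started_on is not None
    if (today - instance.started_on).days > spec.time_limit_days:
        return "expired"
    last_activity = max(
        [instance.started_on, *instance.compliance_log]
    )
    if (today - last_activity).days >= stuck_after_days:
        return "stuck"
    return "ongoing"


def apply_evaluation(instance: MissionInstance, outcome: str) -> MissionInstance:
    """Apply an :func:`evaluate_progress` outcome to the state machine.

    Expired missions are treated as stuck (coping planning re-proposes
    alternatives) rather than failed.
    """
    if outcome == "completed":
        return instance._transition("completed")
    if outcome in ("stuck", "expired"):
        return instance._transition("stuck")
    return instance


def on_completion(
    instance: MissionInstance,
    profile: UserProfile,
    catalogue: MissionCatalogue,
    guidelines: list[GuidelineEntry],
) -> tuple[UserProfile, ScoreBoard, list[MissionSpec], str]:
    """Level-up handling after a mission is completed.

    The mission joins the completion history, the profile is re-scored, and
    the next proposal is the same food group one level up — or, when the
    expert level was just completed, the top of a fresh ranking over the
    remaining groups.  Returns ``(profile', board', proposals,
    congratulation)``.
    """
    if instance.state != "completed":
        raise StateError("on_completion requires a completed mission instance")
    spec = catalogue.by_id(instance.mission_id)
    new_profile = profile.with_completed(instance.mission_id)
    board = score_profile(new_profile, guidelines)
    congratulation = (
        f"Congratulations! You completed '{spec.title}' and levelled up in "
        f"{spec.food_group_id.replace('_', ' ')}."
    )
    if spec.level < 3:
        proposals = [catalogue.get(spec.food_group_id, spec.level + 1)]
    else:
        ranked = [
            c
            for c in rank_candidates(board, new_profile, catalogue, guidelines)
            if c.food_group_id != spec.food_group_id
        ]
        proposals = propose_missions(ranked, catalogue)
    return new_profile, board, proposals, congratulation
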