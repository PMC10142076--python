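"""Engine orchestration: the behaviour-change loop wired through the rules.

This module binds the declarative rule base to the procedural components
(scoring, mission selection, scheduling) and drives the weekly loop:

1. a questionnaire arrives -> the profile is rebuilt and scored, and the
   top-3 ranked missions are proposed (intention formation: one mission at
   a time);
2. the user starts a mission -> a *Did you know...?* tip plus the
   recommendation calendar are scheduled (planning / self-efficacy);
3. button presses log compliance; reaching the target completes the
   mission, levels the user up with a congratulation, and proposes the next
   step (feedback);
4. daily ticks deliver due notifications and detect stuck or expired
   missions, answering with coping alternatives (coping planning);
5. the monthly short FFQ re-enters at step 1 and re-anchors missions and
   levels on measured behaviour (action control).

The same selection logic is available both through the rule engine
(:meth:`NutritionEngine.dispatch_event`) and as a direct procedural
pipeline (:func:`select_missions`); the two are equivalent by construction
and that equivalence is part of the test suite.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .errors import StateError, ValidationError
from .ffq import (
    DietaryPreferences,
    FFQSchema,
    FrequencyReport,
    UserProfile,
    apply_short_ffq,
    build_profile,
    load_ffq_schemas,
)
from .missions import (
    MissionCatalogue,
    MissionInstance,
    MissionSpec,
    apply_evaluation,
    evaluate_progress,
    load_catalogue,
    log_compliance,
    on_completion,
    propose_missions,
    rank_candidates,
    start_mission,
    switch_mission,
)
from .recommender import (
    Repository,
    ScheduledNotification,
    SchedulerConfig,
    build_default_repository,
    build_schedule,
    coping_notice,
)
from .rules import EngineEvent, Rule, WorkingMemory, dispatch, load_rules
from .scoring import GuidelineEntry, ScoreBoard, load_guidelines, score_profile

__all__ = [
    "DEFAULT_STUCK_AFTER_DAYS",
    "EngineBundle",
    "load_default_bundle",
    "select_missions",
    "NutritionEngine",
]

DEFAULT_STUCK_AFTER_DAYS = 3


def _read_data_yaml(name: str) -> dict:
    with resources.files("nutrimission.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class EngineBundle:
    """All validated configuration the engine needs."""

    guidelines: list[GuidelineEntry]
    catalogue: MissionCatalogue
    repository: Repository
    schemas: dict[str, FFQSchema]
    rules: list[Rule]
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    stuck_after_days: int = DEFAULT_STUCK_AFTER_DAYS


def load_default_bundle() -> EngineBundle:
    """Load the shipped guideline tables, catalogue, FFQ schemas and rule
    base, and generate the default motivational repository."""
    guidelines = load_guidelines(_read_data_yaml("guidelines.yaml"))
    catalogue = load_catalogue(_read_data_yaml("catalogue.yaml"))
    schemas = load_ffq_schemas(_read_data_yaml("ffq_schema.yaml"))
    rules = load_rules(_read_data_yaml("rules.yaml"))
    repository = build_default_repository(
        catalogue.specs, catalogue.food_groups
    )
    return EngineBundle(
        guidelines=guidelines,
        catalogue=catalogue,
        repository=repository,
        schemas=schemas,
        rules=rules,
    )


def select_missions(
    profile: UserProfile,
    guidelines: list[GuidelineEntry],
    catalogue: MissionCatalogue,
) -> tuple[ScoreBoard, list[MissionSpec]]:
    """Direct procedural pipeline: score -> rank -> top-3 proposal."""
    board = score_profile(profile, guidelines)
    ranked = rank_candidates(board, profile, catalogue, guidelines)
    return board, propose_missions(ranked, catalogue)


class NutritionEngine:
    """Stateful engine for one user, driven by events through the rule base.

    All state mutation happens inside registered rule handlers, so the
    declarative rule base remains the single place deciding *when* each
    action runs.
    """

    def __init__(
        self,
        bundle: EngineBundle | None = None,
        *,
        user_id: str = "user",
        seed: int = 0,
    ):
        self.bundle = bundle or load_default_bundle()
        self.user_id = user_id
        self.seed = seed
        self.wm = WorkingMemory()
        self.profile: UserProfile | None = None
        self.board: ScoreBoard | None = None
        self.proposals: list[MissionSpec] = []
        self.instances: list[MissionInstance] = []
        self.schedule: list[ScheduledNotification] = []
        self.notification_log: list[ScheduledNotification] = []
        self.event_log: list[EngineEvent] = []
        self.explain_log: list[dict] = []
        self._coping_sent_for: set[str] = set()
        self._handlers = {
            "compute_scores": self._h_compute_scores,
            "propose_missions": self._h_propose,
            "record_compliance": self._h_record_compliance,
            "handle_completion": self._h_handle_completion,
            "record_switch": self._h_record_switch,
            "daily_evaluation": self._h_daily_evaluation,
        }

    # -- public API --------------------------------------------------------

    @property
    def active_instance(self) -> MissionInstance | None:
        for inst in self.instances:
            if inst.state in ("active", "stuck"):
                return inst
        return None

    def dispatch_event(self, event: EngineEvent, *, explain: bool = False) -> list:
        self.event_log.append(event)
        self.wm, effects, log = dispatch(
            event,
            self.wm,
            self.bundle.rules,
            handlers=self._handlers,
            explain=explain,
        )
        if explain:
            self.explain_log.extend(log)
        return effects

    def submit_ffq(
        self,
        responses: list[FrequencyReport],
        prefs: DietaryPreferences,
        *,
        on: _dt.date,
        liked_groups: frozenset[str] | set[str] = frozenset(),
    ) -> list:
        """Full FFQ + dietary questionnaire: (re)build the profile."""
        history = (
            self.profile.completed_missions if self.profile else frozenset()
        )
        profile = build_profile(
            responses,
            self.bundle.schemas["full"],
            prefs,
            user_id=self.user_id,
            liked_groups=liked_groups,
            assessed_on=on,
        )
        self.profile = replace(profile, completed_missions=history)
        self.wm.assert_fact("profile", self.profile)
        return self.dispatch_event(
            EngineEvent(
                "questionnaire_completed",
                payload={"kind": "full", "date": on.isoformat()},
                occurred_at=on,
            )
        )

    def submit_short_ffq(
        self, responses: list[FrequencyReport], *, on: _dt.date
    ) -> list:
        """Monthly short FFQ: overwrite the covered food groups, re-score."""
        if self.profile is None:
            raise StateError("no profile yet; submit the full FFQ first")
        self.profile = apply_short_ffq(
            self.profile, responses, self.bundle.schemas["short"], assessed_on=on
        )
        self.wm.assert_fact("profile", self.profile)
        return self.dispatch_event(
            EngineEvent(
                "questionnaire_completed",
                payload={"kind": "short", "date": on.isoformat()},
                occurred_at=on,
            )
        )

    def start(self, mission_id: str, *, on: _dt.date) -> MissionInstance:
        """Goal setting: activate one proposed mission."""
        spec = self.bundle.catalogue.by_id(mission_id)
        inst = start_mission(spec, self.user_id, on, existing=self.instances)
        self.instances.append(inst)
        self._plan_schedule(inst, spec)
        self.wm.assert_fact("active_mission", mission_id)
        return inst

    def switch(self, new_mission_id: str, *, on: _dt.date) -> MissionInstance:
        inst = self.active_instance
        if inst is None:
            raise StateError("no active mission to switch from")
        new_spec = self.bundle.catalogue.by_id(new_mission_id)
        old, new = switch_mission(inst, new_spec, on)
        self._replace_instance(old)
        self.instances.append(new)
        self._coping_sent_for.discard(old.instance_id)
        self._plan_schedule(new, new_spec)
        self.wm.assert_fact("active_mission", new_mission_id)
        self.dispatch_event(
            EngineEvent(
                "mission_switched",
                payload={"from": old.mission_id, "to": new.mission_id,
                         "date": on.isoformat()},
                occurred_at=on,
            )
        )
        return new

    def press(self, *, on: _dt.date) -> list:
        """Compliance button press for the active mission."""
        return self.dispatch_event(
            EngineEvent(
                "compliance_logged",
                payload={"date": on.isoformat()},
                occurred_at=on,
            )
        )

    def tick(self, *, on: _dt.date) -> list:
        """Advance one day: deliver due notifications, run checkpoints."""
        return self.dispatch_event(
            EngineEvent(
                "day_advanced", payload={"date": on.isoformat()}, occurred_at=on
            )
        )

    # -- internals ---------------------------------------------------------

    def _replace_instance(self, updated: MissionInstance) -> None:
        self.instances = [
            updated if i.instance_id == updated.instance_id else i
            for i in self.instances
        ]

    def _plan_schedule(self, inst: MissionInstance, spec: MissionSpec) -> None:
        prefs = (
            self.profile.preferences if self.profile else DietaryPreferences()
        )
        horizon = max(spec.time_limit_days * 4, 28)
        self.schedule = build_schedule(
            inst,
            spec,
            prefs,
            self.bundle.repository,
            horizon,
            self.seed + len(self.instances),
            config=self.bundle.scheduler,
            start_date=inst.started_on,
        )

    # -- rule handlers -----------------------------------------------------

    def _h_compute_scores(self, wm: WorkingMemory, event: EngineEvent):
        profile = wm.get("profile")
        if profile is None:
            raise ValidationError("no profile fact in working memory")
        self.board = score_profile(profile, self.bundle.guidelines)
        assertions: dict = {"proposals_fresh": False}
        for g, (score, level) in self.board.entries.items():
            assertions[f"score.{g}"] = score.value
            assertions[f"level.{g}"] = level
        assertions["scoreboard_ready"] = True
        return assertions, [{"type": "scored", "groups": len(self.board.entries)}]

    def _h_propose(self, wm: WorkingMemory, event: EngineEvent):
        profile = wm.get("profile")
        assert self.board is not None
        ranked = rank_candidates(
            self.board, profile, self.bundle.catalogue, self.bundle.guidelines
        )
        self.proposals = propose_missions(ranked, self.bundle.catalogue)
        return (
            {"proposals_fresh": True,
             "proposals": [s.mission_id for s in self.proposals]},
            [{
                "type": "propose_missions",
                "mission_ids": [s.mission_id for s in self.proposals],
                "ranking": [
                    (c.food_group_id, c.level, c.score.value) for c in ranked
                ],
            }],
        )

    def _h_record_compliance(self, wm: WorkingMemory, event: EngineEvent):
        inst = self.active_instance
        if inst is None or inst.state != "active":
            raise StateError("compliance logged without an active mission")
        date = _dt.date.fromisoformat(event.payload["date"])
        inst = log_compliance(inst, date)
        self._replace_instance(inst)
        spec = self.bundle.catalogue.by_id(inst.mission_id)
        effects = [{
            "type": "progress",
            "mission_id": inst.mission_id,
            "progress": inst.progress,
            "target": spec.target_count,
        }]
        if evaluate_progress(
            inst, spec, date, stuck_after_days=self.bundle.stuck_after_days
        ) == "completed":
            inst = apply_evaluation(inst, "completed")
            self._replace_instance(inst)
            effects.extend(
                self.dispatch_event(
                    EngineEvent(
                        "mission_completed",
                        payload={"mission_id": inst.mission_id,
                                 "date": event.payload["date"]},
                        occurred_at=date,
                    )
                )
            )
        return {f"progress.{inst.mission_id}": inst.progress}, effects

    def _h_handle_completion(self, wm: WorkingMemory, event: EngineEvent):
        inst = next(
            (
                i for i in self.instances
                if i.mission_id == event.payload["mission_id"]
                and i.state == "completed"
            ),
            None,
        )
        if inst is None:
            raise StateError("mission_completed event without completed instance")
        assert self.profile is not None
        self.profile, self.board, next_specs, congrats = on_completion(
            inst, self.profile, self.bundle.catalogue, self.bundle.guidelines
        )
        self.proposals = next_specs
        date = _dt.date.fromisoformat(event.payload["date"])
        notice = ScheduledNotification(
            date=date, reason="congratulation", message=congrats
        )
        self.notification_log.append(notice)
        self.schedule = []
        self.wm.retract("active_mission")
        assertions: dict = {
            "profile": self.profile,
            "proposals": [s.mission_id for s in next_specs],
            f"completed.{inst.mission_id}": True,
        }
        for g, (score, level) in self.board.entries.items():
            assertions[f"score.{g}"] = score.value
            assertions[f"level.{g}"] = level
        return assertions, [
            {"type": "congratulation", "message": congrats},
            {"type": "propose_missions",
             "mission_ids": [s.mission_id for s in next_specs]},
        ]

    def _h_record_switch(self, wm: WorkingMemory, event: EngineEvent):
        return (
            {"last_switch": event.payload},
            [{"type": "mission_switched", **event.payload}],
        )

    def _h_daily_evaluation(self, wm: WorkingMemory, event: EngineEvent):
        date = _dt.date.fromisoformat(event.payload["date"])
        effects: list = []
        due = [n for n in self.schedule if n.date == date]
        for n in due:
            self.notification_log.append(n)
            effects.append({
                "type": "notification",
                "reason": n.reason,
                "rec_id": n.rec_id,
                "message": n.message,
            })
        inst = self.active_instance
        assertions: dict = {"today": event.payload["date"]}
        if inst is not None and inst.state == "active":
            spec = self.bundle.catalogue.by_id(inst.mission_id)
            outcome = evaluate_progress(
                inst, spec, date, stuck_after_days=self.bundle.stuck_after_days
            )
            if outcome == "completed":
                inst = apply_evaluation(inst, outcome)
                self._replace_instance(inst)
                effects.extend(
                    self.dispatch_event(
                        EngineEvent(
                            "mission_completed",
                            payload={"mission_id": inst.mission_id,
                                     "date": event.payload["date"]},
                            occurred_at=date,
                        )
                    )
                )
            elif outcome in ("stuck", "expired"):
                inst = apply_evaluation(inst, outcome)
                self._replace_instance(inst)
                if (
                    inst.instance_id not in self._coping_sent_for
                    and self.board is not None
                    and self.profile is not None
                ):
                    ranked = rank_candidates(
                        self.board, self.profile, self.bundle.catalogue,
                        self.bundle.guidelines,
                    )
                    alternatives = [
                        s
                        for s in propose_missions(ranked, self.bundle.catalogue)
                        if s.mission_id != inst.mission_id
                    ]
                    if alternatives:
                        notice = coping_notice(inst, alternatives, date)
                        self.notification_log.append(notice)
                        self._coping_sent_for.add(inst.instance_id)
                        effects.append({
                            "type": "coping",
                            "alternatives": list(notice.alternatives),
                            "message": notice.message,
                        })
        return assertions, effects
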