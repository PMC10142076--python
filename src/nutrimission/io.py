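"""Configuration loading, session persistence, and tabular exports.

The engine is file-driven: guideline tables, the mission catalogue, the
motivational repository, the FFQ schemas and the rule base are YAML/JSON
documents; session state (profile, mission instances, notification history)
persists between CLI invocations as a single JSON document per user.  Dates
are ISO-8601 throughout.  ``save -> load -> save`` is byte-identical.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .engine import EngineBundle, NutritionEngine, load_default_bundle
from .ffq import UserProfile, load_ffq_schemas
from .missions import MissionInstance, load_catalogue
from .recommender import (
    ScheduledNotification,
    SchedulerConfig,
    build_default_repository,
    load_repository,
)
from .rules import load_rules
from .scoring import load_guidelines
from .simulator import SimulationTrace

__all__ = [
    "EngineConfig",
    "load_bundle_from_config",
    "save_state",
    "load_state",
    "compliance_log_to_csv",
    "trace_to_csv",
]


@dataclass(frozen=True)
class EngineConfig:
    """Paths to the configuration documents plus engine constants.

    Any path left as ``None`` falls back to the shipped default document.
    """

    guidelines_path: Path | None = None
    catalogue_path: Path | None = None
    repository_path: Path | None = None
    ffq_schema_path: Path | None = None
    rules_path: Path | None = None
    stuck_after_days: int = 3
    seed: int = 0

    @classmethod
    def from_file(cls, path: Path) -> "EngineConfig":
        doc = _load_doc(path)
        base = path.parent

        def p(key: str) -> Path | None:
            return (base / doc[key]) if key in doc and doc[key] else None

        return cls(
            guidelines_path=p("guidelines"),
            catalogue_path=p("catalogue"),
            repository_path=p("repository"),
            ffq_schema_path=p("ffq_schema"),
            rules_path=p("rules"),
            stuck_after_days=int(doc.get("stuck_after_days", 3)),
            seed=int(doc.get("seed", 0)),
        )


def _load_doc(path: Path):
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def load_bundle_from_config(config: EngineConfig) -> EngineBundle:
    """Build an :class:`EngineBundle`, mixing configured documents with the
    shipped defaults for any path left unset."""
    default = load_default_bundle()
    guidelines = (
        load_guidelines(_load_doc(config.guidelines_path))
        if config.guidelines_path
        else default.guidelines
    )
    catalogue = (
        load_catalogue(_load_doc(config.catalogue_path))
        if config.catalogue_path
        else default.catalogue
    )
    schemas = (
        load_ffq_schemas(_load_doc(config.ffq_schema_path))
        if config.ffq_schema_path
        else default.schemas
    )
    rules = (
        load_rules(_load_doc(config.rules_path))
        if config.rules_path
        else default.rules
    )
    if config.repository_path:
        repository = load_repository(
            _load_doc(config.repository_path),
            mission_ids={s.mission_id for s in catalogue.specs},
            food_groups=set(catalogue.food_groups),
        )
    else:
        repository = build_default_repository(
            catalogue.specs, catalogue.food_groups
        )
    return EngineBundle(
        guidelines=guidelines,
        catalogue=catalogue,
        repository=repository,
        schemas=schemas,
        rules=rules,
        scheduler=SchedulerConfig(),
        stuck_after_days=config.stuck_after_days,
    )


# ---------------------------------------------------------------------------
# Session state


def _notification_to_dict(n: ScheduledNotification) -> dict:
    return {
        "date": n.date.isoformat(),
        "reason": n.reason,
        "rec_id": n.rec_id,
        "message": n.message,
        "alternatives": list(n.alternatives),
    }


def _notification_from_dict(d: dict) -> ScheduledNotification:
    return ScheduledNotification(
        date=_dt.date.fromisoformat(d["date"]),
        reason=d["reason"],
        rec_id=d.get("rec_id"),
        message=d.get("message", ""),
        alternatives=tuple(d.get("alternatives", ())),
    )


def _instance_to_dict(i: MissionInstance) -> dict:
    return {
        "instance_id": i.instance_id,
        "mission_id": i.mission_id,
        "user_id": i.user_id,
        "state": i.state,
        "started_on": i.started_on.isoformat() if i.started_on else None,
        "compliance_log": [d.isoformat() for d in i.compliance_log],
        "progress": i.progress,
    }


def _instance_from_dict(d: dict) -> MissionInstance:
    return MissionInstance(
        instance_id=d["instance_id"],
        mission_id=d["mission_id"],
        user_id=d["user_id"],
        state=d["state"],
        started_on=(
            _dt.date.fromisoformat(d["started_on"]) if d["started_on"] else None
        ),
        compliance_log=tuple(
            _dt.date.fromisoformat(x) for x in d["compliance_log"]
        ),
        progress=int(d["progress"]),
    )


def save_state(engine: NutritionEngine, path: Path) -> None:
    """Persist the session (profile, missions, notifications) as JSON."""
    doc = {
        "user_id": engine.user_id,
        "seed": engine.seed,
        "profile": engine.profile.to_json_dict() if engine.profile else None,
        "proposals": [s.mission_id for s in engine.proposals],
        "instances": [_instance_to_dict(i) for i in engine.instances],
        "schedule": [_notification_to_dict(n) for n in engine.schedule],
        "notification_log": [
            _notification_to_dict(n) for n in engine.notification_log
        ],
        "coping_sent_for": sorted(engine._coping_sent_for),
        "events": [
            {"event_type": e.event_type, "payload": e.payload}
            for e in engine.event_log
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2) + "\n")


def load_state(
    path: Path, bundle: EngineBundle | None = None
) -> NutritionEngine:
    """Rebuild an engine from a saved session.

    The working memory and scoreboard are reconstructed deterministically
    from the persisted profile, so ``load(save(state))`` behaves
    identically to the original engine.
    """
    doc = json.loads(Path(path).read_text())
    engine = NutritionEngine(
        bundle or load_default_bundle(),
        user_id=doc["user_id"],
        seed=int(doc.get("seed", 0)),
    )
    if doc.get("profile"):
        engine.profile = UserProfile.from_json_dict(doc["profile"])
        engine.wm.assert_fact("profile", engine.profile)
        from .scoring import score_profile

        engine.board = score_profile(engine.profile, engine.bundle.guidelines)
    engine.proposals = [
        engine.bundle.catalogue.by_id(m) for m in doc.get("proposals", ())
    ]
    engine.instances = [
        _instance_from_dict(d) for d in doc.get("instances", ())
    ]
    engine.schedule = [
        _notification_from_dict(d) for d in doc.get("schedule", ())
    ]
    engine.notification_log = [
        _notification_from_dict(d) for d in doc.get("notification_log", ())
    ]
    engine._coping_sent_for = set(doc.get("coping_sent_for", ()))
    from .rules import EngineEvent

    engine.event_log = [
        EngineEvent(event_type=e["event_type"], payload=e["payload"])
        for e in doc.get("events", ())
    ]
    active = engine.active_instance
    if active is not None:
        engine.wm.assert_fact("active_mission", active.mission_id)
    return engine


# ---------------------------------------------------------------------------
# Tabular exports


def compliance_log_to_csv(
    instances: list[MissionInstance], path: Path
) -> None:
    """Export all compliance presses as CSV (date, mission_id, increment)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "mission_id", "increment"])
        rows = [
            (d.isoformat(), inst.mission_id, 1)
            for inst in instances
            for d in inst.compliance_log
        ]
        writer.writerows(sorted(rows))


def trace_to_csv(trace: SimulationTrace, path: Path) -> None:
    """Flatten a simulation trace to CSV (one row per day)."""
    if not trace.records:
        Path(path).write_text("")
        return
    groups = sorted(trace.records[0]["latent_weekly"])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["user_id", "day", "date", "mission_id", "mission_state",
             "progress", "notifications"] + [f"latent_{g}" for g in groups]
        )
        for r in trace.records:
            writer.writerow(
                [trace.user_id, r["day"], r["date"], r["mission_id"],
                 r["mission_state"], r["progress"], r["notifications"]]
                + [round(r["latent_weekly"][g], 4) for g in groups]
            )
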