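"""Generic forward-chaining rule-based reasoning (RBR) engine.

Classic three-part architecture: a *working memory* (WM) of facts about the
user, a declarative *rule base* (RB) holding the expert knowledge, and an
*inference engine* (IE) that matches rules against facts when an event
arrives and fires them to quiescence.

Design constraints (kept deliberately narrow so the rule base stays
auditable):

* conditions are conjunctions of simple comparisons
  (``= != < <= > >= in exists absent``) on fact keys — no pattern
  unification;
* a rule *activation* is the pair (rule, exact matched-fact timestamps);
  each activation fires at most once per dispatch, so rules re-fire only
  when the facts they matched have changed;
* conflict resolution: higher salience first, then the activation whose
  matched facts are most recent, then rule definition order;
* a cycle guard (default 1000 firings per dispatch) turns runaway rule
  interactions into a diagnosable error instead of a hang.

Rule actions either manipulate facts directly (``assert``/``retract``),
emit effects for the host application (``emit``), or invoke a registered
procedural handler (``call``) — the hook through which scoring and mission
selection are exposed to the declarative layer.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Any, Callable

from .errors import ConfigurationError, EngineError

__all__ = [
    "EVENT_TYPES",
    "Fact",
    "Condition",
    "Rule",
    "EngineEvent",
    "WorkingMemory",
    "assert_fact",
    "retract_fact",
    "dispatch",
    "load_rules",
]

EVENT_TYPES = (
    "questionnaire_completed",
    "mission_completed",
    "mission_switched",
    "compliance_logged",
    "day_advanced",
)

_OPS: dict[str, Callable[[Any, Any], bool]] = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
}


@dataclass(frozen=True)
class Fact:
    """One WM entry: a dotted key path, a value, and an assertion counter.

    ``asserted_at`` is a monotonically increasing logical timestamp managed
    by the working memory; re-asserting a key replaces the fact.
    """

    key: str
    value: Any
    asserted_at: int = 0


@dataclass(frozen=True)
class Condition:
    """``key <op> value`` over the working memory (or the event payload
    via ``event.<field>`` keys).  ``exists``/``absent`` take no value."""

    key: str
    op: str
    value: Any = None

    def __post_init__(self):
        if self.op not in _OPS and self.op not in ("exists", "absent"):
            raise ConfigurationError(f"unknown condition operator {self.op!r}")


@dataclass(frozen=True)
class Rule:
    rule_id: str
    salience: int = 0
    on: str | None = None  # event_type filter; None matches any event
    conditions: tuple[Condition, ...] = ()
    actions: tuple[dict, ...] = ()

    def __post_init__(self):
        if self.on is not None and self.on not in EVENT_TYPES:
            raise ConfigurationError(
                f"rule {self.rule_id!r}: unknown event type {self.on!r}"
            )
        for a in self.actions:
            if len(a) != 1 or next(iter(a)) not in (
                "assert", "retract", "emit", "call"
            ):
                raise ConfigurationError(
                    f"rule {self.rule_id!r}: malformed action {a!r}"
                )


@dataclass(frozen=True)
class EngineEvent:
    event_type: str
    payload: dict = field(default_factory=dict)
    occurred_at: _dt.datetime | _dt.date | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ConfigurationError(f"unknown event type {self.event_type!r}")


class WorkingMemory:
    """Keyed fact store; re-assertion replaces and bumps the timestamp."""

    def __init__(self, facts: dict[str, Any] | None = None):
        self._facts: dict[str, Fact] = {}
        self._clock = 0
        for k, v in (facts or {}).items():
            self.assert_fact(k, v)

    def assert_fact(self, key: str, value: Any) -> Fact:
        self._clock += 1
        fact = Fact(key=key, value=value, asserted_at=self._clock)
        self._facts[key] = fact
        return fact

    def retract(self, key: str) -> None:
        self._facts.pop(key, None)

    def get(self, key: str, default: Any = None) -> Any:
        f = self._facts.get(key)
        return default if f is None else f.value

    def fact(self, key: str) -> Fact | None:
        return self._facts.get(key)

    def __contains__(self, key: str) -> bool:
        return key in self._facts

    def __len__(self) -> int:
        return len(self._facts)

    def as_dict(self) -> dict[str, Any]:
        return {k: f.value for k, f in self._facts.items()}

    def snapshot(self) -> dict[str, Fact]:
        return dict(self._facts)


def assert_fact(wm: WorkingMemory, fact: Fact) -> WorkingMemory:
    """Functional-style assertion (mutates and returns ``wm``)."""
    wm.assert_fact(fact.key, fact.value)
    return wm


def retract_fact(wm: WorkingMemory, key: str) -> WorkingMemory:
    wm.retract(key)
    return wm


# ---------------------------------------------------------------------------
# Matching and firing

#: A procedural handler: (wm, event) -> (facts to assert, effects to emit).
ActionHandler = Callable[[WorkingMemory, EngineEvent], tuple[dict, list]]


def _resolve(key: str, wm: WorkingMemory, event: EngineEvent):
    """Look up a condition key in the WM, or the event payload for
    ``event.<field>`` keys.  Returns (found, value)."""
    if key.startswith("event."):
        name = key[len("event."):]
        return name in event.payload, event.payload.get(name)
    return key in wm, wm.get(key)


def _matches(
    rule: Rule, wm: WorkingMemory, event: EngineEvent
) -> tuple[bool, tuple[tuple[str, int], ...]]:
    """Does the rule match?  Also returns the matched-fact fingerprint
    (key, asserted_at) used for activation identity and recency."""
    if rule.on is not None and rule.on != event.event_type:
        return False, ()
    matched: list[tuple[str, int]] = []
    for cond in rule.conditions:
        found, value = _resolve(cond.key, wm, event)
        if cond.op == "exists":
            if not found:
                return False, ()
        elif cond.op == "absent":
            if found:
                return False, ()
            continue
        else:
            if not found:
                return False, ()
            try:
                if not _OPS[cond.op](value, cond.value):
                    return False, ()
            except TypeError:
                return False, ()
        if not cond.key.startswith("event."):
            f = wm.fact(cond.key)
            if f is not None:
                matched.append((cond.key, f.asserted_at))
    return True, tuple(sorted(matched))


def _recency(fingerprint: tuple[tuple[str, int], ...]) -> int:
    return max((t for _, t in fingerprint), default=0)


def dispatch(
    event: EngineEvent,
    wm: WorkingMemory,
    rules: list[Rule],
    *,
    handlers: dict[str, ActionHandler] | None = None,
    max_firings: int = 1000,
    explain: bool = False,
) -> tuple[WorkingMemory, list, list[dict]]:
    """Fire all matching rules for an event until quiescence.

    Returns ``(wm, effects, firing_log)``; the firing log is populated when
    ``explain`` is true (rule_id, matched facts, effects per firing) for
    auditability.
    """
    handlers = handlers or {}
    effects: list = []
    log: list[dict] = []
    fired: set[tuple[str, tuple[tuple[str, int], ...]]] = set()
    sequence: list[str] = []
    order = {r.rule_id: i for i, r in enumerate(rules)}

    firings = 0
    while True:
        candidates = []
        for r in rules:
            ok, fingerprint = _matches(r, wm, event)
            if ok and (r.rule_id, fingerprint) not in fired:
                candidates.append((r, fingerprint))
        if not candidates:
            break
        candidates.sort(
            key=lambda cf: (
                -cf[0].salience,
                -_recency(cf[1]),
                order[cf[0].rule_id],
            )
        )
        rule, fingerprint = candidates[0]
        fired.add((rule.rule_id, fingerprint))
        sequence.append(rule.rule_id)
        firings += 1
        if firings > max_firings:
            raise EngineError(
                f"cycle guard: more than {max_firings} firings in one "
                f"dispatch; sequence tail: {sequence[-20:]}"
            )
        new_effects: list = []
        for action in rule.actions:
            kind, spec = next(iter(action.items()))
            if kind == "assert":
                value = spec.get("value")
                if "from_event" in spec:
                    value = event.payload.get(spec["from_event"])
                wm.assert_fact(spec["key"], value)
            elif kind == "retract":
                wm.retract(spec["key"])
            elif kind == "emit":
                new_effects.append(dict(spec))
            elif kind == "call":
                name = spec if isinstance(spec, str) else spec["handler"]
                if name not in handlers:
                    raise ConfigurationError(
                        f"rule {rule.rule_id!r} calls unregistered handler "
                        f"{name!r}"
                    )
                assertions, handler_effects = handlers[name](wm, event)
                for k, v in assertions.items():
                    wm.assert_fact(k, v)
                new_effects.extend(handler_effects)
        effects.extend(new_effects)
        if explain:
            log.append(
                {
                    "rule_id": rule.rule_id,
                    "matched": list(fingerprint),
                    "effects": new_effects,
                }
            )
    return wm, effects, log


# ---------------------------------------------------------------------------
# Rule-base loading


def load_rules(doc: dict) -> list[Rule]:
    """Parse a declarative rule-base document (parsed YAML/JSON)."""
    rules: list[Rule] = []
    seen: set[str] = set()
    for r in doc["rules"]:
        rid = r["rule_id"]
        if rid in seen:
            raise ConfigurationError(f"duplicate rule_id {rid!r}")
        seen.add(rid)
        conditions = tuple(
            Condition(key=c["key"], op=c["op"], value=c.get("value"))
            for c in r.get("conditions", ())
        )
        actions = tuple(r.get("actions", ()))
        # YAML 1.1 parses a bare `on` key as boolean True; accept both
        on = r.get("on", r.get(True))
        rules.append(
            Rule(
                rule_id=rid,
                salience=int(r.get("salience", 0)),
                on=on,
                conditions=conditions,
                actions=actions,
            )
        )
    return rules
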