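"""Food-frequency questionnaire (FFQ) modelling and behavioural user profiles.

The dietary assessment instrument is a 20-item FFQ in which each item names a
food or food group, lists representative foods, and defines a portion in
household measures.  Users report an average eating frequency per item as a
count over a recall period (per day, per week, or per month).  A short monthly
variant of the same questionnaire, covering one representative item per food
group, is used to re-assess progression without repeating the full instrument.

All frequencies are normalised to servings/week and aggregated per food group
into a :class:`UserProfile` — the behavioural status snapshot that every
downstream component (scoring, mission selection, recommendation tailoring)
consumes.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PERIODS",
    "VEGETARIAN_TYPES",
    "FFQItem",
    "FFQSchema",
    "FrequencyReport",
    "DietaryPreferences",
    "UserProfile",
    "normalize_frequency",
    "build_profile",
    "apply_short_ffq",
    "load_ffq_schemas",
]

#: Recognised reporting periods and their servings/week conversion factors.
#: A month is taken as the calendar-exact average of 52/12 weeks.
PERIODS: dict[str, float] = {
    "day": 7.0,
    "week": 1.0,
    "month": 12.0 / 52.0,
}

VEGETARIAN_TYPES = ("none", "vegan", "ovo_vegetarian", "lacto_ovo_vegetarian")


@dataclass(frozen=True)
class FFQItem:
    """One questionnaire item: a food (group) with portion guidance."""

    item_id: str
    food_group_id: str
    label: str
    representative_foods: tuple[str, ...] = ()
    portion_description: str = ""


@dataclass(frozen=True)
class FFQSchema:
    """An ordered questionnaire definition.

    ``version`` is ``"full"`` (the 20-item instrument) or ``"short"`` (the
    monthly progression check whose items are a subset of the full schema).
    """

    schema_id: str
    version: str
    items: tuple[FFQItem, ...]

    def __post_init__(self):
        if self.version not in ("full", "short"):
            raise ConfigurationError(
                f"schema {self.schema_id!r}: version must be 'full' or 'short', "
                f"got {self.version!r}"
            )
        ids = [it.item_id for it in self.items]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ConfigurationError(
                f"schema {self.schema_id!r}: duplicate item_ids {dupes}"
            )
        if self.version == "full" and len(self.items) != 20:
            raise ConfigurationError(
                f"full FFQ schema must have exactly 20 items, got {len(self.items)}"
            )
        if not self.items:
            raise ConfigurationError(f"schema {self.schema_id!r} has no items")

    @property
    def item_ids(self) -> frozenset[str]:
        return frozenset(it.item_id for it in self.items)

    @property
    def food_groups(self) -> frozenset[str]:
        return frozenset(it.food_group_id for it in self.items)

    def items_for_group(self, food_group_id: str) -> tuple[FFQItem, ...]:
        return tuple(it for it in self.items if it.food_group_id == food_group_id)


@dataclass(frozen=True)
class FrequencyReport:
    """A single item response: ``count`` consumptions per ``period``."""

    item_id: str
    count: float
    period: str

    def __post_init__(self):
        if self.period not in PERIODS:
            raise ConfigurationError(
                f"unknown period {self.period!r}; expected one of {sorted(PERIODS)}"
            )
        if self.count < 0:
            raise ValidationError(
                f"frequency count must be >= 0, got {self.count} for {self.item_id!r}"
            )


@dataclass(frozen=True)
class DietaryPreferences:
    """Dietary-habits questionnaire outcome: coeliac flag + vegetarian type."""

    coeliac: bool = False
    vegetarian_type: str = "none"

    def __post_init__(self):
        if self.vegetarian_type not in VEGETARIAN_TYPES:
            raise ValidationError(
                f"vegetarian_type must be one of {VEGETARIAN_TYPES}, "
                f"got {self.vegetarian_type!r}"
            )


@dataclass(frozen=True)
class UserProfile:
    """Behavioural status snapshot of one user.

    ``weekly_servings`` maps every configured food group to its current
    servings/week estimate; ``liked_groups`` holds optional food preferences
    marked on the questionnaires and only influences ranking tie-breaks;
    ``completed_missions`` is the gamification history used for level
    promotion.
    """

    user_id: str
    weekly_servings: dict[str, float]
    preferences: DietaryPreferences = field(default_factory=DietaryPreferences)
    liked_groups: frozenset[str] = frozenset()
    completed_missions: frozenset[str] = frozenset()
    last_assessed: _dt.date | None = None

    def __post_init__(self):
        bad = {g: v for g, v in self.weekly_servings.items() if v < 0}
        if bad:
            raise ValidationError(f"negative weekly servings: {bad}")

    def with_completed(self, mission_id: str) -> "UserProfile":
        return replace(
            self, completed_missions=self.completed_missions | {mission_id}
        )

    def to_json_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "weekly_servings": dict(sorted(self.weekly_servings.items())),
            "preferences": {
                "coeliac": self.preferences.coeliac,
                "vegetarian_type": self.preferences.vegetarian_type,
            },
            "liked_groups": sorted(self.liked_groups),
            "completed_missions": sorted(self.completed_missions),
            "last_assessed": (
                self.last_assessed.isoformat() if self.last_assessed else None
            ),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "UserProfile":
        return cls(
            user_id=d["user_id"],
            weekly_servings={k: float(v) for k, v in d["weekly_servings"].items()},
            preferences=DietaryPreferences(
                coeliac=bool(d["preferences"]["coeliac"]),
                vegetarian_type=d["preferences"]["vegetarian_type"],
            ),
            liked_groups=frozenset(d.get("liked_groups", ())),
            completed_missions=frozenset(d.get("completed_missions", ())),
            last_assessed=(
                _dt.date.fromisoformat(d["last_assessed"])
                if d.get("last_assessed")
                else None
            ),
        )


def normalize_frequency(count: float, period: str) -> float:
    """Convert a reported frequency to servings/week.

    day -> count*7; week -> count; month -> count*12/52.
    """
    if period not in PERIODS:
        raise ConfigurationError(
            f"unknown period {period!r}; expected one of {sorted(PERIODS)}"
        )
    if count < 0:
        raise ValidationError(f"count must be >= 0, got {count}")
    return count * PERIODS[period]


def _check_coverage(
    responses: list[FrequencyReport], schema: FFQSchema
) -> None:
    """Every schema item answered exactly once, nothing outside the schema."""
    reported = [r.item_id for r in responses]
    missing = sorted(schema.item_ids - set(reported))
    extra = sorted(set(reported) - schema.item_ids)
    dupes = sorted({i for i in reported if reported.count(i) > 1})
    problems = []
    if missing:
        problems.append(f"missing items: {missing}")
    if extra:
        problems.append(f"items outside schema: {extra}")
    if dupes:
        problems.append(f"duplicated items: {dupes}")
    if problems:
        raise ValidationError(
            f"response does not cover schema {schema.schema_id!r} exactly once: "
            + "; ".join(problems),
            details=missing + extra + dupes,
        )


def _aggregate(responses: list[FrequencyReport], schema: FFQSchema) -> dict[str, float]:
    by_item = {r.item_id: r for r in responses}
    out: dict[str, float] = {}
    for group in schema.food_groups:
        out[group] = sum(
            normalize_frequency(by_item[it.item_id].count, by_item[it.item_id].period)
            for it in schema.items_for_group(group)
        )
    return out


def build_profile(
    responses: list[FrequencyReport],
    schema: FFQSchema,
    prefs: DietaryPreferences,
    *,
    user_id: str = "user",
    liked_groups: frozenset[str] | set[str] = frozenset(),
    assessed_on: _dt.date | None = None,
) -> UserProfile:
    """Build the behavioural profile from a complete full-FFQ response.

    Per food group, weekly servings are the sum of the normalised frequencies
    of that group's items.  The response must cover every item of the full
    schema exactly once.
    """
    if schema.version != "full":
        raise ValidationError("build_profile requires the full FFQ schema")
    _check_coverage(responses, schema)
    return UserProfile(
        user_id=user_id,
        weekly_servings=_aggregate(responses, schema),
        preferences=prefs,
        liked_groups=frozenset(liked_groups),
        last_assessed=assessed_on or _dt.date.today(),
    )


def apply_short_ffq(
    profile: UserProfile,
    responses: list[FrequencyReport],
    short_schema: FFQSchema,
    *,
    assessed_on: _dt.date | None = None,
) -> UserProfile:
    """Overwrite only the food groups covered by the short monthly FFQ.

    Groups outside the short schema, the preference flags, and the mission
    history are all preserved; ``last_assessed`` is advanced.
    """
    if short_schema.version != "short":
        raise ValidationError("apply_short_ffq requires a short FFQ schema")
    _check_coverage(responses, short_schema)
    updated = dict(profile.weekly_servings)
    updated.update(_aggregate(responses, short_schema))
    return replace(
        profile,
        weekly_servings=updated,
        last_assessed=assessed_on or _dt.date.today(),
    )


# ---------------------------------------------------------------------------
# Schema loading


def _parse_schema(doc: dict) -> FFQSchema:
    try:
        items = tuple(
            FFQItem(
                item_id=it["item_id"],
                food_group_id=it["food_group_id"],
                label=it.get("label", it["item_id"]),
                representative_foods=tuple(it.get("representative_foods", ())),
                portion_description=it.get("portion_description", ""),
            )
            for it in doc["items"]
        )
        return FFQSchema(
            schema_id=doc["schema_id"], version=doc["version"], items=items
        )
    except KeyError as exc:
        raise ConfigurationError(f"FFQ schema document missing key {exc}") from exc


def load_ffq_schemas(doc: dict) -> dict[str, FFQSchema]:
    """Load the full and short schemas from one parsed YAML/JSON document.

    The short schema's items must be a subset of the full schema's.
    """
    schemas = {name: _parse_schema(sub) for name, sub in doc["schemas"].items()}
    full = next((s for s in schemas.values() if s.version == "full"), None)
    if full is None:
        raise ConfigurationError("schema document defines no full FFQ")
    for s in schemas.values():
        if s.version == "short" and not s.item_ids <= full.item_ids:
            raise ConfigurationError(
                f"short schema {s.schema_id!r} has items outside the full schema: "
                f"{sorted(s.item_ids - full.item_ids)}"
            )
    return schemas


def responses_from_json(doc: list[dict]) -> list[FrequencyReport]:
    """Parse a JSON list of ``{item_id, count, period}`` records."""
    return [
        FrequencyReport(
            item_id=r["item_id"], count=float(r["count"]), period=r["period"]
        )
        for r in doc
    ]


def profile_to_json(profile: UserProfile) -> str:
    return json.dumps(profile.to_json_dict(), indent=2, sort_keys=False)
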