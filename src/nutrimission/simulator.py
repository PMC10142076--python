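"""Synthetic-user cohort generation and engine-in-the-loop simulation.

Real deployments collect questionnaires and button presses from people; for
testing the whole behaviour-change loop end to end we emulate that
population.  Each :class:`SimulatedUser` carries a latent "true" diet (a
weekly-servings vector drawn per food group from a log-normal around
configurable medians), a daily compliance probability, a responsiveness
rate, and a reporting-noise level for questionnaire answers.

The latent-behaviour model is deliberately minimal: in any week with at
least one compliance event toward the active mission, the latent servings
of that mission's food group move a fraction ``responsiveness`` of the way
toward the guideline target (the recommended interval's midpoint, or its
nearest bound when unbounded).  Non-targeted groups never change, so the
monthly short FFQ genuinely measures whether the intervention moved
behaviour.

Everything is driven by explicit seeds; a trace is fully reproducible from
``(cohort seed, user seed, engine seed)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .engine import EngineBundle, NutritionEngine, load_default_bundle
from .ffq import DietaryPreferences, FFQSchema, FrequencyReport
from .scoring import GuidelineEntry

__all__ = [
    "DEFAULT_LATENT_MEDIANS",
    "CohortConfig",
    "SimulatedUser",
    "SimulationTrace",
    "generate_cohort",
    "respond_ffq",
    "simulate",
    "group_target",
]

#: Default latent medians (servings/week) portraying a typical sub-optimal
#: Western-style diet: low fruit/vegetable/pulse/nut intake, moderate
#: excess of meat, sugar and ultra-processed foods.
DEFAULT_LATENT_MEDIANS: dict[str, float] = {
    "fruits": 7.0,
    "vegetables": 7.0,
    "pulses": 1.0,
    "nuts": 1.0,
    "wholegrains": 4.0,
    "olive_oil": 7.0,
    "water": 21.0,
    "fish": 1.5,
    "dairy": 10.0,
    "red_meat": 4.0,
    "processed_meat": 5.0,
    "sugary_foods": 6.0,
    "ultraprocessed": 4.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters for cohort generation."""

    latent_medians: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_MEDIANS)
    )
    latent_sigma: float = 0.5  # log-space sd of the log-normal
    compliance_prob: float = 0.9
    responsiveness: float = 0.5
    report_noise_sd: float = 0.5
    coeliac_rate: float = 0.05
    vegetarian_rates: dict[str, float] = field(
        default_factory=lambda: {
            "vegan": 0.03,
            "ovo_vegetarian": 0.02,
            "lacto_ovo_vegetarian": 0.05,
        }
    )


@dataclass(frozen=True)
class SimulatedUser:
    user_id: str
    latent_weekly: dict[str, float]
    compliance_prob: float
    responsiveness: float
    report_noise_sd: float
    prefs: DietaryPreferences
    seed: int

    def __post_init__(self):
        if any(v < 0 for v in self.latent_weekly.values()):
            raise ValidationError("latent servings must be >= 0")
        for name in ("compliance_prob", "responsiveness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.report_noise_sd < 0:
            raise ValidationError("report_noise_sd must be >= 0")


@dataclass
class SimulationTrace:
    """Chronological per-day records of one simulated intervention."""

    user_id: str
    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def latent_on(self, day: int) -> dict[str, float]:
        return self.records[day]["latent_weekly"]

    def to_json_records(self) -> list[dict]:
        return self.records


def generate_cohort(
    n: int, config: CohortConfig | None = None, seed: int = 0
) -> list[SimulatedUser]:
    """Draw ``n`` reproducible synthetic users.

    Latent weekly servings are log-normal per food group
    (``median * exp(sigma * z)``, strictly positive); dietary preferences
    follow the configured population rates.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    users: list[SimulatedUser] = []
    veg_types = list(cfg.vegetarian_rates)
    veg_probs = [cfg.vegetarian_rates[t] for t in veg_types]
    for i in range(n):
        latent = {
            g: float(m * np.exp(cfg.latent_sigma * rng.standard_normal()))
            for g, m in cfg.latent_medians.items()
        }
        u = rng.random()
        vegetarian = "none"
        acc = 0.0
        for t, p in zip(veg_types, veg_probs):
            acc += p
            if u < acc:
                vegetarian = t
                break
        users.append(
            SimulatedUser(
                user_id=f"sim_{i:04d}",
                latent_weekly=latent,
                compliance_prob=cfg.compliance_prob,
                responsiveness=cfg.responsiveness,
                report_noise_sd=cfg.report_noise_sd,
                prefs=DietaryPreferences(
                    coeliac=bool(rng.random() < cfg.coeliac_rate),
                    vegetarian_type=vegetarian,
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return users


def respond_ffq(
    user: SimulatedUser, schema: FFQSchema, seed: int
) -> list[FrequencyReport]:
    """Answer a questionnaire from the latent diet plus reporting noise.

    A group's latent weekly servings are split evenly over the schema's
    items for that group; each item's weekly value gets additive Gaussian
    noise (sd ``report_noise_sd``), is clamped at 0, and is reported in the
    most natural period unit (daily above 7/week, monthly below 1/week,
    weekly otherwise) using exact unit conversion.
    """
    rng = np.random.default_rng(seed)
    reports: list[FrequencyReport] = []
    for item in schema.items:
        n_items = len(schema.items_for_group(item.food_group_id))
        weekly = user.latent_weekly.get(item.food_group_id, 0.0) / n_items
        if user.report_noise_sd > 0:
            weekly = weekly + user.report_noise_sd * float(rng.standard_normal())
            weekly = round(max(0.0, weekly), 1)
        if weekly >= 7.0:
            period, count = "day", weekly / 7.0
        elif 0 < weekly < 1.0:
            period, count = "month", weekly * 52.0 / 12.0
        else:
            period, count = "week", weekly
        reports.append(FrequencyReport(item_id=item.item_id, count=count,
                                       period=period))
    return reports


def group_target(entry: GuidelineEntry) -> float:
    """The latent-update target: midpoint of the recommended interval, or
    its finite bound when the interval is unbounded above."""
    if entry.recommended_hi is None:
        return entry.recommended_lo
    return (entry.recommended_lo + entry.recommended_hi) / 2.0


def simulate(
    user: SimulatedUser,
    bundle: EngineBundle | None = None,
    days: int = 56,
    seed: int = 0,
    *,
    start: _dt.date = _dt.date(2024, 1, 1),
    short_ffq_every_days: int = 28,
) -> SimulationTrace:
    """Run one user through the full loop for ``days`` simulated days.

    Day 0 submits the full FFQ and auto-starts the top-ranked proposal.
    Every day the engine ticks (notifications, checkpoints), and the user
    presses the compliance button with probability ``compliance_prob``.  At
    the end of any week with at least one press, the active mission's food
    group moves toward its guideline target by fraction ``responsiveness``.
    Every 28 days a short FFQ re-reports the (possibly improved) latent
    diet and missions/levels are re-anchored.
    """
    if days < 1:
        raise ValidationError(f"days must be >= 1, got {days}")
    bundle = bundle or load_default_bundle()
    engine = NutritionEngine(bundle, user_id=user.user_id, seed=seed)
    rng = np.random.default_rng((seed, user.seed))
    latent = dict(user.latent_weekly)
    entries = {e.food_group_id: e for e in bundle.guidelines}
    trace = SimulationTrace(user_id=user.user_id)

    sim_user = user
    pressed_this_week: dict[str, bool] = {}

    def _respond(schema: FFQSchema) -> list[FrequencyReport]:
        nonlocal sim_user
        sim_user = SimulatedUser(
            user_id=user.user_id,
            latent_weekly=dict(latent),
            compliance_prob=user.compliance_prob,
            responsiveness=user.responsiveness,
            report_noise_sd=user.report_noise_sd,
            prefs=user.prefs,
            seed=user.seed,
        )
        return respond_ffq(sim_user, schema, int(rng.integers(0, 2**31 - 1)))

    for day in range(days):
        today = start + _dt.timedelta(days=day)
        day_effects: list = []

        if day == 0:
            day_effects += engine.submit_ffq(
                _respond(bundle.schemas["full"]), user.prefs, on=today
            )
        elif short_ffq_every_days and day % short_ffq_every_days == 0:
            day_effects += engine.submit_short_ffq(
                _respond(bundle.schemas["short"]), on=today
            )

        # goal setting: always work on the top proposal when idle
        if engine.active_instance is None and engine.proposals:
            engine.start(engine.proposals[0].mission_id, on=today)

        day_effects += engine.tick(on=today)

        inst = engine.active_instance
        if inst is not None and inst.state == "active":
            if rng.random() < user.compliance_prob:
                day_effects += engine.press(on=today)
                group = bundle.catalogue.by_id(inst.mission_id).food_group_id
                pressed_this_week[group] = True
            # a press may have completed the mission; restart immediately
            if engine.active_instance is None and engine.proposals:
                engine.start(engine.proposals[0].mission_id, on=today)

        # weekly latent-behaviour update on compliant weeks
        if day % 7 == 6:
            for group in pressed_this_week:
                target = group_target(entries[group])
                latent[group] = latent[group] + sim_user.responsiveness * (
                    target - latent[group]
                )
            pressed_this_week = {}

        active = engine.active_instance
        trace.records.append(
            {
                "day": day,
                "date": today.isoformat(),
                "effects": [e.get("type") for e in day_effects],
                "notifications": sum(
                    1 for e in day_effects if e.get("type") == "notification"
                ),
                "mission_id": active.mission_id if active else None,
                "mission_state": active.state if active else None,
                "progress": active.progress if active else None,
                "latent_weekly": dict(latent),
            }
        )
    return trace
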