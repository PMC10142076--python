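# nutrimission

A gamified, guideline-anchored engine for **nutritional behaviour change**,
built for digital-health teams (nutritionists, mHealth developers,
behaviour-change researchers) who want dietary coaching that works at the
**food-group level** rather than by calorie or nutrient counting.

The engine implements the full loop of a mission-based dietary
intervention, structured along the Health Action Process Approach (HAPA):

1. **Dietary assessment** — a 20-item food-frequency questionnaire (FFQ)
   plus a dietary-habits questionnaire (coeliac flag, vegetarian type) is
   normalised to weekly servings per food group and aggregated into a
   behavioural user profile. A 13-item short FFQ re-assesses progression
   monthly.
2. **Guideline scoring** — each of 13 food groups carries a recommended
   weekly serving interval (after the "Small changes to eat better" guide of
   the Public Health Agency of Catalonia) and a piecewise score table. The
   score `s_g ∈ {0, …, max_g}` measures distance from the recommendation:
   0 inside the recommended interval, saturating at `max_g` at the extreme.
   Group importance is encoded in `max_g`: 10 for vegetables, water, sugary
   foods, red meat, processed meat and ultra-processed foods; 9 for fruits;
   8 otherwise. Scores collapse to a three-level adherence status
   (1 = poor for `s > 5`, 2 = average for `3 ≤ s ≤ 5`, 3 = good for `s < 3`).
3. **Mission selection** — a catalogue of 39 missions (13 food groups × 3
   levels: beginner / advanced / expert) is ranked by score; the top 3
   "food group + level" candidates are proposed and the user commits to one
   mission at a time. Selection runs through a forward-chaining rule engine
   (working memory / rule base / inference engine) so the expert knowledge
   stays declarative and auditable.
4. **Mission monitoring** — compliance is a single button press per healthy
   action; a mission completes at its target count (default 3 presses
   within 7 days). Completion levels the user up within the food group;
   silence triggers stuck detection and coping alternatives.
5. **Motivational recommendations** — a repository of 505 tagged entries
   (390 mission-linked, "Did you know…?" tips per food group, general
   healthy-eating advice) is scheduled at a fixed cadence: a tip on mission
   start, mission-linked content every other day, one general
   recommendation per week — 3–4 notifications per steady-state week, all
   filtered by dietary suitability (gluten-free, vegan, ovo-/lacto-ovo-
   vegetarian).

A seeded synthetic-user simulator drives the whole loop end to end, so
every stage is testable without real users.

## Worked example

```python
import datetime as dt
from nutrimission import (
    DietaryPreferences, FrequencyReport, load_default_bundle, NutritionEngine,
)

bundle = load_default_bundle()
engine = NutritionEngine(bundle, user_id="ana", seed=42)

# A diet low in nuts/vegetables and heavy on processed meat:
weekly = {g: 2.0 for g in bundle.catalogue.food_groups}
weekly.update({"water": 30.0, "fruits": 14.0, "processed_meat": 8.0,
               "nuts": 0.0, "red_meat": 1.0, "sugary_foods": 1.0})
responses = []
for item in bundle.schemas["full"].items:
    n = len(bundle.schemas["full"].items_for_group(item.food_group_id))
    responses.append(
        FrequencyReport(item.item_id, weekly[item.food_group_id] / n, "week"))

engine.submit_ffq(responses, DietaryPreferences(), on=dt.date(2024, 1, 1))
for g in ("processed_meat", "fruits", "nuts"):
    sc, lvl = engine.board.entries[g]
    print(f"{g:15s} score={sc.value:2d} status_level={lvl}")
print("proposed:", [s.mission_id for s in engine.proposals])

engine.start(engine.proposals[0].mission_id, on=dt.date(2024, 1, 1))
for day in range(3):
    engine.tick(on=dt.date(2024, 1, 1 + day))
    effects = engine.press(on=dt.date(2024, 1, 1 + day))
for e in effects:
    if e["type"] in ("congratulation", "propose_missions"):
        print(e["type"] + ":", e.get("message", e.get("mission_ids")))
```

prints

```
processed_meat  score=10 status_level=1
fruits          score= 5 status_level=2
nuts            score= 8 status_level=1
proposed: ['processed_meat_l1', 'nuts_l1', 'vegetables_l1']
congratulation: Congratulations! You completed 'Processed meat Level 1: Innovate your sandwiches and toasts' and levelled up in processed meat.
propose_missions: ['processed_meat_l2']
```

Reading the output: eight weekly servings of processed meat lie beyond the
seven-per-week extreme, so the group scores its maximum of 10 and ranks
first; zero nuts score the non-priority maximum of 8 (status *poor*,
beginner mission); 14 weekly fruit servings are mid-range (score 5, status
*average*). After three compliance presses the beginner processed-meat
mission completes and the advanced level of the same food group is
proposed next.

The same workflow is available from the shell:

```sh
nutrimission init
nutrimission ffq response.json --today 2024-01-01   # full FFQ, rebuild profile
nutrimission propose                                # top-3 missions
nutrimission start processed_meat_l1 --today 2024-01-01
nutrimission tick --today 2024-01-02                # daily notifications
nutrimission log  --today 2024-01-02                # compliance press
nutrimission validate                               # check all shipped configs
nutrimission simulate --n 20 --days 56 --seed 1 --out traces.csv
```

## Configuration is data

Guideline score tables (`data/guidelines.yaml`), the mission catalogue
(`data/catalogue.yaml`), the FFQ schemas (`data/ffq_schema.yaml`) and the
rule base (`data/rules.yaml`) are YAML documents that nutritionists can
revise without touching code; `nutrimission validate` checks any revision
against the engine's structural invariants (cardinalities, score-table
monotonicity, maximum-score assignment, band consistency).

See `docs/methods.md` for the scoring model, scheduling cadence, simulator
assumptions and design decisions.
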