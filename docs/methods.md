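# Methods

This note documents the models, parameters and design decisions behind
`nutrimission`: what each component computes, which constants matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Dietary assessment and profiling

The full FFQ has 20 items, each mapped to one of 13 scored food groups
(several groups carry two items, e.g. raw and cooked vegetables). An item
response is a count per period; normalisation to servings/week uses

- day → count × 7,
- week → count,
- month → count × 12/52.

The month factor is the calendar-exact average (52 weeks / 12 months);
reported counts may be non-integers so that banded answers such as
"2–3 per week" can be encoded as 2.5. Group servings are the sum over the
group's items. The short monthly FFQ keeps one representative item per
food group; applying it overwrites exactly the covered groups and leaves
preferences and mission history untouched, so a short round trip with the
original values restores the original profile.

The 13 scored groups are an editorial reading of the source guide's focus
areas: fruits, vegetables, pulses, nuts, wholegrains, virgin olive oil,
water, fish, dairy, red meat, processed meat, sugary foods and
ultra-processed foods. Salt and "seasonal and locally grown" are treated
as advisory themes (they appear in recommendation prose) rather than
scored groups, and red and processed meat are scored separately so each
carries its own three-level mission track.

## Scoring model

Each group's guideline entry holds a recommended weekly interval, a
direction (encourage/limit), a maximum score and a piecewise-constant
score table over servings/week. Tables are **data** (`guidelines.yaml`),
not code. Table rows are upper-inclusive — a row covers
`(previous upto, upto]` — which makes strict cutoffs such as "more than
seven servings per week" exact at the boundary.

Structural invariants, enforced by `validate_guidelines` via a grid scan:

- the table is total on `[0, ∞)` and its maximum equals the group maximum
  (10 for vegetables, water, sugary foods, red meat, processed meat,
  ultra-processed; 9 for fruits; 8 otherwise);
- the score is 0 everywhere inside the recommended interval;
- the score is monotone non-decreasing with distance from the interval on
  each side;
- for nuts, 0/1/2 servings/week score into status 1 (poor) and anything
  above 3 servings/week into status 3 (good), matching the published
  mission eligibility bands.

Status levels use global score bands by default — poor for score > 5,
average for 3–5, good for < 3 — overridable per group. The published
material pins only the poor cutoff (> 5, stated for nuts); the average/good
boundary at 3 is this package's choice, made once so that every attainable
score maps to a level and the nuts serving bands above hold.

Since the full per-group tables are not published, the shipped tables were
constructed to satisfy every published constraint (the 10/9/8 maxima, the
processed-meat extreme, the nuts bands) with interval boundaries taken
from the guide's serving recommendations (e.g. nuts 3–7/week, fish 2–4/week,
red meat ≤ 2/week). They are intended as a sensible default for
nutritionists to refine.

## Rule engine

Mission selection and event handling run on a small forward-chaining
engine: facts in a working memory (keyed, re-assertion replaces and bumps
a logical timestamp), declarative rules (`rules.yaml`) with salience, an
event filter and conjunctive conditions over fact keys or event payload
fields, and actions that assert/retract facts, emit effects, or call a
registered procedural handler. Conflict resolution is salience, then
recency of matched facts, then definition order; an activation (rule +
matched-fact timestamps) fires at most once per dispatch, and a
1000-firing cycle guard turns pathological rule bases into a diagnosable
error. Conditions are deliberately restricted to simple comparisons — no
unification — to keep the rule base auditable.

The rule path and the direct procedural pipeline
(`score_profile → rank_candidates → propose_missions`) are equivalent by
construction; the test suite verifies the equivalence on 1000 random
profiles.

## Missions

39 missions = 13 groups × 3 levels. The mission level offered for a group
is its adherence status; completing the mission at that level promotes the
offer one level (never beyond expert). Ranking is by score descending,
with ties broken by group maximum (more health-relevant first), then
user-liked groups, then catalogue order; groups whose expert mission is
completed leave the ranking. The top three are proposed; the user works on
exactly one mission at a time.

Defaults (per-spec configurable): target 3 compliance events within a
7-day limit; stuck after 3 days without activity. Expired missions are
treated as stuck — coping planning offers the current top alternatives —
rather than as failures, which matches the system's coping-oriented
design. The eligibility bands stored in the catalogue mirror the
"type of users" descriptions and are validated for consistency against the
scoring pipeline; the authoritative level assignment is always computed
from the score.

## Recommendation scheduling

The shipped repository is generated programmatically: 10 mission-linked
entries per mission (390 total), 5 "Did you know…?" tips per food group,
and 50 general recommendations — 505 entries, satisfying the
more-than-500 composition requirement. Prose is placeholder; the
composition counts, ordering indices and dietary tagging are the normative
parts. Tags per mission follow a fixed pattern (seven universal entries
plus vegetarian-, omnivore- and gluten-free-specific ones) so that every
mission retains eligible content under every preference combination, which
the suite verifies exhaustively.

Cadence: the published description (a tip at mission start, mission-linked
content every two days, a general recommendation weekly) yields five
deliveries in the first week but is stated as 3–4 per week. This is
resolved by treating the day-0 tip as one-off onboarding, placing
mission-linked content on even days, the weekly general on day 5 of each
7-day block (shifted one day forward on collision), and capping each
post-onboarding block at 4 notifications by dropping the block's first
mission slot when a block would otherwise receive five. The result is
exactly 4 notifications in every steady-state week, one per day at most.
All cadence constants live in `SchedulerConfig`, not in the algorithm.

Within a pool (same type, same mission/group) delivery follows ascending
`order_index`, with seeded shuffling among equal indices; a pool is fully
consumed before anything repeats, and each new cycle is re-permuted.
Changing the seed permutes within-pool choices but never the calendar.

## Simulator

`generate_cohort` draws latent weekly servings per group from a log-normal
(`median × exp(σz)`, σ = 0.5) around medians portraying a typical
sub-optimal Western-style diet (e.g. nuts 1, pulses 1, processed meat 5,
fruits 7 servings/week); preferences follow population-like rates (5%
coeliac, 10% vegetarian of some type). Questionnaire answers add Gaussian
noise (sd 0.5 servings/week per item by default), clamp at zero, and
report in the most natural period unit with exact unit conversion.

The behavioural model is the minimal one that makes action control
observable: in any week with at least one compliance press, the active
mission's group moves toward the guideline target (interval midpoint, or
the finite bound for unbounded intervals) by fraction `responsiveness`
(default 0.5); untargeted groups never change. Daily compliance is
Bernoulli with probability `compliance_prob` (default 0.9). The short FFQ
re-enters every 28 days.

What passing simulations show: the engine's plumbing — scoring, selection,
levelling, scheduling, stuck/coping handling, monthly re-anchoring — is
correct and deterministic given seeds, and the loop improves the targeted
behaviour *under the model's own dynamics* (a 200-user cohort at
compliance 0.9 improves the median status of its first-targeted group
between day 0 and day 56; at compliance 0 it does not). What they do not
show: anything about real human adherence, dropout, recall bias beyond
additive noise, or effect sizes — the update rule is a modelling
convenience, not a fitted behaviour model.

Problem sizes used by the default suite and the acceptance computations —
1000-profile equivalence checks, 52-week schedules, 200-user × 56-day
cohorts — were chosen as the smallest sizes at which the properties are
meaningfully exercised; the full suite runs in a few seconds.

## Persistence and CLI

All state and payloads are JSON with ISO-8601 dates (`save → load → save`
is byte-identical); configs are YAML; logs and traces export as CSV. The
CLI maps the weekly workflow onto subcommands and emits line-oriented JSON
for scriptability, with `--today` and `--seed` keeping the clock and all
randomness explicit.

## Known limitations

- Mission and recommendation prose outside the published nuts example is
  placeholder text with the correct structure.
- The default level bands below the published poor cutoff, the exact score
  tables and the 13-group identity are editorial choices (flagged in the
  config comments) pending a published enumeration.
- The scheduler keeps delivering mission content while a mission is stuck;
  whether the weekly general recommendation should continue with no active
  mission is left to the caller (no schedule exists without one).
- No push transport, time-of-day windows beyond the `time_slot` tag,
  multi-user backend, or nutrient-level computation (the last is out of
  scope by design).
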