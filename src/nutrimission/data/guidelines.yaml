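# Default guideline and scoring tables, anchored on the "Small changes to eat
# better" dietary guide (Public Health Agency of Catalonia): eat more fruit,
# vegetables, pulses and nuts; switch to water, wholegrains and virgin olive
# oil; eat less sugary, red/processed-meat and ultra-processed foods.
#
# EDITORIAL NOTE on the 13 mission food groups: the guide names more aspects
# than are scored here (salt and "seasonal and locally grown" are treated as
# advisory-only, not scored); "red and processed meats" is split into two
# scored groups so each can carry its own missions.  Nutritionists can revise
# every interval and table here without touching code.
#
# score_table rows are upper-INCLUSIVE: a row covers (previous upto, upto],
# the first row covers [0, upto], upto: null means unbounded.  This makes
# "more than seven servings/week" style cutoffs exact.
#
# level bands default to the global cutoffs (score > 5 -> 1 poor,
# 3..5 -> 2 average, < 3 -> 3 good) unless overridden per group.

food_groups:
  - food_group_id: fruits
    direction: encourage
    recommended_weekly: {lo: 21, hi: null}   # 3 pieces/day
    max_score: 9
    score_table:
      - {upto: 0, score: 9}
      - {upto: 7, score: 7}
      - {upto: 14, score: 5}
      - {upto: 20, score: 2}
      - {upto: null, score: 0}

  - food_group_id: vegetables
    direction: encourage
    recommended_weekly: {lo: 14, hi: null}   # 2 servings/day
    max_score: 10
    score_table:
      - {upto: 0, score: 10}
      - {upto: 7, score: 7}
      - {upto: 13, score: 4}
      - {upto: null, score: 0}

  - food_group_id: pulses
    direction: encourage
    recommended_weekly: {lo: 3, hi: null}    # 3-4 servings/week
    max_score: 8
    score_table:
      - {upto: 0, score: 8}
      - {upto: 1, score: 5}
      - {upto: 2, score: 2}
      - {upto: null, score: 0}

  - food_group_id: nuts
    direction: encourage
    recommended_weekly: {lo: 3, hi: 7}       # a daily handful, 3-7/week
    max_score: 8
    score_table:
      - {upto: 2, score: 8}                  # 0/1/2 servings: poor
      - {upto: 7, score: 0}
      - {upto: 10, score: 1}
      - {upto: null, score: 2}

  - food_group_id: wholegrains
    direction: encourage
    recommended_weekly: {lo: 14, hi: null}   # switch to wholegrain, 2+/day
    max_score: 8
    score_table:
      - {upto: 1, score: 8}
      - {upto: 6, score: 6}
      - {upto: 13, score: 3}
      - {upto: null, score: 0}

  - food_group_id: olive_oil
    direction: encourage
    recommended_weekly: {lo: 7, hi: null}    # virgin olive oil daily
    max_score: 8
    score_table:
      - {upto: 0, score: 8}
      - {upto: 3, score: 6}
      - {upto: 6, score: 3}
      - {upto: null, score: 0}

  - food_group_id: water
    direction: encourage
    recommended_weekly: {lo: 35, hi: null}   # ~5+ glasses/day as main drink
    max_score: 10
    score_table:
      - {upto: 6, score: 10}
      - {upto: 20, score: 7}
      - {upto: 34, score: 4}
      - {upto: null, score: 0}

  - food_group_id: fish
    direction: encourage
    recommended_weekly: {lo: 2, hi: 4}       # 2-4 servings/week
    max_score: 8
    score_table:
      - {upto: 0, score: 8}
      - {upto: 1, score: 4}
      - {upto: 4, score: 0}
      - {upto: 7, score: 2}
      - {upto: null, score: 4}

  - food_group_id: dairy
    direction: encourage
    recommended_weekly: {lo: 7, hi: 21}      # 1-3 servings/day, unsweetened
    max_score: 8
    score_table:
      - {upto: 1, score: 8}
      - {upto: 6, score: 4}
      - {upto: 21, score: 0}
      - {upto: 28, score: 2}
      - {upto: null, score: 4}

  - food_group_id: red_meat
    direction: limit
    recommended_weekly: {lo: 0, hi: 2}       # at most 2 servings/week
    max_score: 10
    score_table:
      - {upto: 2, score: 0}
      - {upto: 4, score: 3}
      - {upto: 7, score: 6}
      - {upto: null, score: 10}

  - food_group_id: processed_meat
    direction: limit
    recommended_weekly: {lo: 0, hi: 1}       # occasional at most
    max_score: 10
    score_table:
      - {upto: 1, score: 0}
      - {upto: 3, score: 4}
      - {upto: 7, score: 7}
      - {upto: null, score: 10}              # more than 7/week: maximum

  - food_group_id: sugary_foods
    direction: limit
    recommended_weekly: {lo: 0, hi: 2}       # sweets + sugary drinks
    max_score: 10
    score_table:
      - {upto: 2, score: 0}
      - {upto: 4, score: 4}
      - {upto: 7, score: 7}
      - {upto: null, score: 10}

  - food_group_id: ultraprocessed
    direction: limit
    recommended_weekly: {lo: 0, hi: 1}
    max_score: 10
    score_table:
      - {upto: 1, score: 0}
      - {upto: 3, score: 4}
      - {upto: 7, score: 7}
      - {upto: null, score: 10}
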