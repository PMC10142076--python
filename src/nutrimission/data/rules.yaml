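# Default rule base: the expert knowledge wiring events to engine actions,
# kept declarative so nutritionists/knowledge engineers can audit and revise
# the behaviour without touching code.
#
# Conflict resolution: higher salience fires first, then most-recent matched
# facts, then definition order.

rules:
  # A completed questionnaire (full or short FFQ) refreshes the scores...
  - rule_id: score_on_questionnaire
    "on": questionnaire_completed
    salience: 100
    conditions:
      - {key: profile, op: exists}
    actions:
      - call: compute_scores

  # ...and fresh scores trigger a new ranked mission proposal.
  - rule_id: propose_after_scoring
    "on": questionnaire_completed
    salience: 50
    conditions:
      - {key: scoreboard_ready, op: eq, value: true}
      - {key: proposals_fresh, op: ne, value: true}
    actions:
      - call: propose_missions

  # Button press: update progress; completion is detected downstream.
  - rule_id: compliance_update
    "on": compliance_logged
    salience: 50
    actions:
      - call: record_compliance

  # Mission completed: level up, re-score, congratulate, propose next.
  - rule_id: completion_levelup
    "on": mission_completed
    salience: 100
    actions:
      - call: handle_completion

  # Mission switched: bookkeeping only (old abandoned, new active).
  - rule_id: switch_bookkeeping
    "on": mission_switched
    salience: 50
    actions:
      - call: record_switch

  # Daily checkpoint: deliver due notifications, detect stuck/expired
  # missions and offer coping alternatives.
  - rule_id: daily_checkpoint
    "on": day_advanced
    salience: 50
    actions:
      - call: daily_evaluation
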