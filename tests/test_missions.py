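import datetime as dt
import itertools

import pytest

from nutrimission.errors import StateError, ValidationError
from nutrimission.ffq import DietaryPreferences, UserProfile
from nutrimission.missions import (
    MissionInstance,
    apply_evaluation,
    evaluate_progress,
    load_catalogue,
    log_compliance,
    mission_level_for,
    on_completion,
    propose_missions,
    rank_candidates,
    start_mission,
    switch_mission,
)
from nutrimission.scoring import score_profile

D0 = dt.date(2024, 1, 1)


def _profile(bundle, weekly, history=frozenset(), liked=frozenset()):
    servings = {g: 0.0 for g in bundle.catalogue.food_groups}
    servings.update(weekly)
    return UserProfile(
        user_id="u",
        weekly_servings=servings,
        preferences=DietaryPreferences(),
        liked_groups=frozenset(liked),
        completed_missions=frozenset(history),
    )


class TestCatalogue:
    def test_default_is_13_groups_by_3_levels(self, bundle):
        cat = bundle.catalogue
        assert len(cat.food_groups) == 13
        assert len(cat.specs) == 39
        for g in cat.food_groups:
            assert {s.level for s in cat.specs if s.food_group_id == g} == {1, 2, 3}

    def test_missing_mission_named_in_error(self, bundle):
        doc = {
            "missions": [
                {"mission_id": s.mission_id, "food_group_id": s.food_group_id,
                 "level": s.level, "title": s.title}
                for s in bundle.catalogue.specs
                if not (s.food_group_id == "nuts" and s.level == 3)
            ]
        }
        with pytest.raises(ValidationError) as exc:
            load_catalogue(doc)
        assert "('nuts', 3)" in str(exc.value)

    def test_duplicate_group_level_rejected(self, bundle):
        specs = [
            {"mission_id": s.mission_id, "food_group_id": s.food_group_id,
             "level": s.level, "title": s.title}
            for s in bundle.catalogue.specs
        ]
        dup = dict(specs[0], mission_id="dup")
        with pytest.raises(ValidationError):
            load_catalogue({"missions": specs + [dup]})

    def test_level2_requires_level1_of_same_group(self, bundle):
        for g in bundle.catalogue.food_groups:
            l2 = bundle.catalogue.get(g, 2)
            assert l2.requires == bundle.catalogue.get(g, 1).mission_id


class TestMissionLevel:
    @pytest.mark.parametrize("servings,expected", [(0, 1), (1, 1), (2, 1)])
    def test_low_nut_intake_is_beginner(self, bundle, servings, expected):
        assert mission_level_for(
            "nuts", servings, set(), bundle.catalogue, bundle.guidelines
        ) == expected

    def test_completing_level1_promotes_to_advanced(self, bundle):
        assert mission_level_for(
            "nuts", 2, {"nuts_l1"}, bundle.catalogue, bundle.guidelines
        ) == 2

    def test_high_nut_intake_is_expert(self, bundle):
        assert mission_level_for(
            "nuts", 4, set(), bundle.catalogue, bundle.guidelines
        ) == 3

    def test_promotion_never_exceeds_expert(self, bundle):
        assert mission_level_for(
            "nuts", 1, {"nuts_l1", "nuts_l2", "nuts_l3"},
            bundle.catalogue, bundle.guidelines,
        ) == 3

    def test_unknown_group_rejected(self, bundle):
        with pytest.raises(ValidationError):
            mission_level_for(
                "chocolate", 1, set(), bundle.catalogue, bundle.guidelines
            )


class TestRanking:
    def test_descending_by_score(self, bundle):
        profile = _profile(bundle, {"fruits": 0.0, "nuts": 5.0})
        board = score_profile(profile, bundle.guidelines)
        ranked = rank_candidates(
            board, profile, bundle.catalogue, bundle.guidelines
        )
        assert ranked[0].score.value >= ranked[-1].score.value
        fruits_rank = next(c.rank for c in ranked if c.food_group_id == "fruits")
        nuts_rank = next(c.rank for c in ranked if c.food_group_id == "nuts")
        assert fruits_rank < nuts_rank

    def test_ranks_are_gapless_permutation(self, bundle):
        profile = _profile(bundle, {})
        board = score_profile(profile, bundle.guidelines)
        ranked = rank_candidates(
            board, profile, bundle.catalogue, bundle.guidelines
        )
        assert [c.rank for c in ranked] == list(range(1, len(ranked) + 1))
        assert {c.food_group_id for c in ranked} == set(
            bundle.catalogue.food_groups
        )

    def test_tie_breaks_exhaustively_on_three_groups(self, bundle):
        """Oracle: for groups tied on score, order is max-score descending,
        then liked groups, then catalogue order — checked by explicit
        enumeration of the expected sequence."""
        # all groups at zero intake; compare three groups that tie at 8:
        # pulses, olive_oil, fish (catalogue order: pulses < olive_oil < fish)
        for liked in ([], ["olive_oil"], ["fish"], ["olive_oil", "fish"]):
            profile = _profile(bundle, {}, liked=liked)
            board = score_profile(profile, bundle.guidelines)
            ranked = rank_candidates(
                board, profile, bundle.catalogue, bundle.guidelines
            )
            trio = [
                c.food_group_id
                for c in ranked
                if c.food_group_id in ("pulses", "olive_oil", "fish")
            ]
            order = {g: i for i, g in enumerate(bundle.catalogue.food_groups)}
            expected = sorted(
                ("pulses", "olive_oil", "fish"),
                key=lambda g: (0 if g in liked else 1, order[g]),
            )
            assert trio == expected

    def test_example_scoreboard_orders_fruits_vegetables_nuts(self, bundle):
        # fruits deviating most, vegetables mid, nuts least
        profile = _profile(
            bundle, {"fruits": 0.0, "vegetables": 5.0, "nuts": 8.0}
        )
        board = score_profile(profile, bundle.guidelines)
        ranked = rank_candidates(
            board, profile, bundle.catalogue, bundle.guidelines
        )
        sub = [
            c.food_group_id
            for c in ranked
            if c.food_group_id in ("fruits", "vegetables", "nuts")
        ]
        assert sub == ["fruits", "vegetables", "nuts"]

    def test_group_with_expert_level_completed_is_excluded(self, bundle):
        profile = _profile(bundle, {}, history={"nuts_l3"})
        board = score_profile(profile, bundle.guidelines)
        ranked = rank_candidates(
            board, profile, bundle.catalogue, bundle.guidelines
        )
        assert all(c.food_group_id != "nuts" for c in ranked)


class TestProposal:
    def _ranked(self, bundle, profile):
        board = score_profile(profile, bundle.guidelines)
        return rank_candidates(
            board, profile, bundle.catalogue, bundle.guidelines
        )

    def test_top_three_proposed(self, bundle):
        ranked = self._ranked(bundle, _profile(bundle, {}))
        proposals = propose_missions(ranked, bundle.catalogue)
        assert len(proposals) == 3
        assert [p.food_group_id for p in proposals] == [
            c.food_group_id for c in ranked[:3]
        ]

    def test_fewer_candidates_truncate(self, bundle):
        ranked = self._ranked(bundle, _profile(bundle, {}))[:2]
        assert len(propose_missions(ranked, bundle.catalogue)) == 2

    def test_proposal_is_prefix_of_ranking(self, bundle):
        ranked = self._ranked(bundle, _profile(bundle, {"red_meat": 9.0}))
        proposals = propose_missions(ranked, bundle.catalogue)
        for spec, cand in zip(proposals, ranked):
            assert spec.food_group_id == cand.food_group_id
            assert spec.level == cand.level

    def test_proposals_match_level_assignment(self, bundle):
        """Every proposed mission carries exactly the level the profile's
        servings and history imply for that group."""
        import numpy as np

        rng = np.random.default_rng(3)
        for _ in range(20):
            weekly = {
                g: float(rng.uniform(0, 25))
                for g in bundle.catalogue.food_groups
            }
            profile = _profile(bundle, weekly)
            proposals = propose_missions(
                self._ranked(bundle, profile), bundle.catalogue
            )
            for spec in proposals:
                assert spec.level == mission_level_for(
                    spec.food_group_id,
                    weekly[spec.food_group_id],
                    set(),
                    bundle.catalogue,
                    bundle.guidelines,
                )


class TestLifecycle:
    def _spec(self, bundle):
        return bundle.catalogue.by_id("nuts_l1")

    def test_start_gives_active_zero_progress(self, bundle):
        inst = start_mission(self._spec(bundle), "u", D0)
        assert inst.state == "active"
        assert inst.progress == 0

    def test_second_concurrent_start_rejected(self, bundle):
        inst = start_mission(self._spec(bundle), "u", D0)
        with pytest.raises(StateError):
            start_mission(bundle.catalogue.by_id("fruits_l1"), "u", D0,
                          existing=[inst])

    def test_switch_abandons_old_and_activates_new(self, bundle):
        inst = start_mission(self._spec(bundle), "u", D0)
        old, new = switch_mission(
            inst, bundle.catalogue.by_id("fruits_l1"), D0
        )
        assert old.state == "abandoned"
        assert new.state == "active"
        assert new.mission_id == "fruits_l1"

    def test_compliance_log_drives_progress(self, bundle):
        inst = start_mission(self._spec(bundle), "u", D0)
        for k in range(3):
            inst = log_compliance(inst, D0 + dt.timedelta(days=k))
        assert inst.progress == 3
        assert inst.progress == len(inst.compliance_log)

    def test_logging_on_completed_instance_rejected(self, bundle):
        inst = start_mission(self._spec(bundle), "u", D0)
        inst = log_compliance(inst, D0)
        done = apply_evaluation(inst, "completed")
        with pytest.raises(StateError):
            log_compliance(done, D0)

    def test_state_machine_edges_exhaustive(self, bundle):
        """Every (state, state) pair outside the declared edges raises."""
        allowed = {
            ("proposed", "active"),
            ("active", "completed"), ("active", "stuck"),
            ("active", "abandoned"),
            ("stuck", "active"), ("stuck", "abandoned"),
        }
        states = ("proposed", "active", "completed", "stuck", "abandoned")
        for a, b in itertools.product(states, states):
            inst = MissionInstance(
                instance_id="i", mission_id="nuts_l1", user_id="u",
                state=a, started_on=D0,
            )
            if (a, b) in allowed:
                assert inst._transition(b).state == b
            else:
                with pytest.raises(StateError):
                    inst._transition(b)


class TestEvaluateProgress:
    def _active(self, bundle, progress_days=()):
        inst = start_mission(bundle.catalogue.by_id("nuts_l1"), "u", D0)
        for d in progress_days:
            inst = log_compliance(inst, D0 + dt.timedelta(days=d))
        return inst

    def test_target_reached_is_completed(self, bundle):
        inst = self._active(bundle, (0, 1, 2))
        spec = bundle.catalogue.by_id("nuts_l1")
        assert evaluate_progress(
            inst, spec, D0 + dt.timedelta(days=4)
        ) == "completed"

    def test_silent_days_make_stuck(self, bundle):
        """Oracle: slide a window over the log; the instance is stuck on
        the first day lying >= stuck_after_days after the last activity."""
        inst = self._active(bundle, (0, 1))
        spec = bundle.catalogue.by_id("nuts_l1")
        for day in range(2, 8):
            outcome = evaluate_progress(
                inst, spec, D0 + dt.timedelta(days=day), stuck_after_days=3
            )
            expected = "stuck" if day - 1 >= 3 else "ongoing"
            assert outcome == expected, f"day {day}"

    def test_time_limit_exceeded_is_expired(self, bundle):
        inst = self._active(bundle, (7,))
        spec = bundle.catalogue.by_id("nuts_l1")
        assert evaluate_progress(
            inst, spec, D0 + dt.timedelta(days=8)
        ) == "expired"

    def test_expired_is_treated_as_stuck(self, bundle):
        inst = self._active(bundle)
        assert apply_evaluation(inst, "expired").state == "stuck"


class TestCompletion:
    def _complete(self, bundle, mission_id, weekly, history=frozenset()):
        profile = _profile(bundle, weekly, history=history)
        spec = bundle.catalogue.by_id(mission_id)
        inst = start_mission(spec, "u", D0)
        for k in range(spec.target_count):
            inst = log_compliance(inst, D0 + dt.timedelta(days=k))
        inst = apply_evaluation(inst, "completed")
        return on_completion(inst, profile, bundle.catalogue, bundle.guidelines)

    def test_next_proposal_is_same_group_next_level(self, bundle):
        _, _, proposals, congrats = self._complete(bundle, "nuts_l1", {})
        assert proposals[0].mission_id == "nuts_l2"
        assert "ongratulation" in congrats

    def test_expert_completion_moves_to_other_group(self, bundle):
        _, _, proposals, _ = self._complete(
            bundle, "nuts_l3", {"nuts": 4.0},
            history={"nuts_l1", "nuts_l2"},
        )
        assert proposals
        assert all(p.food_group_id != "nuts" for p in proposals)

    def test_history_grows_by_exactly_one(self, bundle):
        profile2, _, _, _ = self._complete(bundle, "nuts_l1", {})
        assert profile2.completed_missions == {"nuts_l1"}
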