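import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wit2 import (
    Arm,
    GlucosePanel,
    HypoEvent,
    Period,
    Reason,
    TitrationDecision,
    administered_units,
    apply_decision,
    attribute_hypo,
    classify_hypoglycemia,
    decide_titration,
    governing_readings,
    initiate_doses,
    make_arm_params,
)
from wit2.protocol import INJECTIONS, MEALS


def panel(day, fbg=12.0, b=13.0, l=13.0, d=13.0, night=11.0):
    return GlucosePanel(day=day, fbg=fbg, ppg={"breakfast": b, "lunch": l, "dinner": d}, bg_0300=night)


class TestArmParams:
    def test_rejects_unknown_arm(self):
        with pytest.raises(ValueError):
            make_arm_params("2:1")

    def test_ratio_is_exact(self, params_a, params_b):
        assert params_a.bolus_basal_ratio == 1.5
        assert params_b.bolus_basal_ratio == 1.0

    def test_printed_rule_sets(self, params_a, params_b):
        assert (params_a.tdd_init_per_kg, params_a.basal_init_per_kg, params_a.bolus_init_total_per_kg) == (0.5, 0.2, 0.3)
        assert (params_a.basal_increment_per_kg, params_a.bolus_increment_per_meal_per_kg) == (0.1, 0.05)
        assert (params_b.tdd_init_per_kg, params_b.basal_init_per_kg, params_b.bolus_init_total_per_kg) == (0.4, 0.2, 0.2)
        assert params_b.bolus_increment_per_meal_per_kg == pytest.approx(0.1 / 3, abs=1e-15)
        for p in (params_a, params_b):
            assert (p.fbg_target, p.ppg_target) == (7.8, 10.0)
            assert p.basal_decrement_per_kg == p.basal_increment_per_kg
            assert p.bolus_decrement_per_meal_per_kg == p.bolus_increment_per_meal_per_kg


class TestInitiation:
    def test_seventy_kg_1_1_5(self, params_a):
        state = initiate_doses(70, params_a)
        assert administered_units(state.basal_per_kg, 70) == 14
        assert [administered_units(state.bolus_per_kg[m], 70) for m in MEALS] == [7, 7, 7]

    def test_sixty_kg_1_1(self, params_b):
        state = initiate_doses(60, params_b)
        assert administered_units(state.basal_per_kg, 60) == 12
        assert [administered_units(state.bolus_per_kg[m], 60) for m in MEALS] == [4, 4, 4]

    def test_rejects_nonpositive_weight(self, params_a):
        with pytest.raises(ValueError):
            initiate_doses(0, params_a)

    @given(weight=st.floats(40, 140), arm=st.sampled_from(list(Arm)))
    def test_tdd_conserved_and_meals_equal(self, weight, arm):
        p = make_arm_params(arm)
        state = initiate_doses(weight, p)
        assert state.day == 1
        assert state.tdd_per_kg == pytest.approx(p.tdd_init_per_kg, abs=1e-12)
        assert len({state.bolus_per_kg[m] for m in MEALS}) == 1


@pytest.mark.parametrize(
    "per_kg,weight,mode,expected",
    [
        (0.1, 66.8, "nearest", 7.0),
        (0.2, 70, "nearest", 14.0),
        (0.0, 93.4, "nearest", 0.0),
        (0.05, 70, "nearest", 4.0),  # 3.5 rounds half away from zero
        (0.1, 66.8, "exact", 6.68),
    ],
)
def test_administered_units(per_kg, weight, mode, expected):
    assert administered_units(per_kg, weight, mode) == pytest.approx(expected, abs=1e-12)


class TestGoverningReadings:
    def test_schedule(self):
        history = [panel(1, l=9.1, d=12.5), panel(2, fbg=8.4, b=11.3, d=10.7), panel(3)]
        got = governing_readings(history, 2)
        assert got == {"basal": 8.4, "breakfast": 11.3, "lunch": 9.1, "dinner": 12.5}
        assert governing_readings(history, 3)["dinner"] == 10.7

    def test_day_one_has_no_previous_day(self):
        got = governing_readings([panel(1)], 1)
        assert got["lunch"] is None and got["dinner"] is None
        assert got["basal"] == 12.0

    def test_missing_panels_are_absent(self):
        assert governing_readings([], 5) == {k: None for k in INJECTIONS}

    def test_rejects_day_below_one(self):
        with pytest.raises(ValueError):
            governing_readings([], 0)


@pytest.mark.parametrize(
    "bg,assisted,level",
    [(3.5, False, 1), (3.0, False, 1), (2.9, False, 2), (3.9, False, 0),
     (3.89, False, 1), (7.0, False, 0), (5.0, True, 3)],
)
def test_classify_hypoglycemia(bg, assisted, level):
    assert classify_hypoglycemia(bg, assisted) == level


@pytest.mark.parametrize(
    "period,injection",
    [(Period.NIGHT, "basal"), (Period.MORNING, "breakfast"),
     (Period.AFTERNOON, "lunch"), (Period.EVENING, "dinner")],
)
def test_attribute_hypo(period, injection):
    event = HypoEvent(day=3, period=period, bg=3.4)
    assert attribute_hypo(event) == injection


class TestDecideTitration:
    def all_above(self):
        return {"basal": 12.0, "breakfast": 13.0, "lunch": 12.5, "dinner": 14.0}

    @pytest.mark.parametrize("arm", list(Arm))
    def test_all_above_target_steps_up(self, arm):
        p = make_arm_params(arm)
        state = initiate_doses(70, p)
        dec = decide_titration(state, self.all_above(), [], p)
        assert dec.delta_per_kg["basal"] == p.basal_increment_per_kg
        for m in MEALS:
            assert dec.delta_per_kg[m] == p.bolus_increment_per_meal_per_kg
        assert all(r is Reason.ABOVE_TARGET_UP for r in dec.reason.values())

    def test_reading_below_target_holds_that_meal(self, params_a):
        state = initiate_doses(70, params_a)
        readings = {**self.all_above(), "lunch": 9.2}
        dec = decide_titration(state, readings, [], params_a)
        assert dec.delta_per_kg["lunch"] == 0.0
        assert dec.reason["lunch"] is Reason.AT_TARGET_HOLD
        assert dec.delta_per_kg["dinner"] > 0

    def test_reading_exactly_at_target_titrates_up(self, params_a):
        state = initiate_doses(70, params_a)
        readings = {**self.all_above(), "basal": 7.8, "lunch": 10.0}
        dec = decide_titration(state, readings, [], params_a)
        assert dec.reason["basal"] is Reason.ABOVE_TARGET_UP
        assert dec.reason["lunch"] is Reason.ABOVE_TARGET_UP

    def test_night_hypo_reduces_basal_despite_high_fbg(self, params_a):
        state = initiate_doses(70, params_a)
        hypo = [HypoEvent(day=1, period=Period.NIGHT, bg=3.4)]
        dec = decide_titration(state, self.all_above(), hypo, params_a)
        assert dec.delta_per_kg["basal"] == -params_a.basal_decrement_per_kg
        assert dec.reason["basal"] is Reason.HYPO_DOWN

    def test_hypo_action_hold_keeps_dose(self, params_a):
        state = initiate_doses(70, params_a)
        hypo = [HypoEvent(day=1, period=Period.AFTERNOON, bg=3.1)]
        dec = decide_titration(state, self.all_above(), hypo, params_a, hypo_action="hold")
        assert dec.delta_per_kg["lunch"] == 0.0
        assert dec.reason["lunch"] is Reason.HYPO_DOWN

    def test_absent_reading_holds(self, params_a):
        state = initiate_doses(70, params_a)
        readings = {**self.all_above(), "lunch": None, "dinner": None}
        dec = decide_titration(state, readings, [], params_a)
        assert dec.reason["lunch"] is Reason.NO_READING_HOLD
        assert dec.delta_per_kg["dinner"] == 0.0

    def test_every_injection_gets_a_reason(self, params_b):
        state = initiate_doses(55, params_b)
        dec = decide_titration(state, {}, [], params_b)
        assert set(dec.reason) == set(INJECTIONS)
        assert set(dec.delta_per_kg) == set(INJECTIONS)

    def test_locked_meal_never_steps_up(self, params_a):
        state = initiate_doses(70, params_a)
        dec = decide_titration(state, self.all_above(), [], params_a, locked={"lunch"})
        assert dec.delta_per_kg["lunch"] == 0.0


class TestApplyDecision:
    def up_decision(self, state, p):
        return decide_titration(
            state, {"basal": 12.0, "breakfast": 13.0, "lunch": 12.5, "dinner": 14.0}, [], p
        )

    def test_two_escalations_give_printed_day3_doses(self, params_a):
        state = initiate_doses(70, params_a)
        for _ in range(2):
            state = apply_decision(state, self.up_decision(state, params_a))
        assert state.day == 3
        assert administered_units(state.basal_per_kg, 70) == 28
        for m in MEALS:
            assert administered_units(state.bolus_per_kg[m], 70) == 14

    def test_one_escalation_1_1_gives_tenth_per_kg_per_meal(self, params_b):
        state = initiate_doses(60, params_b)
        state = apply_decision(state, self.up_decision(state, params_b))
        for m in MEALS:
            assert state.bolus_per_kg[m] == pytest.approx(0.1, abs=1e-12)

    def test_zero_decision_is_identity_except_day(self, params_a):
        state = initiate_doses(70, params_a)
        zero = TitrationDecision(
            day=1,
            delta_per_kg={k: 0.0 for k in INJECTIONS},
            reason={k: Reason.AT_TARGET_HOLD for k in INJECTIONS},
        )
        nxt = apply_decision(state, zero)
        assert nxt.day == 2
        assert nxt.basal_per_kg == state.basal_per_kg
        assert nxt.bolus_per_kg == state.bolus_per_kg

    def test_dose_clamped_at_zero(self, params_a):
        state = initiate_doses(70, params_a)
        state = state.__class__(day=1, basal_per_kg=0.05, bolus_per_kg=state.bolus_per_kg, weight=70)
        down = TitrationDecision(
            day=1,
            delta_per_kg={"basal": -0.1, "breakfast": 0.0, "lunch": 0.0, "dinner": 0.0},
            reason={k: Reason.HYPO_DOWN if k == "basal" else Reason.AT_TARGET_HOLD for k in INJECTIONS},
        )
        assert apply_decision(state, down).basal_per_kg == 0.0

    def test_day_mismatch_rejected(self, params_a):
        state = initiate_doses(70, params_a)
        dec = self.up_decision(state, params_a)
        state2 = apply_decision(state, dec)
        with pytest.raises(ValueError):
            apply_decision(state2, dec)

    def test_tdd_ceiling_blocks_escalation(self, params_a, caplog):
        state = initiate_doses(70, params_a)
        with caplog.at_level("WARNING", logger="wit2.protocol"):
            for _ in range(40):
                state = apply_decision(state, self.up_decision(state, params_a), tdd_ceiling_per_kg=3.0)
        assert state.tdd_per_kg <= 3.0 + 1e-12
        assert any("ceiling" in rec.message for rec in caplog.records)

    def test_hypo_down_never_with_positive_delta(self):
        with pytest.raises(ValueError):
            TitrationDecision(
                day=1,
                delta_per_kg={"basal": 0.1, "breakfast": 0.0, "lunch": 0.0, "dinner": 0.0},
                reason={k: Reason.HYPO_DOWN if k == "basal" else Reason.AT_TARGET_HOLD for k in INJECTIONS},
            )


class TestLedgerProperties:
    @given(
        arm=st.sampled_from(list(Arm)),
        days=st.integers(1, 8),
    )
    def test_monotone_escalation_is_exactly_one_increment_per_day(self, arm, days):
        """Above target with no hypoglycemia: +increment/day, every injection."""
        p = make_arm_params(arm)
        state = initiate_doses(66.0, p)
        readings = {"basal": 15.0, "breakfast": 16.0, "lunch": 16.0, "dinner": 16.0}
        for _ in range(days):
            state = apply_decision(state, decide_titration(state, readings, [], p))
        assert state.basal_per_kg == pytest.approx(
            p.basal_init_per_kg + days * p.basal_increment_per_kg, abs=1e-12
        )
        for m in MEALS:
            assert state.bolus_per_kg[m] == pytest.approx(
                p.bolus_init_total_per_kg / 3 + days * p.bolus_increment_per_meal_per_kg,
                abs=1e-12,
            )

    @settings(max_examples=1000)
    @given(
        arm=st.sampled_from(list(Arm)),
        moves=st.lists(
            st.tuples(*[st.sampled_from(["up", "hold", "down"]) for _ in INJECTIONS]),
            min_size=1,
            max_size=12,
        ),
    )
    def test_doses_never_negative_under_random_decision_streams(self, arm, moves):
        p = make_arm_params(arm)
        state = initiate_doses(66.0, p)
        for move in moves:
            delta, reason = {}, {}
            for inj, m in zip(INJECTIONS, move):
                if m == "up":
                    delta[inj], reason[inj] = p.increment_for(inj), Reason.ABOVE_TARGET_UP
                elif m == "down":
                    delta[inj], reason[inj] = -p.decrement_for(inj), Reason.HYPO_DOWN
                else:
                    delta[inj], reason[inj] = 0.0, Reason.AT_TARGET_HOLD
            state = apply_decision(
                state, TitrationDecision(day=state.day, delta_per_kg=delta, reason=reason)
            )
            assert state.basal_per_kg >= 0.0
            assert all(v >= 0.0 for v in state.bolus_per_kg.values())


def test_panel_rejects_implausible_readings():
    with pytest.raises(ValueError):
        panel(1, fbg=0.0)
    with pytest.raises(ValueError):
        panel(1, b=61.0)


def test_day_one_bolus_must_be_equal_across_meals(params_a):
    state = initiate_doses(70, params_a)
    assert len({state.bolus_per_kg[m] for m in MEALS}) == 1


def test_hypo_event_level_autofilled_and_checked():
    ev = HypoEvent(day=2, period=Period.MORNING, bg=2.5)
    assert ev.level == 2
    with pytest.raises(ValueError):
        HypoEvent(day=2, period=Period.MORNING, bg=5.0)  # not hypoglycemic
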