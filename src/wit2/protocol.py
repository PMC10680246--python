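"""Deterministic dosing engine for weight-based basal-bolus insulin therapy.

Implements the WIT2 (weight-based initiation and titration) algorithm for
hospitalized adults with type 2 diabetes.  Two arms are supported, named by
their basal:bolus ratio:

* ``1:1.5`` — total daily dose (TDD) 0.5 U/kg, split 0.2 U/kg glargine and
  0.3 U/kg aspart; glargine titrated by 0.1 U/kg/day, aspart by
  0.05 U/kg/day per meal.
* ``1:1`` — TDD 0.4 U/kg, split 0.2 U/kg glargine and 0.2 U/kg aspart;
  glargine titrated by 0.1 U/kg/day, aspart by 0.1/3 U/kg/day per meal.

Glargine is titrated against the fasting glucose target (< 7.8 mmol/L) and
each meal's aspart against the 2-h postprandial target (< 10.0 mmol/L).
A reading exactly at a threshold counts as *not* at target (titrate up).
Hypoglycemia attributed to an injection reduces that injection's dose by the
same per-kg step (or holds it, depending on configuration).

All titration bookkeeping is carried in exact per-kg units; rounding to
whole pen units happens only at administration time (see
:func:`administered_units`), so rounding error never compounds across days.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

log = logging.getLogger(__name__)

MEALS: tuple[str, ...] = ("breakfast", "lunch", "dinner")
INJECTIONS: tuple[str, ...] = ("basal",) + MEALS

#: Default safety ceiling on total daily dose, units/kg/day.  The protocol
#: itself states no cap; this guards runaway simulations only.
DEFAULT_TDD_CEILING_PER_KG = 3.0


class Arm(str, Enum):
    """Trial arm, named by its basal:bolus ratio at initiation."""

    RATIO_1_1_5 = "1:1.5"
    RATIO_1_1 = "1:1"


class Reason(str, Enum):
    """Why a titration decision moved (or held) one injection."""

    ABOVE_TARGET_UP = "ABOVE_TARGET_UP"
    AT_TARGET_HOLD = "AT_TARGET_HOLD"
    HYPO_DOWN = "HYPO_DOWN"
    NO_READING_HOLD = "NO_READING_HOLD"


class Period(str, Enum):
    """Clock period of a glucose reading (boundaries 06:30/12:00/17:30/23:00)."""

    MORNING = "morning"      # 06:30-12:00
    AFTERNOON = "afternoon"  # 12:00-17:30
    EVENING = "evening"      # 17:30-23:00
    NIGHT = "night"          # 23:00-06:30


#: Which injection a hypoglycemic episode in each period is attributed to,
#: by temporal proximity of insulin action: the bedtime basal dose is the
#: only insulin active overnight; each meal bolus dominates its own
#: postprandial window.
PERIOD_TO_INJECTION: dict[Period, str] = {
    Period.NIGHT: "basal",
    Period.MORNING: "breakfast",
    Period.AFTERNOON: "lunch",
    Period.EVENING: "dinner",
}


@dataclass(frozen=True)
class ProtocolParams:
    """One arm's complete rule set: initiation splits, steps, and targets.

    All doses are in units per kg body weight; targets in mmol/L.
    """

    arm_label: Arm
    tdd_init_per_kg: float
    basal_init_per_kg: float
    bolus_init_total_per_kg: float
    basal_increment_per_kg: float
    bolus_increment_per_meal_per_kg: float
    basal_decrement_per_kg: float
    bolus_decrement_per_meal_per_kg: float
    fbg_target: float = 7.8
    ppg_target: float = 10.0

    def __post_init__(self) -> None:
        if not math.isclose(
            self.basal_init_per_kg + self.bolus_init_total_per_kg,
            self.tdd_init_per_kg,
            rel_tol=0,
            abs_tol=1e-12,
        ):
            raise ValueError("basal + bolus initiation doses must equal the TDD")
        for name in (
            "tdd_init_per_kg",
            "basal_init_per_kg",
            "bolus_init_total_per_kg",
            "basal_increment_per_kg",
            "bolus_increment_per_meal_per_kg",
            "basal_decrement_per_kg",
            "bolus_decrement_per_meal_per_kg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.fbg_target < self.ppg_target:
            raise ValueError("fasting target must lie below the postprandial target")

    @property
    def bolus_basal_ratio(self) -> float:
        """Initiation bolus:basal ratio (1.5 or 1.0).

        Rounded to 12 decimals so the decimal ratios the protocol states
        are recovered exactly despite binary float representation.
        """
        return round(self.bolus_init_total_per_kg / self.basal_init_per_kg, 12)

    def increment_for(self, injection: str) -> float:
        return (
            self.basal_increment_per_kg
            if injection == "basal"
            else self.bolus_increment_per_meal_per_kg
        )

    def decrement_for(self, injection: str) -> float:
        return (
            self.basal_decrement_per_kg
            if injection == "basal"
            else self.bolus_decrement_per_meal_per_kg
        )

    def target_for(self, injection: str) -> float:
        return self.fbg_target if injection == "basal" else self.ppg_target


def make_arm_params(arm_label: Arm | str) -> ProtocolParams:
    """Return the printed rule set for one trial arm.

    Parameters
    ----------
    arm_label
        ``Arm.RATIO_1_1_5`` (or ``"1:1.5"``) or ``Arm.RATIO_1_1`` (``"1:1"``).
    """
    arm = Arm(arm_label)
    if arm is Arm.RATIO_1_1_5:
        return ProtocolParams(
            arm_label=arm,
            tdd_init_per_kg=0.5,
            basal_init_per_kg=0.2,
            bolus_init_total_per_kg=0.3,
            basal_increment_per_kg=0.1,
            bolus_increment_per_meal_per_kg=0.05,
            basal_decrement_per_kg=0.1,
            bolus_decrement_per_meal_per_kg=0.05,
        )
    return ProtocolParams(
        arm_label=arm,
        tdd_init_per_kg=0.4,
        basal_init_per_kg=0.2,
        bolus_init_total_per_kg=0.2,
        basal_increment_per_kg=0.1,
        bolus_increment_per_meal_per_kg=0.1 / 3,
        basal_decrement_per_kg=0.1,
        bolus_decrement_per_meal_per_kg=0.1 / 3,
    )


@dataclass(frozen=True)
class DoseState:
    """The per-kg dose ledger for one patient-day.

    ``day`` 1 is the first day of insulin therapy (admission day).  The
    ledger holds the doses *ordered* for that day: the basal entry is
    injected at that night's bedtime, the breakfast entry at that morning's
    pre-breakfast injection, lunch and dinner before their meals.
    """

    day: int
    basal_per_kg: float
    bolus_per_kg: Mapping[str, float]
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.basal_per_kg < 0 or any(v < 0 for v in self.bolus_per_kg.values()):
            raise ValueError("per-kg doses must be non-negative")
        if set(self.bolus_per_kg) != set(MEALS):
            raise ValueError(f"bolus ledger must cover exactly {MEALS}")

    def per_kg(self, injection: str) -> float:
        if injection == "basal":
            return self.basal_per_kg
        return self.bolus_per_kg[injection]

    @property
    def tdd_per_kg(self) -> float:
        return self.basal_per_kg + sum(self.bolus_per_kg.values())


@dataclass(frozen=True)
class GlucosePanel:
    """One day's five scheduled capillary readings (mmol/L).

    ``fbg`` before breakfast, ``ppg`` two hours after each meal,
    ``bg_0300`` at 03:00 that calendar day (i.e. the night preceding that
    day's fasting reading).  ``extra_readings`` holds symptomatic spot
    checks as ``(period, mmol/L)`` pairs.
    """

    day: int
    fbg: float
    ppg: Mapping[str, float]
    bg_0300: float
    extra_readings: Sequence[tuple[Period, float]] = ()

    def __post_init__(self) -> None:
        values = [self.fbg, self.bg_0300, *self.ppg.values()]
        values += [bg for _, bg in self.extra_readings]
        if any(not (0 < v < 60) for v in values):
            raise ValueError("glucose readings must lie in (0, 60) mmol/L")
        if set(self.ppg) != set(MEALS):
            raise ValueError(f"postprandial readings must cover exactly {MEALS}")


@dataclass(frozen=True)
class HypoEvent:
    """A hypoglycemic episode: level 1 (3.0-3.9), 2 (< 3.0) or 3 (assisted)."""

    day: int
    period: Period
    bg: float
    level: int = field(default=0)
    assisted: bool = False

    def __post_init__(self) -> None:
        expected = classify_hypoglycemia(self.bg, self.assisted)
        if self.level == 0:
            object.__setattr__(self, "level", expected)
        elif self.level != expected and not (self.assisted and self.level == 3):
            raise ValueError(
                f"level {self.level} inconsistent with bg={self.bg}, assisted={self.assisted}"
            )
        if self.level not in (1, 2, 3):
            raise ValueError("a HypoEvent must have level 1, 2 or 3")


@dataclass(frozen=True)
class TitrationDecision:
    """Signed per-kg dose deltas and a reason code for all four injections."""

    day: int
    delta_per_kg: Mapping[str, float]
    reason: Mapping[str, Reason]

    def __post_init__(self) -> None:
        if set(self.delta_per_kg) != set(INJECTIONS) or set(self.reason) != set(INJECTIONS):
            raise ValueError(f"decision must cover exactly {INJECTIONS}")
        for inj in INJECTIONS:
            if self.reason[inj] is Reason.HYPO_DOWN and self.delta_per_kg[inj] > 0:
                raise ValueError("HYPO_DOWN cannot carry a positive delta")


def classify_hypoglycemia(bg: float, assisted: bool = False) -> int:
    """Classify a glucose reading: 0 = no event, 1, 2 or 3 (assisted).

    Level 1 is 3.0 <= BG < 3.9 mmol/L, level 2 is BG < 3.0 mmol/L; an event
    requiring third-party assistance is level 3 regardless of the reading.

    >>> classify_hypoglycemia(3.5)
    1
    >>> classify_hypoglycemia(3.9)
    0
    """
    if bg <= 0:
        raise ValueError("bg must be positive")
    if assisted:
        return 3
    if bg < 3.0:
        return 2
    if bg < 3.9:
        return 1
    return 0


def attribute_hypo(event: HypoEvent) -> str:
    """Map a hypoglycemic episode to the injection whose titration it holds."""
    return PERIOD_TO_INJECTION[event.period]


def initiate_doses(weight: float, params: ProtocolParams) -> DoseState:
    """Day-1 dose ledger: basal per the arm's split, bolus in three equal parts."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    per_meal = params.bolus_init_total_per_kg / 3
    return DoseState(
        day=1,
        basal_per_kg=params.basal_init_per_kg,
        bolus_per_kg={meal: per_meal for meal in MEALS},
        weight=weight,
    )


def administered_units(
    per_kg: float, weight: float, rounding_mode: str = "nearest"
) -> float:
    """Convert a per-kg dose to the administered dose in pen units.

    ``nearest`` (default) rounds the product to the nearest whole unit,
    halves away from zero; ``exact`` returns the unrounded product.  The
    per-kg ledger itself is never rounded, so discretization cannot drift.
    """
    if per_kg < 0:
        raise ValueError("per_kg must be non-negative")
    dose = per_kg * weight
    if rounding_mode == "exact":
        return dose
    if rounding_mode == "nearest":
        return float(math.floor(dose + 0.5))
    raise ValueError(f"unknown rounding mode {rounding_mode!r}")


ABSENT = None  # sentinel for a governing reading that does not exist


def governing_readings(
    history: Sequence[GlucosePanel], day: int
) -> dict[str, Optional[float]]:
    """The four readings that govern ``day``'s 09:00 titration decision.

    Basal is judged on the same day's fasting reading, the breakfast bolus
    on the same day's post-breakfast reading, and the lunch and dinner
    boluses on the *previous* day's post-meal readings (the day-``day``
    values are not yet measured at decision time).  A missing panel yields
    ``None`` (absent) for its readings.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    by_day = {p.day: p for p in history}
    today = by_day.get(day)
    yesterday = by_day.get(day - 1)
    return {
        "basal": today.fbg if today else ABSENT,
        "breakfast": today.ppg["breakfast"] if today else ABSENT,
        "lunch": yesterday.ppg["lunch"] if yesterday else ABSENT,
        "dinner": yesterday.ppg["dinner"] if yesterday else ABSENT,
    }


def decide_titration(
    state: DoseState,
    readings: Mapping[str, Optional[float]],
    hypo_last_24h: Sequence[HypoEvent],
    params: ProtocolParams,
    *,
    hypo_action: str = "reduce",
    locked: frozenset[str] | set[str] = frozenset(),
) -> TitrationDecision:
    """One day's titration decision for all four injections.

    Per injection, in priority order: (1) an attributed hypoglycemic episode
    in the last 24 h forces a step down (``hypo_action="reduce"``) or a hold
    (``"hold"``), reason ``HYPO_DOWN``; (2) an absent governing reading holds
    (``NO_READING_HOLD``); (3) a reading at or above its target steps up by
    the arm's printed increment (``ABOVE_TARGET_UP``); (4) otherwise the dose
    holds (``AT_TARGET_HOLD``).  ``locked`` injections (permanent-stop
    configuration) never step up.
    """
    if hypo_action not in ("reduce", "hold"):
        raise ValueError(f"unknown hypo_action {hypo_action!r}")
    hypo_injections = {attribute_hypo(ev) for ev in hypo_last_24h}
    delta: dict[str, float] = {}
    reason: dict[str, Reason] = {}
    for inj in INJECTIONS:
        reading = readings.get(inj, ABSENT)
        if inj in hypo_injections:
            delta[inj] = -params.decrement_for(inj) if hypo_action == "reduce" else 0.0
            reason[inj] = Reason.HYPO_DOWN
        elif reading is ABSENT:
            delta[inj] = 0.0
            reason[inj] = Reason.NO_READING_HOLD
        elif reading >= params.target_for(inj) and inj not in locked:
            delta[inj] = params.increment_for(inj)
            reason[inj] = Reason.ABOVE_TARGET_UP
        else:
            delta[inj] = 0.0
            reason[inj] = Reason.AT_TARGET_HOLD
    return TitrationDecision(day=state.day, delta_per_kg=delta, reason=reason)


def apply_decision(
    state: DoseState,
    decision: TitrationDecision,
    *,
    tdd_ceiling_per_kg: float = DEFAULT_TDD_CEILING_PER_KG,
) -> DoseState:
    """Advance the ledger one day by the decision's deltas, clamped at zero.

    Timing contract: the basal delta takes effect at that night's bedtime
    injection, lunch and dinner deltas the same day, and the breakfast delta
    the following morning (the 09:00 decision post-dates that day's
    pre-breakfast injection) — i.e. the next-day ledger's breakfast entry is
    the first one the delta reaches.

    If the increments would push the total daily dose above
    ``tdd_ceiling_per_kg``, the upward steps are skipped for that day (a
    warning is logged); decrements always apply.
    """
    if decision.day != state.day:
        raise ValueError(f"decision day {decision.day} != state day {state.day}")

    def stepped(include_increments: bool) -> tuple[float, dict[str, float]]:
        basal = state.basal_per_kg
        bolus = dict(state.bolus_per_kg)
        for inj in INJECTIONS:
            d = decision.delta_per_kg[inj]
            if d > 0 and not include_increments:
                continue
            if inj == "basal":
                basal = max(0.0, basal + d)
            else:
                bolus[inj] = max(0.0, bolus[inj] + d)
        return basal, bolus

    basal, bolus = stepped(include_increments=True)
    if basal + sum(bolus.values()) > tdd_ceiling_per_kg:
        log.warning(
            "day %d: TDD ceiling %.2f U/kg reached; upward titration skipped",
            state.day,
            tdd_ceiling_per_kg,
        )
        basal, bolus = stepped(include_increments=False)
    return replace(state, day=state.day + 1, basal_per_kg=basal, bolus_per_kg=bolus)
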