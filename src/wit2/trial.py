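"""In-silico two-arm inpatient trial: day loop, endpoints, arm bookkeeping.

Couples the virtual-patient glucose model to the dosing engine one day at a
time, mirroring the ward routine the algorithm was designed for:

* day 1 is the initiation day — the weight-based doses are ordered, the
  first aspart is given before breakfast and the first glargine at bedtime;
* from day 2 on, the 09:00 round reviews the same day's fasting and
  post-breakfast readings and the previous day's post-lunch/dinner
  readings, plus any hypoglycemia in the last 24 h, and titrates;
* a titration's basal delta reaches that night's bedtime injection, lunch
  and dinner deltas reach the same day's meals, and the breakfast delta the
  next morning (that day's pre-breakfast dose is already given).

The primary endpoint is the first day (counted from day 2, the first
on-treatment day for every reading) on which a reading falls below its
target; patients who never reach a target are censored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as vc
from .cohort import CohortConfig, LatentState, PatientProfile
from .protocol import (
    DEFAULT_TDD_CEILING_PER_KG,
    INJECTIONS,
    MEALS,
    Arm,
    DoseState,
    GlucosePanel,
    HypoEvent,
    Period,
    ProtocolParams,
    Reason,
    administered_units,
    apply_decision,
    classify_hypoglycemia,
    decide_titration,
    governing_readings,
    initiate_doses,
    make_arm_params,
)

CENSORED = None

#: Clock period of each scheduled reading.
READING_PERIOD: dict[str, Period] = {
    "fbg": Period.MORNING,
    "breakfast": Period.MORNING,
    "lunch": Period.AFTERNOON,
    "dinner": Period.EVENING,
    "bg_0300": Period.NIGHT,
}

#: First-passage search starts here: readings governed by insulin first
#: administered on day 1 cannot respond before day 2.
DEFAULT_START_DAY = 2


@dataclass(frozen=True)
class TrialRecord:
    """Per-patient endpoint bundle."""

    patient_id: str
    arm: str
    weight: float
    days_to_target: Mapping[str, Optional[int]]  # keys fbg/breakfast/lunch/dinner
    final_doses: Mapping[str, float]  # administered units/day per injection
    hypo_events: tuple[HypoEvent, ...]
    days_observed: int
    daily: tuple[dict, ...] = ()  # per-day trace rows (doses, readings, reasons)

    def __post_init__(self) -> None:
        for key, day in self.days_to_target.items():
            if day is not CENSORED and day > self.days_observed:
                raise ValueError(f"{key}: days_to_target beyond days_observed")
        if any(v < 0 for v in self.final_doses.values()):
            raise ValueError("final doses must be non-negative")


@dataclass(frozen=True)
class CohortResult:
    """All records of one simulated trial, keyed by arm label."""

    arms: Mapping[str, tuple[TrialRecord, ...]]
    meta: Mapping[str, object]

    def records(self) -> list[TrialRecord]:
        return [r for recs in self.arms.values() for r in recs]


def days_to_target(
    series: Sequence[float],
    threshold: float,
    start_day: int = DEFAULT_START_DAY,
) -> Optional[int]:
    """First day (1-based) at or after ``start_day`` with a reading strictly
    below ``threshold``; ``None`` (censored) if the series never crosses.

    A reading exactly at the threshold does not count as at target.
    """
    if not len(series):
        raise ValueError("series must be non-empty")
    for i, value in enumerate(series, start=1):
        if i >= start_day and value < threshold:
            return i
    return CENSORED


def _panel_hypos(panel: GlucosePanel) -> list[HypoEvent]:
    """Hypoglycemic episodes evident in one day's readings."""
    events = []
    pairs = [("fbg", panel.fbg), ("bg_0300", panel.bg_0300)]
    pairs += [(meal, panel.ppg[meal]) for meal in MEALS]
    for key, bg in pairs:
        if classify_hypoglycemia(bg) > 0:
            events.append(HypoEvent(day=panel.day, period=READING_PERIOD[key], bg=bg))
    for period, bg in panel.extra_readings:
        if classify_hypoglycemia(bg) > 0:
            events.append(HypoEvent(day=panel.day, period=period, bg=bg))
    return events


def run_patient(
    profile: PatientProfile,
    params: ProtocolParams,
    max_days: int = 10,
    rng: np.random.Generator | None = None,
    *,
    hypo_action: str = "reduce",
    bolus_stop: str = "suspend",
    tdd_ceiling_per_kg: float = DEFAULT_TDD_CEILING_PER_KG,
    start_day: int = DEFAULT_START_DAY,
    rounding_mode: str = "nearest",
    keep_trace: bool = True,
) -> TrialRecord:
    """Simulate one patient's stay under the titration protocol.

    ``rng=None`` runs the glucose model noise-free.  Noise draws are
    consumed in the wall-clock order of the readings (fasting,
    post-breakfast and 03:00 before the 09:00 decision; post-lunch and
    post-dinner after it), so runs are bitwise-reproducible.

    The loop stops at ``max_days``, or earlier once every reading has
    reached its target and a full day passes with no dose change.
    """
    if max_days < 2:
        raise ValueError("max_days must be >= 2")
    if bolus_stop not in ("suspend", "permanent"):
        raise ValueError(f"unknown bolus_stop {bolus_stop!r}")

    state = initiate_doses(profile.weight, params)
    latent = vc.initial_latent(profile)
    panels: list[GlucosePanel] = []
    all_hypos: list[HypoEvent] = []
    locked: set[str] = set()
    trace: list[dict] = []
    prev_events: list[HypoEvent] = []  # afternoon/evening of the previous day
    days_observed = max_days

    def measure(value: float) -> float:
        return vc._measure(value, rng, profile.noise_sd)

    for day in range(1, max_days + 1):
        # --- morning: previous-bedtime basal acts on fasting physiology ---
        basal_prev_night = state.basal_per_kg if day >= 2 else 0.0
        fasting = vc.relax(
            latent.fasting, vc.fasting_setpoint(profile, basal_prev_night), profile.lag
        )
        fbg = measure(fasting)
        breakfast_dose = state.bolus_per_kg["breakfast"]
        post = dict(latent.postprandial)
        post["breakfast"] = vc.relax(
            post["breakfast"],
            vc.meal_setpoint(profile, "breakfast", breakfast_dose, basal_prev_night),
            profile.lag,
        )
        ppg_breakfast = measure(post["breakfast"])
        bg_0300 = measure(fasting - profile.nocturnal_dip)

        # --- 09:00 round: decide (from day 2) ---
        morning_events = [
            HypoEvent(day=day, period=READING_PERIOD[k], bg=bg)
            for k, bg in (("fbg", fbg), ("breakfast", ppg_breakfast), ("bg_0300", bg_0300))
            if classify_hypoglycemia(bg) > 0
        ]
        if day >= 2:
            partial = panels + [
                GlucosePanel(
                    day=day,
                    fbg=fbg,
                    ppg={"breakfast": ppg_breakfast, "lunch": 55.0, "dinner": 55.0},
                    bg_0300=bg_0300,
                )
            ]
            readings = governing_readings(partial, day)
            decision = decide_titration(
                state,
                readings,
                prev_events + morning_events,
                params,
                hypo_action=hypo_action,
                locked=locked,
            )
            next_state = apply_decision(
                state, decision, tdd_ceiling_per_kg=tdd_ceiling_per_kg
            )
            if bolus_stop == "permanent":
                for meal in MEALS:
                    r = readings[meal]
                    if r is not None and r < params.ppg_target:
                        locked.add(meal)
        else:
            decision = None
            next_state = replace(state, day=2)

        # --- afternoon/evening: same-day lunch & dinner deltas apply ---
        for meal in ("lunch", "dinner"):
            post[meal] = vc.relax(
                post[meal],
                vc.meal_setpoint(
                    profile, meal, next_state.bolus_per_kg[meal], basal_prev_night
                ),
                profile.lag,
            )
        panel = GlucosePanel(
            day=day,
            fbg=fbg,
            ppg={
                "breakfast": ppg_breakfast,
                "lunch": measure(post["lunch"]),
                "dinner": measure(post["dinner"]),
            },
            bg_0300=bg_0300,
        )
        panels.append(panel)
        latent = LatentState(day=day, fasting=fasting, postprandial=post)

        afternoon_events = [
            HypoEvent(day=day, period=READING_PERIOD[meal], bg=panel.ppg[meal])
            for meal in ("lunch", "dinner")
            if classify_hypoglycemia(panel.ppg[meal]) > 0
        ]
        all_hypos += morning_events + afternoon_events
        prev_events = afternoon_events

        if keep_trace:
            row = {
                "day": day,
                "fbg": fbg,
                "ppg_breakfast": panel.ppg["breakfast"],
                "ppg_lunch": panel.ppg["lunch"],
                "ppg_dinner": panel.ppg["dinner"],
                "bg_0300": bg_0300,
                "basal_perkg": next_state.basal_per_kg,
                "bolus_breakfast_perkg": state.bolus_per_kg["breakfast"],
                "bolus_lunch_perkg": next_state.bolus_per_kg["lunch"],
                "bolus_dinner_perkg": next_state.bolus_per_kg["dinner"],
            }
            for inj in INJECTIONS:
                row[f"reason_{inj}"] = (
                    decision.reason[inj].value if decision is not None else ""
                )
            trace.append(row)

        # --- early stop: all targets reached and doses stable for a day ---
        if day >= start_day:
            fbg_hit = any(
                i >= start_day and p.fbg < params.fbg_target
                for i, p in enumerate(panels, start=1)
            )
            meals_hit = all(
                any(
                    i >= start_day and p.ppg[m] < params.ppg_target
                    for i, p in enumerate(panels, start=1)
                )
                for m in MEALS
            )
            stable = decision is not None and all(
                d == 0 for d in decision.delta_per_kg.values()
            )
            if fbg_hit and meals_hit and stable:
                days_observed = day
                state = next_state
                break
        state = next_state

    result_days = {
        "fbg": days_to_target(
            [p.fbg for p in panels], params.fbg_target, start_day
        ),
    }
    for meal in MEALS:
        result_days[meal] = days_to_target(
            [p.ppg[meal] for p in panels], params.ppg_target, start_day
        )
    final_doses = {
        inj: administered_units(state.per_kg(inj), profile.weight, rounding_mode)
        for inj in INJECTIONS
    }
    return TrialRecord(
        patient_id=profile.id,
        arm=params.arm_label.value,
        weight=profile.weight,
        days_to_target=result_days,
        final_doses=final_doses,
        hypo_events=tuple(all_hypos),
        days_observed=days_observed,
        daily=tuple(trace) if keep_trace else (),
    )


def _config_hash(config: CohortConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_trial(
    config: CohortConfig,
    seed: int | None = None,
    *,
    dropout_rate: float = 0.0,
    noise: bool = True,
    **patient_kwargs,
) -> CohortResult:
    """Run the full two-arm in-silico trial, reproducible by seed.

    One cohort is sampled, arm labels (1:1 allocation, or the explicit
    per-arm counts when ``config.n_per_arm`` is a pair) are assigned by a
    seeded permutation, and every patient is run through
    :func:`run_patient` on an independent random substream.  Optional
    ``dropout_rate`` removes patients after randomization, before analysis.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    seed = config.seed if seed is None else seed
    if isinstance(config.n_per_arm, tuple):
        n_a, n_b = config.n_per_arm
    else:
        n_a = n_b = config.n_per_arm
    labels = [Arm.RATIO_1_1_5.value] * n_a + [Arm.RATIO_1_1.value] * n_b
    master = np.random.default_rng(np.random.SeedSequence([seed, 2_000_001]))
    order = master.permutation(len(labels))
    labels = [labels[i] for i in order]

    sample_rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_002]))
    params_by_arm = {a.value: make_arm_params(a) for a in Arm}
    arms: dict[str, list[TrialRecord]] = {a.value: [] for a in Arm}
    n_randomized = len(labels)
    n_dropped = 0
    for i, arm_label in enumerate(labels):
        pid = f"P{i + 1:04d}"
        profile = vc.sample_patient(sample_rng, config, pid)
        if dropout_rate > 0 and master.random() < dropout_rate:
            n_dropped += 1
            continue
        prng = vc.patient_rng(seed, pid) if noise else None
        record = run_patient(
            profile,
            params_by_arm[arm_label],
            max_days=config.max_days,
            rng=prng,
            **patient_kwargs,
        )
        arms[arm_label].append(record)
    meta = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_randomized": n_randomized,
        "n_analyzed": n_randomized - n_dropped,
        "noise": noise,
    }
    return CohortResult(
        arms={k: tuple(v) for k, v in arms.items()}, meta=meta
    )


def hypo_by_period(records: Sequence[TrialRecord]) -> dict[str, dict[object, int]]:
    """Patients with at least one episode, by clock period and level.

    A patient counts once per (period, level) and once in the period's
    ``"any"`` bucket regardless of how many episodes they had — the
    patient-denominator convention used for inpatient hypoglycemia rates.
    """
    counts: dict[str, dict[object, int]] = {
        p.value: {1: 0, 2: 0, 3: 0, "any": 0} for p in Period
    }
    for rec in records:
        seen: set[tuple[str, int]] = set()
        periods: set[str] = set()
        for ev in rec.hypo_events:
            seen.add((ev.period.value, ev.level))
            periods.add(ev.period.value)
        for period, level in seen:
            counts[period][level] += 1
        for period in periods:
            counts[period]["any"] += 1
    return counts


def records_to_frame(result: CohortResult) -> pd.DataFrame:
    """Tidy one-row-per-patient frame of endpoints, doses and hypo counts."""
    rows = []
    for arm_label, records in result.arms.items():
        for rec in records:
            row: dict[str, object] = {
                "patient_id": rec.patient_id,
                "arm": arm_label,
                "weight": rec.weight,
                "days_observed": rec.days_observed,
            }
            for key in ("fbg", *MEALS):
                row[f"days_{key}"] = rec.days_to_target[key]
            for inj in INJECTIONS:
                row[f"final_{inj}_units"] = rec.final_doses[inj]
            per_patient = hypo_by_period([rec])
            for period in (p.value for p in Period):
                for level in (1, 2, 3):
                    row[f"hypo_{period}_l{level}"] = per_patient[period][level]
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["arm", "patient_id"]).reset_index(drop=True)


def replay_decision(
    weight: float,
    params: ProtocolParams,
    panels: Sequence[GlucosePanel],
    day: int,
    *,
    hypo_action: str = "reduce",
    bolus_stop: str = "suspend",
    tdd_ceiling_per_kg: float = DEFAULT_TDD_CEILING_PER_KG,
):
    """Replay titration over an observed panel history up to ``day``.

    Returns ``(state, decision, next_state)``: the ledger in effect that
    morning, the day's decision (``None`` on the initiation day), and the
    post-decision ledger.  The doses actually administered on ``day`` are
    the morning ledger's breakfast entry plus the post-decision basal,
    lunch and dinner entries (same timing contract as the simulator).
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    state = initiate_doses(weight, params)
    if day == 1:
        return state, None, replace(state, day=2)
    by_day = {p.day: p for p in panels}
    locked: set[str] = set()
    cur = replace(state, day=2)
    for d in range(2, day + 1):
        readings = governing_readings(panels, d)
        events: list[HypoEvent] = []
        prev = by_day.get(d - 1)
        if prev is not None:
            events += [
                ev for ev in _panel_hypos(prev)
                if ev.period in (Period.AFTERNOON, Period.EVENING)
            ]
        today = by_day.get(d)
        if today is not None:
            events += [
                ev for ev in _panel_hypos(today)
                if ev.period in (Period.MORNING, Period.NIGHT)
            ]
        decision = decide_titration(
            cur, readings, events, params, hypo_action=hypo_action, locked=locked
        )
        nxt = apply_decision(cur, decision, tdd_ceiling_per_kg=tdd_ceiling_per_kg)
        if bolus_stop == "permanent":
            for meal in MEALS:
                r = readings[meal]
                if r is not None and r < params.ppg_target:
                    locked.add(meal)
        if d == day:
            return cur, decision, nxt
        cur = nxt
    raise AssertionError("unreachable")
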