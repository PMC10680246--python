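"""Independent scalar day-loop oracle for the titration + glucose pipeline.

Deliberately written from first principles against the documented rules
(printed per-kg constants, governing-reading schedule, timing contract,
first-order setpoint dynamics) using plain scalars and no wit2 machinery,
so it can serve as an external check on the package's trial loop.
"""

from __future__ import annotations

import math

FBG_TARGET = 7.8
PPG_TARGET = 10.0
HYPO_BG = 3.9
FLOOR = 1.0

ARM_CONSTANTS = {
    # basal init, per-meal bolus init, basal step, per-meal bolus step
    "1:1.5": (0.2, 0.1, 0.1, 0.05),
    "1:1": (0.2, 0.2 / 3, 0.1, 0.1 / 3),
}


def oracle_run(
    weight: float,
    fbg_base: float,
    ppg_base: dict[str, float],
    s_basal: float,
    s_bolus: float,
    c_spill: float,
    lag: float,
    dip: float,
    arm: str,
    max_days: int = 10,
) -> dict:
    """Noise-free single-patient run; returns endpoints, final doses, trace."""
    b_init, m_init, b_step, m_step = ARM_CONSTANTS[arm]

    basal = b_init            # order after the most recent decision
    lunch = m_init
    dinner = m_init
    bkf = m_init              # dose delivered at the next breakfast

    F = fbg_base
    P = dict(ppg_base)
    first_pass: dict[str, int | None] = {k: None for k in ("fbg", "breakfast", "lunch", "dinner")}
    trace = []
    yesterday_pm_hypo: dict[str, bool] = {"lunch": False, "dinner": False}
    days_observed = max_days

    for day in range(1, max_days + 1):
        bed_basal_prev = basal if day >= 2 else 0.0

        # morning physiology: fasting + post-breakfast + 03:00
        F = F + lag * ((fbg_base - s_basal * bed_basal_prev) - F)
        bkf_delivered = bkf
        P["breakfast"] = P["breakfast"] + lag * (
            (ppg_base["breakfast"] - s_bolus * bkf_delivered - c_spill * bed_basal_prev)
            - P["breakfast"]
        )
        fbg_reading = max(FLOOR, F)
        ppg_b_reading = max(FLOOR, P["breakfast"])
        night_reading = max(FLOOR, F - dip)

        deltas = {"basal": 0.0, "breakfast": 0.0, "lunch": 0.0, "dinner": 0.0}
        if day >= 2:
            hypo = {
                "basal": night_reading < HYPO_BG,
                "breakfast": fbg_reading < HYPO_BG or ppg_b_reading < HYPO_BG,
                "lunch": yesterday_pm_hypo["lunch"],
                "dinner": yesterday_pm_hypo["dinner"],
            }
            governing = {
                "basal": (fbg_reading, FBG_TARGET),
                "breakfast": (ppg_b_reading, PPG_TARGET),
                "lunch": (trace[-1]["ppg_lunch"], PPG_TARGET),
                "dinner": (trace[-1]["ppg_dinner"], PPG_TARGET),
            }
            for inj, (reading, target) in governing.items():
                step = b_step if inj == "basal" else m_step
                if hypo[inj]:
                    deltas[inj] = -step
                elif reading >= target:
                    deltas[inj] = step
            basal = max(0.0, basal + deltas["basal"])
            bkf = max(0.0, bkf + deltas["breakfast"])
            lunch = max(0.0, lunch + deltas["lunch"])
            dinner = max(0.0, dinner + deltas["dinner"])

        # afternoon/evening: same-day lunch & dinner deltas apply
        P["lunch"] = P["lunch"] + lag * (
            (ppg_base["lunch"] - s_bolus * lunch - c_spill * bed_basal_prev) - P["lunch"]
        )
        P["dinner"] = P["dinner"] + lag * (
            (ppg_base["dinner"] - s_bolus * dinner - c_spill * bed_basal_prev) - P["dinner"]
        )
        ppg_l_reading = max(FLOOR, P["lunch"])
        ppg_d_reading = max(FLOOR, P["dinner"])
        yesterday_pm_hypo = {
            "lunch": ppg_l_reading < HYPO_BG,
            "dinner": ppg_d_reading < HYPO_BG,
        }

        if day >= 2:
            if first_pass["fbg"] is None and fbg_reading < FBG_TARGET:
                first_pass["fbg"] = day
            for meal, reading in (
                ("breakfast", ppg_b_reading),
                ("lunch", ppg_l_reading),
                ("dinner", ppg_d_reading),
            ):
                if first_pass[meal] is None and reading < PPG_TARGET:
                    first_pass[meal] = day

        trace.append(
            {
                "day": day,
                "fbg": fbg_reading,
                "ppg_breakfast": ppg_b_reading,
                "ppg_lunch": ppg_l_reading,
                "ppg_dinner": ppg_d_reading,
                "bg_0300": night_reading,
                "basal_perkg": basal,
                "bolus_breakfast_perkg": bkf_delivered,
                "bolus_lunch_perkg": lunch,
                "bolus_dinner_perkg": dinner,
            }
        )

        all_hit = all(v is not None for v in first_pass.values())
        stable = day >= 2 and all(d == 0.0 for d in deltas.values())
        if all_hit and stable:
            days_observed = day
            break

    final_units = {
        "basal": math.floor(basal * weight + 0.5),
        "breakfast": math.floor(bkf * weight + 0.5),
        "lunch": math.floor(lunch * weight + 0.5),
        "dinner": math.floor(dinner * weight + 0.5),
    }
    return {
        "days_to_target": first_pass,
        "final_doses": final_units,
        "days_observed": days_observed,
        "trace": trace,
    }
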