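"""Titrate one 70-kg patient through three days of glucose readings.

Builds a small panel history by hand, replays the weight-based titration
rules over it, and prints each day's four injections.  Doses rise by the
arm's printed per-kg steps while readings sit above target (fasting
7.8 mmol/L, post-meal 10.0 mmol/L), hold once a reading drops below, and
step down after hypoglycemia.
"""

from wit2 import GlucosePanel, administered_units, make_arm_params
from wit2.protocol import INJECTIONS
from wit2.trial import replay_decision

weight = 70.0
params = make_arm_params("1:1.5")

history = [
    GlucosePanel(day=1, fbg=12.4, ppg={"breakfast": 14.1, "lunch": 13.0, "dinner": 12.2}, bg_0300=10.8),
    GlucosePanel(day=2, fbg=10.1, ppg={"breakfast": 11.6, "lunch": 9.4, "dinner": 11.0}, bg_0300=9.0),
    GlucosePanel(day=3, fbg=8.9, ppg={"breakfast": 9.8, "lunch": 9.1, "dinner": 9.9}, bg_0300=7.7),
]

for day in (1, 2, 3):
    state, decision, nxt = replay_decision(weight, params, history, day)
    print(f"day {day}:")
    for inj in INJECTIONS:
        # breakfast is injected before the 09:00 round, so its dose lags a day
        per_kg = state.per_kg(inj) if inj == "breakfast" else nxt.per_kg(inj)
        reason = decision.reason[inj].value if decision else "INITIATION"
        print(f"  {inj:<9} {administered_units(per_kg, weight):>4.0f} U  ({per_kg:.3f} U/kg)  {reason}")

print(
    "\nDay 1 is the weight-based start (0.5 U/kg total: 14 U glargine, 7 U aspart per meal).\n"
    "Day 2 escalates everything still above target; day 3 holds the lunch bolus because\n"
    "the previous day's post-lunch reading (9.4 mmol/L) was already below 10.0."
)
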