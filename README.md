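# wit2 — weight-based basal–bolus insulin titration, in silico

`wit2` is a Python library (with a thin CLI) for the WIT2 class of
inpatient insulin protocols: basal–bolus therapy in hospitalized adults
with type 2 diabetes where **both initiation and daily titration are
expressed in units per kg body weight**, instead of the glucose-indexed
sliding scales most wards still use. It is aimed at researchers who want
to study such treat-to-target dosing rules — their dynamics, endpoints and
statistics — without clinical data, by coupling the deterministic dosing
engine to a synthetic virtual-patient glucose model.

The package provides:

- **`wit2.protocol`** — the dosing engine. Two arms, named by their
  basal:bolus ratio: *1:1.5* (TDD 0.5 U/kg: glargine 0.2, aspart 0.3
  split equally over three meals; steps +0.1 and +0.05 U/kg/day) and
  *1:1* (TDD 0.4 U/kg: 0.2/0.2; steps +0.1 and +0.1/3 U/kg/day).
  Glargine titrates against FBG < 7.8 mmol/L, each meal's aspart against
  2hBG < 10.0 mmol/L, using the same day's fasting/post-breakfast and the
  previous day's post-lunch/post-dinner readings; hypoglycemia
  (level 1: 3.0–3.9, level 2: < 3.0 mmol/L, level 3: assisted) steps the
  attributed injection down.
- **`wit2.diet`** — the standardized ward diet: ideal weight =
  height (cm) − 105, 25–30 kcal/kg/day by BMI, protein 1.0 g/kg, fat
  0.8 g/kg, rest carbohydrate, meals 1:2:2.
- **`wit2.cohort`** — synthetic inpatients: baseline marginals matching a
  Chinese T2D ward population (weight ≈ 66 ± 11 kg, admission glucose
  ≈ 18.6 ± 5.4 mmol/L), log-normal insulin sensitivities, and a
  day-granular first-order glucose response
  `F_d = F_{d−1} + lag·(setpoint − F_{d−1})` with dose-proportional
  setpoints and Gaussian measurement noise.
- **`wit2.trial`** — the in-silico two-arm randomized trial: per-patient
  day loop, first-passage days-to-target endpoints (censoring included),
  final doses, hypoglycemia by clock period.
- **`wit2.stats`** — endpoint statistics: pooled/Welch t-tests from raw or
  summary data, 2×2 chi-square for proportions, dropout-inflated
  enrollment arithmetic, and arm-level reports.

See `docs/methods.md` for the model, its assumptions and its limitations,
and `examples/` for narrative scripts (one per capability).

## Worked example

Titrate a 70-kg patient on the 1:1.5 arm from a three-day glucose history
(`python examples/titrate_one_patient.py`):

```
day 1:
  basal       14 U  (0.200 U/kg)  INITIATION
  breakfast    7 U  (0.100 U/kg)  INITIATION
  lunch        7 U  (0.100 U/kg)  INITIATION
  dinner       7 U  (0.100 U/kg)  INITIATION
day 2:
  basal       21 U  (0.300 U/kg)  ABOVE_TARGET_UP
  breakfast    7 U  (0.100 U/kg)  ABOVE_TARGET_UP
  lunch       11 U  (0.150 U/kg)  ABOVE_TARGET_UP
  dinner      11 U  (0.150 U/kg)  ABOVE_TARGET_UP
day 3:
  basal       28 U  (0.400 U/kg)  ABOVE_TARGET_UP
  breakfast   11 U  (0.150 U/kg)  AT_TARGET_HOLD
  lunch       11 U  (0.150 U/kg)  AT_TARGET_HOLD
  dinner      14 U  (0.200 U/kg)  ABOVE_TARGET_UP
```

Day 1 is the weight-based start: 0.5 U/kg total — 14 U glargine plus
3 × 7 U aspart at 70 kg. On day 2 every governing reading is still at or
above target, so glargine rises by 0.1 U/kg and each bolus by
0.05 U/kg (the breakfast increase reaches the *next* morning's injection,
since that day's dose is already given by the 09:00 round). On day 3 the
lunch bolus holds because the previous day's post-lunch reading
(9.4 mmol/L) was already below the 10.0 mmol/L target.

Running a small simulated trial (`python examples/run_small_trial.py`,
30 patients/arm, seed 42) prints, among others:

```
arm 1:1.5 (n = 30):
  days to post-lunch     3.5 +/- 1.6 (censored 0)
arm 1:1 (n = 30):
  days to post-lunch     4.7 +/- 2.5 (censored 0)
between-arm p-values (pooled t):
  days to lunch: p = 0.034
```

i.e. the arm carrying more prandial insulin reaches post-meal targets
earlier, while fasting control (identical basal rules) is comparable —
the structural behavior this class of protocol is designed around.

## Command line

```sh
wit2 dose --weight 70 --arm 1:1.5 --day 2 --history panels.csv
wit2 diet 170 80 --format json
wit2 simulate --config cfg.yaml --seed 7 --out run/
wit2 analyze run/results.csv --out report.json
```

All commands are pure functions of (inputs, config, seed): re-runs are
byte-identical. Glucose CSVs use columns
`day,fbg,ppg_breakfast,ppg_lunch,ppg_dinner,bg_0300` (mmol/L, header
required, days 1-based).

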