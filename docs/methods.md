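# Methods

## The dosing algorithm

`wit2` implements a weight-based basal–bolus insulin algorithm for
hospitalized adults with type 2 diabetes, in which both initiation and
daily titration are expressed in units per kg body weight rather than in
glucose-indexed sliding scales. Two regimens are implemented, named by
their basal:bolus ratio at initiation:

| arm | TDD | glargine | aspart (total) | glargine step | aspart step / meal |
|---|---|---|---|---|---|
| 1:1.5 | 0.5 U/kg | 0.2 U/kg | 0.3 U/kg | 0.1 U/kg/day | 0.05 U/kg/day |
| 1:1 | 0.4 U/kg | 0.2 U/kg | 0.2 U/kg | 0.1 U/kg/day | 0.1/3 U/kg/day |

Aspart is divided equally across breakfast, lunch and dinner. Glargine is
titrated against the fasting target (FBG < 7.8 mmol/L) and each meal's
aspart against the 2-h postprandial target (2hBG < 10.0 mmol/L). The
decision is made at the 09:00 ward round using the same day's FBG and
post-breakfast reading and the *previous* day's post-lunch and post-dinner
readings, since the latter are not yet measured at decision time.
Hypoglycemia (level 1: 3.0 ≤ BG < 3.9 mmol/L; level 2: BG < 3.0 mmol/L;
level 3: any event requiring third-party assistance) attributed to an
injection steps that injection down by the same per-kg amount.

### Decision rules and tie-breaks

Per injection, in priority order: hypoglycemia in the preceding 24 h →
step down; governing reading absent → hold; reading ≥ target → step up;
otherwise hold. Notable choices where the protocol statement leaves room:

- **Reduce vs. hold on hypoglycemia.** The rule table prints signed
  reductions while the prose says titration "was held"; we default to the
  reduction (the table is the normative statement) and expose
  `hypo_action: reduce|hold`.
- **Resumption after reaching target.** A meal whose reading falls below
  10.0 stops titrating, but may resume if a later governing reading is
  again at/above target (a permanent lockout would be implausible for a
  treat-to-target protocol); `bolus_stop: suspend|permanent` selects the
  alternative.
- **Boundary readings.** A reading exactly equal to its threshold counts
  as *not* at target (the targets are strict "< 7.8" / "< 10.0"), so it
  titrates up; symmetrically, first-passage to target requires a strictly
  lower reading.
- **Hypo attribution.** Episodes are mapped to injections by clock period
  (boundaries 06:30/12:00/17:30/23:00): night → basal, morning →
  breakfast bolus, afternoon → lunch bolus, evening → dinner bolus —
  temporal proximity of insulin action. A hypoglycemic FBG therefore
  reduces the breakfast bolus; basal-driven lows are caught by the 03:00
  reading, which falls in the night period.
- **Hypoglycemia beats hyperglycemia** when both occur for the same
  injection within 24 h.

### Timing contract

Day 1 is the first day of insulin therapy (admission day); titration
decisions begin on day 2, the first morning with a previous day's
post-meal readings. Within a decision: the basal delta reaches that
night's bedtime injection (so it first influences the next day's FBG);
lunch and dinner deltas reach the same day's meals; the breakfast delta
reaches the *next* morning, because the 09:00 round post-dates that day's
pre-breakfast injection.

### Dose arithmetic

The titration ledger is kept in exact per-kg units and never rounded;
rounding to whole pen units (nearest, halves away from zero) happens only
at administration, so discretization error cannot compound across days.
Doses are clamped at zero. No ceiling is part of the protocol; a
configurable guard (default 3.0 U/kg/day total) skips further escalation
and logs a warning, purely to bound runaway simulations.

## Diet prescription

Ideal body weight is height (cm) − 105. Total energy is 25 kcal/kg ideal
weight for overweight/obese patients and 30 kcal/kg otherwise; the BMI
threshold defaults to 24 kg/m² (the Chinese adult criterion, configurable)
with the coefficient 25 applied at the threshold. Protein is 1.0 g/kg and
fat 0.8 g/kg of ideal weight; the remaining energy is carbohydrate using
Atwater factors 4/9/4 kcal/g. Meals split 1:2:2; breakfast is
floor-rounded to a whole kcal and the remainder divided equally between
lunch and dinner so totals conserve. The carbohydrate fraction is
*reported*, not asserted: the formula yields > 55% of energy at
30 kcal/kg for typical heights, and the package surfaces the computed
value rather than forcing a nominal 50–55% band.

## Virtual patients

No physiological model accompanies the algorithm, so the simulator uses a
deliberately simple day-granular first-order response instead of an
intra-day glucose–insulin ODE (e.g. a Bergman-type minimal model): the
protocol only ever sees once-daily readings, and the first-order form
keeps an independent closed-form oracle feasible. Each monitored reading
has a latent level relaxing toward a dose-determined setpoint at rate
`lag` per day:

    F_d = F_{d−1} + lag · (setpoint_d − F_{d−1})
    fasting setpoint  = fbg_base − s_basal · basal
    post-meal setpoint = ppg_base[meal] − s_bolus · bolus[meal] − c_spill · basal

with the basal dose taken from the previous bedtime. Measured readings add
i.i.d. Gaussian noise (SD `noise_sd`) and are floored at 1.0 mmol/L; the
03:00 reading sits `nocturnal_dip` below the fasting latent. Hypoglycemia
emerges from the same model — any measured reading < 3.9 mmol/L — rather
than from a separate event process; assisted (level-3) events are not
generated.

### Cohort distributions and calibration

Baseline marginals emulate the target ward population: weight ~
N(66, 11²) kg truncated to [40, 120], height ~ N(164, 8²) cm in
[145, 190], admission glucose ~ N(18.6, 5.4²) mmol/L in (10, 35]. The
untreated fasting level is an affine map of the admission draw
(4.0 + 0.55 · BG_adm, keeping every eligible patient above the 7.8
target), and each meal's untreated postprandial level adds a log-normal
excursion (median 3.5 mmol/L). Between-patient insulin sensitivity is
log-normal; `s_basal` (median 20 mmol/L per U/kg, log-SD 0.25), `s_bolus`
(median 45, log-SD 0.3) and `lag` (0.8 ± 0.1, truncated to [0.4, 1]) are
calibration constants chosen once so the median noise-free patient reaches
both targets in roughly 3–4 days under the 1:1.5 regimen — the clinically
observed timescale for this class of protocol. `noise_sd` defaults to
0.8 mmol/L, a modeling choice (no within-patient variability estimate was
available to fit).

All randomness flows from one seed: cohort sampling and arm assignment use
dedicated substreams, and each patient's measurement noise uses a
substream derived from the seed plus a CRC-32 hash of the patient id, so
cohorts and trials are bitwise-reproducible.

### What the generator does not emulate

Meal-composition effects, exercise, steroid use, renal/hepatic impairment,
counter-regulatory (Somogyi-type) responses, and physician overrides are
all absent. Because the dose–response is linear with a first-order lag,
basal escalation can overshoot its setpoint in highly sensitive patients,
which over-generates nocturnal hypoglycemia relative to real wards
(roughly 15–25% of simulated patients have at least one night reading
< 3.9 mmol/L under defaults). Passing tests therefore demonstrate the
correctness of the *algorithmic machinery* — initiation arithmetic,
titration decisions, endpoint extraction, statistics — not the clinical
fidelity of simulated event rates or days-to-target magnitudes.

## Trial simulation and endpoints

`run_trial` samples one cohort, assigns arms by a seeded permutation of
the fixed label vector (equivalent to 1:1 block randomization for equal
arms; explicit per-arm counts are honored exactly), and runs each patient
for up to `max_days` (default 10), stopping early once all four readings
have reached target and a full day passes without a dose change. Dropout
is off by default (a rate hook exists for CONSORT-style accounting).

Days-to-target is the first day, counted from day 2, with a reading
strictly below target; day-1 readings are peri-initiation baselines (the
first glargine is only injected at bedtime of day 1), so no endpoint can
be earlier than day 2. Patients never reaching a target are censored:
excluded from means and reported as separate counts, matching the
patient-count convention for non-reachers. Hypoglycemia is tabulated per
clock period and level with a patient-level denominator (a patient counts
once per period/level however many episodes they had).

## Statistics

Continuous endpoints: two-sided independent two-sample t-test, Student's
pooled-variance by default (the conventional reading of "independent
t-test"), Welch available; both accept raw samples or mean ± SD ± n
summaries. Proportions: 2×2 Pearson chi-square without continuity
correction (reported cell counts are ≥ 5); a zero margin returns p = 1
with a degenerate flag. Enrollment: total = ⌈2n / (1 − dropout)⌉, with a
1e-9 rounding guard so exact decimal quotients are not bumped by binary
float error. Censored values never enter means.

## Problem sizes in the test suite

The shipped suite runs the full trial at the analyzed arm sizes (89/93)
for calibration checks, 50 seeded replicates for the directional
between-arm comparison, a 100-configuration noise-free sweep against the
independent scalar oracle, and 1,000 randomized decision streams for the
non-negativity property — sizes chosen to make the checks statistically
meaningful while keeping the whole suite around half a minute.

## Known limitations

- mmol/L only; no mg/dL conversion.
- No correction ("sliding-scale supplement") boluses — deliberately absent
  from the algorithm being modeled.
- Only the glargine/aspart roles are modeled (no detemir/degludec/faster
  analogues).
- The a-priori power computation behind "86 per group" is out of scope
  (its effect-size inputs are external); only the dropout inflation step
  is implemented.
- Clinical outcome magnitudes (days-to-target means, final doses, event
  rates) produced by the simulator are properties of the synthetic model,
  not reproductions of patient data.
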