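"""Synthetic virtual T2D inpatients and their daily glucose responses.

No physiological model accompanies the dosing algorithm, so virtual
patients use a deliberately simple day-granular first-order response: each
of the four monitored readings (fasting and three 2-h postprandial) has a
latent level that relaxes toward a dose-determined setpoint at a fractional
rate ``lag`` per day,

    F_d = F_{d-1} + lag * (setpoint_d - F_{d-1}),

where the fasting setpoint is ``fbg_base - s_basal * basal`` (basal dose
injected the previous bedtime, units/kg) and each postprandial setpoint is
``ppg_base[meal] - s_bolus * bolus[meal] - c_spill * basal``.  Measured
readings add independent Gaussian noise and are floored at 1.0 mmol/L; the
03:00 reading sits ``nocturnal_dip`` below the fasting latent.

Baseline marginals (weight about 66 +/- 11 kg, admission glucose about
18.6 +/- 5.4 mmol/L, heights typical of a Chinese adult ward population)
match the trial population the simulator emulates.  Insulin sensitivities
are log-normal across patients; their medians are calibration constants
chosen so the median noise-free patient reaches both glycemic targets in
roughly 3-4 days under the 1:1.5 regimen (see the field defaults below).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .protocol import MEALS, GlucosePanel

#: Floor applied to every measured reading, mmol/L.
READING_FLOOR = 1.0


@dataclass(frozen=True)
class PatientProfile:
    """One virtual inpatient: anthropometrics plus glucose-response parameters.

    ``fbg_base`` / ``ppg_base`` are the untreated fasting and 2-h post-meal
    levels (mmol/L); ``s_basal`` and ``s_bolus`` the steady-state glucose
    drop per unit/kg of basal and bolus insulin; ``c_spill`` the basal
    dose's carryover onto postprandial readings; ``lag`` the fraction of the
    remaining gap to setpoint closed per day; ``noise_sd`` the within-day
    measurement noise; ``nocturnal_dip`` the expected fasting-to-03:00
    offset.
    """

    id: str
    weight: float
    height: float
    fbg_base: float
    ppg_base: Mapping[str, float]
    s_basal: float
    s_bolus: float
    c_spill: float
    lag: float
    noise_sd: float
    nocturnal_dip: float

    def __post_init__(self) -> None:
        if min(self.s_basal, self.s_bolus, self.c_spill) < 0:
            raise ValueError("sensitivities must be non-negative")
        if not 0 < self.lag <= 1:
            raise ValueError("lag must lie in (0, 1]")
        if self.noise_sd < 0 or self.nocturnal_dip < 0:
            raise ValueError("noise_sd and nocturnal_dip must be non-negative")
        if set(self.ppg_base) != set(MEALS):
            raise ValueError(f"ppg_base must cover exactly {MEALS}")


@dataclass(frozen=True)
class CohortConfig:
    """Distributional knobs for the virtual cohort.

    Means/SDs follow the emulated ward population; truncation bounds keep
    draws physiologic.  ``s_basal_median``/``s_bolus_median`` (mmol/L per
    unit/kg) and ``lag_mean`` are the calibration constants described in the
    module docstring.
    """

    n_per_arm: int | tuple[int, int] = 86
    seed: int = 0
    weight_mean: float = 66.0
    weight_sd: float = 11.0
    weight_bounds: tuple[float, float] = (40.0, 120.0)
    height_mean: float = 164.0
    height_sd: float = 8.0
    height_bounds: tuple[float, float] = (145.0, 190.0)
    admission_bg_mean: float = 18.6
    admission_bg_sd: float = 5.4
    admission_bg_bounds: tuple[float, float] = (10.0, 35.0)
    # untreated fasting level derived from the admission draw
    fbg_intercept: float = 4.0
    fbg_slope: float = 0.55
    # per-meal postprandial excursion above fasting, log-normal
    excursion_median: float = 3.5
    excursion_log_sd: float = 0.35
    s_basal_median: float = 20.0
    s_basal_log_sd: float = 0.25
    s_bolus_median: float = 45.0
    s_bolus_log_sd: float = 0.3
    c_spill_median: float = 4.0
    c_spill_log_sd: float = 0.4
    lag_mean: float = 0.8
    lag_sd: float = 0.1
    lag_bounds: tuple[float, float] = (0.4, 1.0)
    noise_sd: float = 0.8
    nocturnal_dip_mean: float = 0.6
    nocturnal_dip_sd: float = 0.2
    max_days: int = 10

    def __post_init__(self) -> None:
        n = self.n_per_arm if isinstance(self.n_per_arm, tuple) else (self.n_per_arm,)
        if any(v < 1 for v in n):
            raise ValueError("n_per_arm must be >= 1")
        for name in (
            "weight_sd", "height_sd", "admission_bg_sd", "excursion_log_sd",
            "s_basal_log_sd", "s_bolus_log_sd", "c_spill_log_sd", "lag_sd",
            "noise_sd", "nocturnal_dip_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    """Rejection-sample one draw; degenerate sd returns the clipped mean."""
    lo, hi = bounds
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def sample_patient(rng: np.random.Generator, config: CohortConfig, pid: str = "p0") -> PatientProfile:
    """Draw one virtual patient from the cohort distributions.

    Deterministic given the generator state; draws are consumed in a fixed
    order so cohorts are bitwise-reproducible by seed.
    """
    weight = _truncated_normal(rng, config.weight_mean, config.weight_sd, config.weight_bounds)
    height = _truncated_normal(rng, config.height_mean, config.height_sd, config.height_bounds)
    admission_bg = _truncated_normal(
        rng, config.admission_bg_mean, config.admission_bg_sd, config.admission_bg_bounds
    )
    fbg_base = config.fbg_intercept + config.fbg_slope * admission_bg
    ppg_base = {}
    for meal in MEALS:
        excursion = config.excursion_median * float(
            np.exp(rng.normal(0.0, config.excursion_log_sd))
        )
        ppg_base[meal] = max(fbg_base + excursion, 10.1)
    s_basal = config.s_basal_median * float(np.exp(rng.normal(0.0, config.s_basal_log_sd)))
    s_bolus = config.s_bolus_median * float(np.exp(rng.normal(0.0, config.s_bolus_log_sd)))
    c_spill = config.c_spill_median * float(np.exp(rng.normal(0.0, config.c_spill_log_sd)))
    lag = _truncated_normal(rng, config.lag_mean, config.lag_sd, config.lag_bounds)
    dip = max(0.0, rng.normal(config.nocturnal_dip_mean, config.nocturnal_dip_sd))
    return PatientProfile(
        id=pid,
        weight=weight,
        height=height,
        fbg_base=fbg_base,
        ppg_base=ppg_base,
        s_basal=s_basal,
        s_bolus=s_bolus,
        c_spill=c_spill,
        lag=lag,
        noise_sd=config.noise_sd,
        nocturnal_dip=float(dip),
    )


def patient_rng(seed: int, pid: str) -> np.random.Generator:
    """Per-patient substream: the cohort seed combined with a stable hash of the id."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(pid.encode())]))


@dataclass(frozen=True)
class LatentState:
    """Latent (noise-free) glucose levels carried from day to day."""

    day: int
    fasting: float
    postprandial: Mapping[str, float]


def initial_latent(profile: PatientProfile) -> LatentState:
    """Untreated latent levels before the first insulin dose."""
    return LatentState(day=0, fasting=profile.fbg_base, postprandial=dict(profile.ppg_base))


def _measure(latent_value: float, rng: np.random.Generator | None, noise_sd: float) -> float:
    noise = rng.normal(0.0, noise_sd) if (rng is not None and noise_sd > 0) else 0.0
    return max(READING_FLOOR, latent_value + noise)


def fasting_setpoint(profile: PatientProfile, basal_perkg: float) -> float:
    """Steady-state fasting level under a sustained basal dose (units/kg)."""
    return profile.fbg_base - profile.s_basal * basal_perkg


def meal_setpoint(
    profile: PatientProfile, meal: str, bolus_perkg: float, basal_perkg: float
) -> float:
    """Steady-state 2-h post-meal level under sustained bolus and basal doses."""
    return (
        profile.ppg_base[meal]
        - profile.s_bolus * bolus_perkg
        - profile.c_spill * basal_perkg
    )


def relax(value: float, setpoint: float, lag: float) -> float:
    """One day's first-order approach of a latent level toward its setpoint."""
    return value + lag * (setpoint - value)


def simulate_day_glucose(
    profile: PatientProfile,
    basal_perkg_prev_night: float,
    bolus_perkg_today: Mapping[str, float],
    latent: LatentState,
    rng: np.random.Generator | None = None,
) -> tuple[GlucosePanel, LatentState]:
    """Advance the latent model one day and emit the five-point panel.

    ``basal_perkg_prev_night`` is the glargine dose injected at the previous
    bedtime (0 before the first injection); ``bolus_perkg_today`` the aspart
    doses actually given before each of today's meals.  Passing ``rng=None``
    (or ``noise_sd == 0``) yields the noise-free panel used by the
    closed-form oracles.
    """
    if basal_perkg_prev_night < 0 or any(v < 0 for v in bolus_perkg_today.values()):
        raise ValueError("doses must be non-negative")
    day = latent.day + 1
    fasting = relax(
        latent.fasting,
        fasting_setpoint(profile, basal_perkg_prev_night),
        profile.lag,
    )
    post = {
        meal: relax(
            latent.postprandial[meal],
            meal_setpoint(profile, meal, bolus_perkg_today[meal], basal_perkg_prev_night),
            profile.lag,
        )
        for meal in MEALS
    }
    panel = GlucosePanel(
        day=day,
        fbg=_measure(fasting, rng, profile.noise_sd),
        ppg={m: _measure(post[m], rng, profile.noise_sd) for m in MEALS},
        bg_0300=_measure(fasting - profile.nocturnal_dip, rng, profile.noise_sd),
    )
    return panel, LatentState(day=day, fasting=fasting, postprandial=post)
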