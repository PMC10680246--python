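"""Standardized inpatient dietary prescription.

The ward diet is computed from ideal body weight (height in cm minus 105):
total energy at 25 kcal/kg/day for overweight or obese patients and
30 kcal/kg/day otherwise, protein at 1.0 g/kg ideal weight, fat at
0.8 g/kg ideal weight, the remaining energy as carbohydrate (Atwater
factors 4/9/4 kcal/g), and daily calories split 1:2:2 across breakfast,
lunch and dinner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

#: BMI (kg/m^2) at or above which the 25 kcal/kg coefficient applies.
#: Default follows the Chinese adult overweight criterion.
DEFAULT_OVERWEIGHT_BMI = 24.0

PROTEIN_KCAL_PER_G = 4.0
FAT_KCAL_PER_G = 9.0
CARB_KCAL_PER_G = 4.0


@dataclass(frozen=True)
class DietPrescription:
    """A patient's daily diet order.

    Energies in kcal/day, macronutrients in g/day; ``carb_fraction`` is the
    share of total energy supplied as carbohydrate.
    """

    ideal_weight: float
    total_energy: float
    protein: float
    fat: float
    carbohydrate: float
    meal_energy: Mapping[str, float]
    carb_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        macro_energy = (
            self.protein * PROTEIN_KCAL_PER_G
            + self.fat * FAT_KCAL_PER_G
            + self.carbohydrate * CARB_KCAL_PER_G
        )
        if abs(macro_energy - self.total_energy) > 1.0:
            raise ValueError("macronutrient energies do not add up to total energy")
        if abs(sum(self.meal_energy.values()) - self.total_energy) > 1.0:
            raise ValueError("meal energies do not add up to total energy")
        object.__setattr__(
            self,
            "carb_fraction",
            self.carbohydrate * CARB_KCAL_PER_G / self.total_energy,
        )


def ideal_body_weight(height: float) -> float:
    """Ideal body weight in kg: height (cm) minus 105."""
    if not 100 < height < 250:
        raise ValueError("height must lie in (100, 250) cm")
    ibw = height - 105.0
    if ibw <= 0:
        raise ValueError("height yields a non-positive ideal weight")
    return ibw


def energy_coefficient(bmi: float, overweight_bmi: float = DEFAULT_OVERWEIGHT_BMI) -> float:
    """Daily energy coefficient in kcal/kg ideal weight.

    25 for overweight or obese patients (BMI at or above ``overweight_bmi``),
    30 for normal weight or lean patients.
    """
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return 25.0 if bmi >= overweight_bmi else 30.0


def diet_prescription(
    height: float, weight: float, *, overweight_bmi: float = DEFAULT_OVERWEIGHT_BMI
) -> DietPrescription:
    """Compute the full diet order from anthropometrics.

    The 1:2:2 meal split gives breakfast one fifth of total energy
    (floor-rounded to a whole kcal); the remainder is split equally between
    lunch and dinner so the total is conserved.

    >>> rx = diet_prescription(170, 80)
    >>> rx.total_energy, rx.protein, rx.fat
    (1625.0, 65.0, 52.0)
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    ibw = ideal_body_weight(height)
    bmi = weight / (height / 100.0) ** 2
    energy = energy_coefficient(bmi, overweight_bmi) * ibw
    protein = 1.0 * ibw
    fat = 0.8 * ibw
    carb_energy = energy - protein * PROTEIN_KCAL_PER_G - fat * FAT_KCAL_PER_G
    if carb_energy < 0:
        raise ValueError(
            f"protein and fat alone exceed the energy budget ({energy:.0f} kcal)"
        )
    carbohydrate = carb_energy / CARB_KCAL_PER_G
    breakfast = float(math.floor(energy / 5.0))
    rest = energy - breakfast
    meal_energy = {"breakfast": breakfast, "lunch": rest / 2.0, "dinner": rest / 2.0}
    return DietPrescription(
        ideal_weight=ibw,
        total_energy=energy,
        protein=protein,
        fat=fat,
        carbohydrate=carbohydrate,
        meal_energy=meal_energy,
    )
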