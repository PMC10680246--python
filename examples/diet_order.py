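"""Standardized ward diet order for two body habitus.

Ideal weight is height (cm) - 105; energy is 25 kcal/kg for overweight
patients and 30 kcal/kg otherwise; protein 1.0 g/kg and fat 0.8 g/kg of
ideal weight, the rest as carbohydrate; meals split 1:2:2.
"""

from wit2 import diet_prescription

for height, weight in ((170, 80), (170, 60)):
    rx = diet_prescription(height, weight)
    bmi = weight / (height / 100) ** 2
    print(f"{height} cm, {weight} kg (BMI {bmi:.1f}):")
    print(f"  energy {rx.total_energy:.0f} kcal/day, protein {rx.protein:.0f} g, "
          f"fat {rx.fat:.0f} g, carbohydrate {rx.carbohydrate:.0f} g "
          f"({100 * rx.carb_fraction:.1f}% of energy)")
    print(f"  meals: " + ", ".join(f"{m} {kcal:.0f} kcal" for m, kcal in rx.meal_energy.items()))

print(
    "\nThe 80-kg patient is overweight (25 kcal/kg -> 1625 kcal); the 60-kg patient "
    "is normal weight (30 kcal/kg -> 1950 kcal)."
)
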