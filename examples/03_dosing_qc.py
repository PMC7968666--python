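"""Dosing precision and linearity across a 100-fold concentration range.

Simulates the five-concentration feeding experiment (30 mosquitoes each at
0.01-1 ug/ml) and reports per-concentration dosing CVs, raw and
weight-normalised, plus the amount-vs-concentration regression whose slope
estimates the mean imbibed blood volume in ul.
"""
from mozzipk import (dosing_linearity, dosing_precision,
                     implied_meal_volume_ul, simulate_linearity_experiment)

records = simulate_linearity_experiment(seed=7)
raw = dosing_precision(records, normalize_by_weight=False)
norm = dosing_precision(records, normalize_by_weight=True)

print("conc [ug/ml]   raw CV%   weight-normalised CV%")
for (_, r), (_, n) in zip(raw.per_concentration.iterrows(),
                          norm.per_concentration.iterrows()):
    print(f"   {r.conc_ug_ml:<12g}{r.cv_percent:7.1f}{n.cv_percent:17.1f}")

slope, intercept, r2_raw = dosing_linearity(records)
_, _, r2_norm = dosing_linearity(records, normalize_by_weight=True)
print(f"regression slope {slope:.2f} ul (mean imbibed volume), "
      f"R2 raw {r2_raw:.3f} / weight-normalised {r2_norm:.3f}")
mean_01 = raw.per_concentration.set_index("conc_ug_ml").loc[0.1, "mean"]
print(f"mean amount at 0.1 ug/ml: {mean_01:.3f} ng -> implied volume "
      f"{implied_meal_volume_ul(mean_01, 0.1):.2f} ul")
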