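"""From raw gas records to the two analysis traits: CH4 ppm/d and CH4 g/d.

Fits the per-farm Fourier diurnal model, corrects each record, averages per
cow per day inside the farm DIM windows, converts concentration to mass
output via predicted CO2 volume, and prints the between-farm comparison.
"""

import numpy as np

from ch4herd import phenotypes, simdata
from ch4herd.legendre_rr import LegendreBasis

ped = simdata.simulate_pedigree(60, 2, 60, 2, seed=1, n_sires_per_generation=8)
eff = simdata.simulate_true_effects(
    ped, None, np.diag([5856.0, 1200.0, 400.0]), np.diag([19664.0, 2000.0, 800.0]),
    seed=2,
)
records = simdata.simulate_records(
    ped, eff,
    schedule_spec=simdata.ScheduleSpec(n_days_per_cow=25, mean_visits_per_day=2.5),
    sigma_e=150.0, seed=3, basis=LegendreBasis(2, 5, 305),
)

models = phenotypes.fit_diurnal_fourier(records, n_harmonics=2)
for farm, m in models.items():
    amp1 = np.hypot(m.sin_coeff[0], m.cos_coeff[0])
    print(f"{farm}: diurnal 24h amplitude {amp1:.1f} ppm, intercept {m.intercept:.0f}")

corrected = phenotypes.correct_diurnal(records, models)
daily = phenotypes.daily_average(corrected)
print(f"\ndaily phenotypes: {len(daily)} cow-days")
print(daily[["ch4_ppm_d", "ch4_g_d"]].describe().loc[["mean", "std"]].round(1))

summary = phenotypes.cohort_summary(daily, "ch4_ppm_d")
print("\nper-farm summary (ppm/d):")
print(summary.round(1).to_string(index=False))
print(
    f"Bartlett p = {summary.attrs['bartlett_p']:.3g}, "
    f"Welch t = {summary.attrs['welch_t']:.2f} (p = {summary.attrs['welch_p']:.3g})"
)
# A CH4 g/d mean around 400-500 g/day and ppm/d near 500 matches the scale
# reported for in-parlour measurements on commercial Holstein herds.
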