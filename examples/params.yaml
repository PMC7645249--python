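# Global (non-country-specific) model parameters with their defaults.
# Every key is optional; omitted keys keep the default shown here.
readmission_cost: 1000.0        # EUR flat fee per DSWI readmission
readmission_los_days: null      # null -> use the country's DSWI extra LOS
prolonged_mv_fraction: 0.05     # share of ventilated patients with prolonged MV
daily_mortality: 0.0005         # per-day in-hospital death probability
icu_fraction_of_los: 0.20       # share of infection-free stay spent in ICU
mv_fraction_of_icu: 0.60        # ventilated share of post-surgery ICU time
dswi_extra_icu_fraction: 0.30   # ICU share of in-hospital DSWI extra days
sswi_extra_icu_fraction: 0.0    # ICU share of in-hospital SSWI extra days
hill_t50: 12.0                  # days to half-maximal cumulative incidence
hill_n: 2.0                     # Hill coefficient (curve steepness)
horizon_days: 365               # daily cycles (1 year)
extrapolate_incidence: true     # continue the curve beyond surveillance
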