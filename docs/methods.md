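# Methods

`swiburden` estimates the annual hospital-cost burden of sternal-wound
infections (SWIs) after coronary artery bypass graft (CABG) surgery for a
set of countries, from a hospital perspective: outputs are SWI-attributable
cost, intensive-care (ICU) and general-ward (GW) bed-days, and readmissions;
outpatient care is costed at zero.

## Care-pathway model

The core is a discrete-time Markov cohort model with a 1-day cycle and a
365-day horizon.  A unit cohort enters on the day of surgery and traverses

```
SURGERY -> ICU on MV [-> prolonged MV] -> ICU off MV -> GW -> out of hospital
```

On any day a patient who has not yet had an SWI may develop one
(superficial, SSWI, or deep, DSWI, split by the country's superficial
share) or die in hospital.  States and events:

- **In-hospital SWI** adds the country's extra length of stay for that
  infection type (inputs I9/I10), as a geometric extra-stay state.
- **Out-of-hospital DSWI** triggers a readmission: the country's DSWI
  extra-LOS in GW days plus a flat admission fee.
- **Out-of-hospital SSWI** is outpatient care at zero cost.
- **Death** is an absorbing state with a small uniform daily in-hospital
  probability; out of hospital it is zero.

Internally the state space is expanded (25 states) so that extra-stay
states remember the *paused* baseline phase: onset suspends the baseline
phase, the extra stay runs, and the patient resumes with the transition
decision of the paused phase.  Because sojourns are geometric (memoryless),
this leaves the expected infection-free stay unchanged and makes the
expected additional days equal the extra-LOS input exactly.  The daily
transition matrix is affine in the hazard, `M(d) = M0 + h(d) * M1`, with
`M0` row-stochastic and `M1` row-sum zero, so conservation holds by
construction; the trace asserts unit occupancy to 1e-9 over the year.

Day-counting convention: day *d*'s occupancy is the state at the start of
day *d* (day 1 is the surgery day); the day's boundary then applies
mortality, SWI onset with hazard *h(d)* (onset location = the ward
occupied that day), and the pathway transitions.

### Baseline vs SWI-attributable accrual

The infection-free ("baseline") component of the trace is computed from an
embedded companion run of the same calibrated chain with the SWI hazard
set to zero — i.e. the counterfactual cost of post-CABG care without an
infection, which is also the denominator of the reported relative cost
increase.  SWI-attributable accruals (extra-stay days at the configured
ICU/GW split, readmission days and fees) come from the joint run.  Total
cost is defined as baseline + SWI-attributable, so the decomposition is
exact by construction; the alternative (reading baseline days off the
joint run) would differ by terms of order mortality x extra stay.

## Cumulative incidence: Hill curve

Cumulative SWI incidence over time follows a saturating Hill curve
`CI(t) = i_max * t^n / (t50^n + t^n)`.  The shape `(t50, n)` is shared
across countries; defaults `t50 = 12` days, `n = 2` front-load incidence
in the first post-operative weeks with a plateau well before 90 days.
The height `i_max` is calibrated per country in closed form so the curve
passes through the observed incidence at the country's surveillance day
(clamped to 1 with a warning if the observation cannot be reached).  The
curve is embedded into daily conditional hazards
`h(d) = (CI(d) - CI(d-1)) / (1 - CI(d-1))`; the survival product of the
schedule reproduces the curve to 1e-12.  By default the curve continues
toward its asymptote beyond the surveillance window
(`extrapolate_incidence: true`); setting it false freezes the curve at the
surveillance-day value, for users who prefer not to extrapolate beyond the
observation window.

## Sojourn calibration

Per-state exit probabilities are geometric with mean = target days.  The
ICU target is `icu_fraction_of_los * mean_los` (the surgery day counts as
an ICU day), split 60/40 between ventilated and non-ventilated time; the
GW takes the remainder, so the chain's expected infection-free stay equals
the country's mean LOS exactly (verified against the absorbing-chain
closed form `(I - Q)^-1`).  Stage targets below one day are represented by
probabilistic stage entry (enter with probability = target, stay one day),
which preserves expected days for short stays.  A prolonged-MV episode is
entered with probability `prolonged_mv_fraction`; per-stage means are
deflated so cohort-average ICU time still meets the target.

## Parameters

Country inputs (per row of `countries.csv`): population, CABG rate per
100k/year, mean LOS (days), ICU and GW day costs (EUR-2017), SWI
incidence, surveillance days, superficial share, SSWI and DSWI extra LOS
(days).  Global defaults (all overridable in `params.yaml`, all resampled
by the PSA):

| parameter | default | meaning |
|---|---|---|
| `icu_fraction_of_los` | 0.20 | ICU share of infection-free stay |
| `mv_fraction_of_icu` | 0.60 | ventilated share of post-surgery ICU time |
| `prolonged_mv_fraction` | 0.05 | patients with a prolonged-MV episode |
| `daily_mortality` | 0.0005 | in-hospital death probability per day |
| `dswi_extra_icu_fraction` | 0.30 | ICU share of in-hospital DSWI extra days |
| `sswi_extra_icu_fraction` | 0.0 | ICU share of in-hospital SSWI extra days |
| `readmission_cost` | EUR 1,000 | flat fee per DSWI readmission |
| `readmission_los_days` | country's DSWI extra LOS | GW days per readmission |
| `hill_t50`, `hill_n` | 12 d, 2 | incidence-curve shape |

The pathway split constants and mortality are declared assumptions: the
published analyses this model family descends from do not print them, and
burden outputs are insensitive to them at these magnitudes (they shift
the ICU/GW composition of baseline care, not the SWI-attributable extra
days).  The readmission policy is a deliberate design choice: the
additional stay a deep infection causes is taken to be the same whether
onset happens before or after discharge, so a readmission consumes the
country's DSWI extra-LOS input in GW days; the flat fee covers admission
overhead on top of bed-day costs.  This choice is what lets the model
reproduce the published single-hospital validation (see below), where the
reported additional days equal the realised DSWI count times the DSWI
extra stay.

## Country data handling

A country is included when at least 5 of its 10 inputs are observed.
Missing inputs of included countries are filled with the median of the
observed values (midpoint convention for even counts); the imputation
report records the median and IQR used per filled cell.  Medians are
computed over included countries by default; a `reference` dataset can
widen this to all countries with data.  Raw local-currency costs can be
converted at publication-year average rates and inflated to 2017 via an
adjustment table (conversion first, then inflation).  Every cell carries a
provenance flag (`known` / `imputed` / `sampled` / `missing`) that
downstream stages consult.

## Probabilistic sensitivity analysis

Per run, every country input is redrawn: a uniform proposal between the
min and max of the observed values of that input across countries; a
country with its own observed value uses the mean of value and proposal
(sample in `[(known+lo)/2, (known+hi)/2]`), otherwise the proposal itself
(`[lo, hi]`).  The uniform proposal is the minimal-assumption reading of
"drawn between the bounds".  Global scalars are drawn from
`Normal(base, cv * base)` truncated to their domain by rejection, default
`cv = 0.10` (the source analyses state a normal distribution without a
spread).  Default 44 runs per country (44 sampled parameters in the
original analysis; with 26 countries this gives 1,144 evaluations).
Summaries are median/min/max per country and Europe-wide (per-run
cross-country sums, aligned by run index).  One master seed drives
per-(country, run) `SeedSequence` child streams, so results are
order-independent and exactly reproducible.

## Microsimulation oracle

`simulate_patients` applies the same daily rules per individual patient —
sampling rather than propagating expectations, with branching written
from the calibrated parameters instead of the cohort model's matrices.
Cohort outputs are required to match microsimulation means within 3
standard errors on all burden outputs (5 random parameter sets of 200,000
patients in the acceptance suite).

## Synthetic data

The generator draws country tables uniformly from documented plausible
ranges — SWI incidence 1.6–10.4%, deep share 23.3–76%, surveillance in
{30, 60, 90, 180} days — with synthetic-only cost (ICU 500–3,000, GW
200–1,200 EUR/day) and volume ranges, and controllable per-input
missingness.  It reproduces the *statistical structure* the pipeline
assumes (ranges, missingness, schema), not real-world correlations
between inputs (e.g. richer countries having both higher costs and lower
incidence), so passing tests demonstrate correctness of the machinery,
not calibration to any real country.

## Validation anchor

The single-hospital fixture (`jena_fixture`) encodes a published German
university-hospital cohort: 983 CABG patients, 126 SWIs over 60 days of
surveillance (96 superficial), superficial infections adding no stay,
deep ones 37 days, ward day cost EUR 1,010, mean stay 14.4 days.  Run at
base-case defaults (with the fixture's override costing all extra days at
the ward rate), the model estimates EUR ~8,860 per SWI and ~1,130
additional hospital days for the cohort, against the published model
estimates of EUR 7,860 and 1,178 days — agreement within 15%, the
tolerance used for this validation.

## Numerical choices and limitations

- Cycle length 1 day; horizon 365 cycles; float64 throughout.
- Conservation asserted to 1e-9; calibration round-trips to 1e-10;
  hazard/curve duality to 1e-12.
- Geometric sojourns cannot represent stays under one day except via
  probabilistic entry; extra stays in (0, 1) days round up to one day.
- Hazard saturation (`CI -> 1`) sets subsequent hazards to zero.
- Problem sizes in the test suite (200k-patient microsimulations, 1,144
  PSA evaluations, 1,000-triple calibration sweeps) were chosen to keep
  Monte-Carlo error well below the tolerances being asserted while the
  whole suite runs in well under a minute of model time.
- Not modelled: QALYs or cost-effectiveness ratios, patient-level risk
  factors (age, diabetes), inter-hospital variation, non-SWI adverse
  events, multi-year horizons.
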