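# swiburden

Hospital-cost burden of sternal-wound infections (SWIs) after coronary
artery bypass graft (CABG) surgery, estimated per country and aggregated
across countries.

Sternal-wound infections — superficial (SSWI) or deep (DSWI, including
mediastinitis) — are among the most serious complications of CABG.  From a
hospital's perspective their burden is extra bed-days and readmissions:
this package models a standardized post-CABG care pathway as a daily-cycle
Markov cohort model (surgery → ICU on mechanical ventilation → ICU off
ventilation → general ward → discharge, with death possible from any
state) and layers SWI onset on top of it.  Cumulative SWI incidence over
time follows a Hill curve

    CI(t) = i_max · tⁿ / (t50ⁿ + tⁿ)

whose height `i_max` is calibrated per country so the curve passes through
that country's observed incidence at its surveillance day, while the
shape (t50, n) is shared.  In-hospital infections add the country's extra
length of stay, out-of-hospital deep infections trigger readmission, and
outpatient care is free (hospital perspective).  Per country the model
reports SWI-attributable cost, extra ICU and general-ward days,
readmissions, cost per SWI, and the relative increase over infection-free
post-CABG care; a probabilistic sensitivity analysis (PSA) resamples all
inputs to put ranges on those outputs.

Intended users: health-economics and infection-control analysts who need
country-level burden estimates from sparse published inputs (the package
includes the ≥5-of-10 inclusion rule and cross-country median imputation
such analyses rely on), and methodologists who want a tested reference
implementation with an independent microsimulation oracle.

See `docs/methods.md` for the full model description and assumptions.

## Worked example

Generate a synthetic 8-country input table (with 20% missing cells), run
the base case, then the PSA:

```
$ swiburden synth --out countries.csv --n-countries 8 --missingness 0.2 --seed 42
wrote 8 countries to countries.csv

$ swiburden run --countries countries.csv --out base
8 countries analysed, 0 excluded; reports in base

$ swiburden psa --countries countries.csv --out psa --seed 42
352 PSA runs; reports in psa
```

`base/results.csv` holds one row per country; the first synthetic country
reads (abridged):

```
country_id  n_cabg   total_swi_cost  extra_icu_days  extra_gw_days  n_readmissions  cost_per_swi  relative_increase
SYN01       58405    27477242        4292            49004          1085            9673          0.081
```

i.e. with ~58,405 CABG procedures/year and a 4.9% SWI incidence, SWIs
cost this synthetic country €27.5M per year (4,292 extra ICU days, 49,004
extra ward days, 1,085 readmissions), €9,673 per infection — an 8.1%
increase over infection-free post-CABG care.  `base/summary.json`
aggregates the 8 countries: total €127.3M, 18,379 ICU days, 179,552 GW
days, 4,768 readmissions, median relative increase 4.1%.  The PSA summary
(`psa/psa_summary.json`, 44 runs per country) brackets the total cost at
median €116.0M, range €92.5M–€158.7M.

The same pipeline is available as a library:

```python
from swiburden import (GlobalParams, PSAConfig, compute_burden,
                       impute_missing, load_country_table, run_cohort,
                       run_psa, select_included_countries)

dataset = load_country_table("countries.csv")
included, excluded = select_included_countries(dataset)   # >=5 of 10 inputs
imputed = impute_missing(included)                        # cross-country medians
gp = GlobalParams()
results = [compute_burden(run_cohort(rec, gp), rec) for rec in imputed]
```

Example configuration files live in `examples/` (`params.yaml` for the
global constants, `adjustments.yaml` for currency conversion and
inflation to EUR-2017).

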