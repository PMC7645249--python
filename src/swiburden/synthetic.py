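"""Synthetic country input tables and a published single-hospital fixture.

The generator emulates the kind of multi-country input table the burden
analysis consumes: up to a few dozen countries with ten inputs each, drawn
from ranges documented for European CABG settings (overall SWI incidence
between 1.6% and 10.4%, deep-infection share between 23.3% and 76%,
surveillance windows of 30–180 days), with controllable per-input
missingness so the inclusion rule and median imputation are exercised.
Cost and volume ranges are synthetic-only plausible magnitudes; no attempt
is made to reproduce any specific country's values.

``jena_fixture`` returns the single-hospital parameterisation reported for
a German university hospital (983 CABG patients, 126 SWIs over 60 days of
surveillance of which 96 superficial; superficial infections added no
stay, deep ones 37 days; ward day cost EUR 1,010), used to validate model
outputs against a published cost study.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from pydantic import BaseModel, Field

from .country_data import INPUT_FIELDS, CountryDataset, CountryInputRecord

__all__ = ["SyntheticSpec", "generate_country_table", "jena_fixture",
           "JENA_COHORT_SIZE", "DEFAULT_RANGES", "SURVEILLANCE_CHOICES"]

#: Uniform sampling ranges per input (synthetic-only plausible magnitudes;
#: incidence, deep share and surveillance anchored to reported European
#: ranges).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "population": (3.0e5, 8.5e7),        # Malta/Iceland .. Germany/Turkey
    "cabg_rate_per_100k": (20.0, 100.0),
    "mean_los_days": (7.0, 16.0),
    "icu_day_cost": (500.0, 3000.0),     # EUR-2017/day, synthetic
    "gw_day_cost": (200.0, 1200.0),      # EUR-2017/day, synthetic
    "swi_incidence": (0.016, 0.104),     # 1.6% .. 10.4%
    "sswi_share": (0.24, 0.767),         # deep share 23.3% .. 76%
    "sswi_extra_los_days": (0.0, 10.0),
    "dswi_extra_los_days": (14.0, 40.0),
}

#: Surveillance windows in common use (days).
SURVEILLANCE_CHOICES = (30.0, 60.0, 90.0, 180.0)


class SyntheticSpec(BaseModel):
    """Specification of a synthetic country table."""

    n_countries: int = Field(default=26, ge=1)
    #: scalar missing probability applied to every input, or a per-input map
    missingness: float | dict[str, float] = 0.0
    seed: int = 0
    range_overrides: dict[str, tuple[float, float]] = Field(default_factory=dict)

    def missing_prob(self, name: str) -> float:
        if isinstance(self.missingness, Mapping):
            p = float(self.missingness.get(name, 0.0))
        else:
            p = float(self.missingness)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"missing probability for {name} not in [0,1]: {p}")
        return p


def generate_country_table(spec: SyntheticSpec) -> CountryDataset:
    """Draw a reproducible synthetic country input table."""
    rng = np.random.default_rng(spec.seed)
    ranges = {**DEFAULT_RANGES, **spec.range_overrides}
    records = []
    for i in range(spec.n_countries):
        cid = f"SYN{i + 1:02d}"
        values: dict[str, float | None] = {}
        for name in INPUT_FIELDS:
            if name == "surveillance_days":
                value = float(rng.choice(SURVEILLANCE_CHOICES))
            else:
                lo, hi = ranges[name]
                value = float(rng.uniform(lo, hi))
            if rng.random() < spec.missing_prob(name):
                values[name] = None
            else:
                values[name] = value
        records.append(CountryInputRecord(country_id=cid, **values))
    return CountryDataset(records=records)


#: Patients in the published single-hospital validation cohort.
JENA_COHORT_SIZE = 983


def jena_fixture() -> tuple[CountryInputRecord, dict]:
    """Single-hospital validation inputs plus global-parameter overrides.

    The record encodes the published hospital cohort: incidence 126/983
    over 60 days, superficial share 96/126, superficial extra stay 0 days,
    deep extra stay 37 days, mean stay 14.4 days, ward day cost EUR 1,010.
    The ICU day cost is set to the ward rate as well (the study prices all
    bed-days at the cardiac-ward rate), and the override pins
    ``dswi_extra_icu_fraction`` to 0 accordingly.  Population and CABG rate
    are set so the annual volume equals the 983-patient cohort.
    """
    record = CountryInputRecord(
        country_id="JENA",
        population=float(JENA_COHORT_SIZE),
        cabg_rate_per_100k=100_000.0,  # volume = population = cohort size
        mean_los_days=14.4,
        icu_day_cost=1010.0,
        gw_day_cost=1010.0,
        swi_incidence=126.0 / 983.0,
        surveillance_days=60.0,
        sswi_share=96.0 / 126.0,
        sswi_extra_los_days=0.0,
        dswi_extra_los_days=37.0,
    )
    overrides = {"dswi_extra_icu_fraction": 0.0}
    return record, overrides
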