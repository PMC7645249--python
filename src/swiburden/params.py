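"""Non-country-specific model constants.

All parameters that the multi-country burden model holds fixed across
countries live here.  They cover the care-pathway geometry (how the
infection-free stay is split between intensive care and the general ward),
the shape of the cumulative-incidence curve, the readmission policy for
out-of-hospital deep infections, and in-hospital mortality.  Every scalar
has a documented default and can be overridden from a YAML file; the PSA
engine resamples the scalars listed in :data:`PSA_SAMPLED_FIELDS`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["GlobalParams", "PSA_SAMPLED_FIELDS", "load_params"]


class GlobalParams(BaseModel):
    """Universal (non-country-specific) inputs of the burden model.

    Durations are in days, costs in EUR (2017 price level), probabilities
    per daily cycle.
    """

    #: Flat administrative/procedure fee charged once per DSWI readmission,
    #: on top of the readmission bed-days which are costed at the ward rate.
    readmission_cost: float = Field(default=1000.0, ge=0)

    #: General-ward days consumed by a DSWI readmission.  ``None`` (default)
    #: uses the country's DSWI extra length of stay (input I10): the
    #: additional stay a deep infection causes is taken to be the same
    #: whether onset happens before or after discharge.
    readmission_los_days: Optional[float] = Field(default=None, gt=0)

    #: Fraction of ventilated ICU patients who pass through a prolonged-MV
    #: episode (doubling their expected ventilated time).
    prolonged_mv_fraction: float = Field(default=0.05, ge=0, le=1)

    #: Daily probability of death while in any hospital state (including
    #: SWI treatment and readmission states); out of hospital it is zero.
    daily_mortality: float = Field(default=0.0005, ge=0, le=0.1)

    #: Share of the infection-free stay spent in intensive care (the day of
    #: surgery is counted as an ICU day).
    icu_fraction_of_los: float = Field(default=0.20, gt=0, lt=0.9)

    #: Within the post-surgery ICU time, share spent on mechanical
    #: ventilation (the rest is ICU without MV).
    mv_fraction_of_icu: float = Field(default=0.60, ge=0, le=1)

    #: Share of in-hospital DSWI extra days spent in the ICU (rest in GW).
    dswi_extra_icu_fraction: float = Field(default=0.30, ge=0, le=1)

    #: Share of in-hospital SSWI extra days spent in the ICU.
    sswi_extra_icu_fraction: float = Field(default=0.0, ge=0, le=1)

    #: Days to half-maximal cumulative SWI incidence (Hill curve midpoint).
    hill_t50: float = Field(default=12.0, gt=0)

    #: Hill coefficient; >1 gives a sigmoid front-loaded in the first
    #: post-operative weeks, plateauing well before 90 days.
    hill_n: float = Field(default=2.0, gt=0, le=10)

    #: Model horizon in daily cycles (1 year in the base case).
    horizon_days: int = Field(default=365, ge=1)

    #: If true the incidence curve continues toward its asymptote beyond the
    #: surveillance window; if false it is capped at the surveillance-day
    #: value.
    extrapolate_incidence: bool = True

    model_config = {"validate_assignment": True}

    @model_validator(mode="after")
    def _check(self) -> "GlobalParams":
        if self.icu_fraction_of_los >= 1.0:
            raise ValueError("icu_fraction_of_los must be < 1")
        return self

    def replace(self, **overrides) -> "GlobalParams":
        """Return a copy with ``overrides`` applied (validated)."""
        data = self.model_dump()
        data.update(overrides)
        return GlobalParams(**data)


#: GlobalParams scalars resampled by the PSA, with their admissible domain.
#: Domain is (low, high); draws outside are rejected and redrawn.
PSA_SAMPLED_FIELDS: dict[str, tuple[float, float]] = {
    "readmission_cost": (0.0, float("inf")),
    "prolonged_mv_fraction": (0.0, 1.0),
    "daily_mortality": (0.0, 0.1),
    "icu_fraction_of_los": (1e-6, 0.9 - 1e-9),
    "mv_fraction_of_icu": (0.0, 1.0),
    "dswi_extra_icu_fraction": (0.0, 1.0),
    "sswi_extra_icu_fraction": (0.0, 1.0),
    "hill_t50": (1e-6, float("inf")),
    "hill_n": (1e-6, 10.0),
}


def load_params(path: str | Path | None = None, **overrides) -> GlobalParams:
    """Load :class:`GlobalParams` from a YAML file, defaults for absent keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"params file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    return GlobalParams(**data)
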