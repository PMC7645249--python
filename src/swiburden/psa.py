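"""Probabilistic sensitivity analysis by bounded input resampling.

Each PSA run re-evaluates the cohort model with a fresh input set.  For a
country input the proposal is drawn uniformly between the minimum and
maximum of the values actually observed for that input across countries;
where the country had its own observed value the run uses the mean of the
observed value and the draw (halving the perturbation for well-documented
countries), otherwise the draw itself.  Non-country-specific global
parameters are drawn from a normal distribution centred on their base
value, truncated to their admissible domain.  The default of 44 runs per
country reproduces the scale of the original analysis (44 sampled
parameters, 44 runs each).

Randomness flows from one master seed through per-(country, run) child
streams (``numpy`` ``SeedSequence`` spawn keys), so results do not depend
on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .country_data import (
    INPUT_FIELDS,
    CountryDataError,
    CountryDataset,
    CountryInputRecord,
    Provenance,
)
from .params import PSA_SAMPLED_FIELDS, GlobalParams
from .pathway import compute_burden, run_cohort

__all__ = [
    "SamplingBounds",
    "PSAConfig",
    "PSASummary",
    "compute_bounds",
    "sample_country_inputs",
    "sample_global_params",
    "run_psa",
]

#: Burden outputs summarised by the PSA.
PSA_OUTPUTS = ("total_swi_cost", "extra_icu_days", "extra_gw_days", "n_readmissions")


@dataclass(frozen=True)
class SamplingBounds:
    """Per-input sampling interval: min/max of observed (known) values."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.lower:
            if self.lower[name] > self.upper[name]:
                raise ValueError(
                    f"bounds for {name!r} inverted: "
                    f"[{self.lower[name]}, {self.upper[name]}]"
                )


def compute_bounds(dataset: CountryDataset) -> SamplingBounds:
    """Min/max of known (not imputed or sampled) values per input.

    Each input must be observed for at least two countries, otherwise the
    sampling interval is not meaningful.
    """
    lower, upper = {}, {}
    for name in INPUT_FIELDS:
        known = dataset.known_values(name)
        if known.size < 2:
            raise CountryDataError(
                f"cannot bound input {name!r}: known for {known.size} "
                "countr(y/ies), need >= 2"
            )
        lower[name] = float(known.min())
        upper[name] = float(known.max())
    return SamplingBounds(lower=lower, upper=upper)


class PSAConfig(BaseModel):
    """PSA run configuration."""

    runs_per_country: int = Field(default=44, ge=1)
    seed: int = Field(default=20170)
    global_param_cv: float = Field(default=0.10, ge=0)


def sample_country_inputs(
    record: CountryInputRecord,
    bounds: SamplingBounds,
    rng: np.random.Generator,
) -> CountryInputRecord:
    """Resample one country's inputs for a PSA run.

    Fields without an observed value (missing or median-imputed) take the
    uniform draw from the cross-country bounds; fields with an observed
    value take the mean of that value and the draw, keeping the sample
    inside ``[(known + lo)/2, (known + hi)/2]``.  All fields are flagged
    ``sampled`` in the result.
    """
    out = record
    for name in INPUT_FIELDS:
        draw = rng.uniform(bounds.lower[name], bounds.upper[name])
        if record.provenance[name] is Provenance.KNOWN:
            value = 0.5 * (getattr(record, name) + draw)
        else:
            value = draw
        out = out.with_value(name, float(value), Provenance.SAMPLED)
    return out


def sample_global_params(
    gp: GlobalParams, cv: float, rng: np.random.Generator
) -> GlobalParams:
    """Normal resampling of every global scalar, truncated to its domain.

    Each scalar is drawn ``Normal(base, cv * base)``; draws outside the
    parameter's domain are rejected and redrawn (falling back to clipping
    after 1000 attempts).  ``cv = 0`` returns the input unchanged.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return gp
    overrides = {}
    for name, (lo, hi) in PSA_SAMPLED_FIELDS.items():
        base = getattr(gp, name)
        sd = cv * base
        if sd == 0:
            continue
        value = rng.normal(base, sd)
        tries = 0
        while not (lo <= value <= hi):
            value = rng.normal(base, sd)
            tries += 1
            if tries >= 1000:
                value = min(max(value, lo), hi)
                break
        overrides[name] = float(value)
    return gp.replace(**overrides)


@dataclass
class PSASummary:
    """Median/min/max of burden outputs across PSA runs.

    ``by_country`` is indexed by country_id with a (output, statistic)
    column MultiIndex; ``europe`` summarises the per-run cross-country
    sums.  ``runs`` (audit mode) holds every raw run, and
    ``sampled_inputs`` every sampled country input vector.
    """

    n_evaluations: int
    runs_per_country: int
    by_country: pd.DataFrame
    europe: dict[str, dict[str, float]]
    runs: Optional[pd.DataFrame] = None
    sampled_inputs: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "n_evaluations": self.n_evaluations,
            "runs_per_country": self.runs_per_country,
            "europe": self.europe,
            "by_country": {
                cid: {
                    output: {
                        stat: float(self.by_country.loc[cid, (output, stat)])
                        for stat in ("median", "min", "max")
                    }
                    for output in PSA_OUTPUTS
                }
                for cid in self.by_country.index
            },
        }


def run_psa(
    dataset: CountryDataset,
    gp: GlobalParams,
    config: PSAConfig,
    bounds: SamplingBounds | None = None,
    audit: bool = False,
) -> PSASummary:
    """Run the full PSA over an included-and-imputed dataset.

    ``bounds`` may be supplied to widen the sampling intervals to a larger
    reference dataset (e.g. all countries with any data); by default they
    come from the known values of ``dataset`` itself.  With ``audit`` the
    summary carries every raw run and sampled input vector.
    """
    if len(dataset) == 0:
        raise CountryDataError("PSA needs at least one included country")
    if bounds is None:
        bounds = compute_bounds(dataset)

    run_rows = []
    input_rows = []
    for ci, record in enumerate(dataset):
        if not record.is_complete:
            raise CountryDataError(
                f"{record.country_id}: impute before running the PSA"
            )
        for ri in range(config.runs_per_country):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(ci, ri)
            )
            rng = np.random.default_rng(ss)
            sampled = sample_country_inputs(record, bounds, rng)
            sampled_gp = sample_global_params(gp, config.global_param_cv, rng)
            trace = run_cohort(sampled, sampled_gp)
            burden = compute_burden(trace, sampled)
            run_rows.append(
                {
                    "country_id": record.country_id,
                    "run": ri,
                    **{k: getattr(burden, k) for k in PSA_OUTPUTS},
                }
            )
            if audit:
                input_rows.append(
                    {
                        "country_id": record.country_id,
                        "run": ri,
                        **{f: getattr(sampled, f) for f in INPUT_FIELDS},
                    }
                )

    runs = pd.DataFrame(run_rows)
    stats = runs.groupby("country_id")[list(PSA_OUTPUTS)].agg(
        ["median", "min", "max"]
    )
    europe_runs = runs.groupby("run")[list(PSA_OUTPUTS)].sum()
    europe = {
        output: {
            "median": float(europe_runs[output].median()),
            "min": float(europe_runs[output].min()),
            "max": float(europe_runs[output].max()),
        }
        for output in PSA_OUTPUTS
    }
    return PSASummary(
        n_evaluations=len(runs),
        runs_per_country=config.runs_per_country,
        by_country=stats,
        europe=europe,
        runs=runs if audit else None,
        sampled_inputs=pd.DataFrame(input_rows) if audit else None,
    )
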