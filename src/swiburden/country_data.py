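"""Country-level input handling: load, validate, adjust, include, impute.

The model consumes one row per country with ten inputs: population and CABG
rate (together giving procedures/year), mean CABG length of stay, ICU and
general-ward day costs (EUR, 2017 price level), overall SWI incidence, the
surveillance window over which that incidence was observed, the superficial
share of SWIs, and the extra length of stay attributable to a superficial
resp. deep infection.  Blank cells are missing data.  A country enters the
analysis when at least five of the ten inputs are known; remaining gaps are
filled with the median of the known values across included countries, and
every filled cell is flagged so downstream stages (notably the PSA) can
distinguish observed from interpolated data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "INPUT_FIELDS",
    "PROPORTION_FIELDS",
    "COST_FIELDS",
    "Provenance",
    "CountryDataError",
    "CountryInputRecord",
    "CountryDataset",
    "CostAdjustmentTable",
    "ExcludedCountry",
    "load_country_table",
    "write_country_table",
    "select_included_countries",
    "impute_missing",
]

#: The ten country-specific inputs, in canonical column order.
INPUT_FIELDS: tuple[str, ...] = (
    "population",
    "cabg_rate_per_100k",
    "mean_los_days",
    "icu_day_cost",
    "gw_day_cost",
    "swi_incidence",
    "surveillance_days",
    "sswi_share",
    "sswi_extra_los_days",
    "dswi_extra_los_days",
)

PROPORTION_FIELDS = frozenset({"swi_incidence", "sswi_share"})
COST_FIELDS = frozenset({"icu_day_cost", "gw_day_cost"})

#: Default threshold of the inclusion rule (known inputs out of ten).
MIN_KNOWN_FOR_INCLUSION = 5


class Provenance(str, enum.Enum):
    """Where a country-input value came from."""

    KNOWN = "known"        # observed in the source data
    IMPUTED = "imputed"    # filled with the cross-country median
    SAMPLED = "sampled"    # drawn by the PSA
    MISSING = "missing"    # no value


class CountryDataError(ValueError):
    """Validation failure naming the offending country and field."""


@dataclass
class CountryInputRecord:
    """One country's ten model inputs with per-field provenance."""

    country_id: str
    population: Optional[float] = None
    cabg_rate_per_100k: Optional[float] = None
    mean_los_days: Optional[float] = None
    icu_day_cost: Optional[float] = None
    gw_day_cost: Optional[float] = None
    swi_incidence: Optional[float] = None
    surveillance_days: Optional[float] = None
    sswi_share: Optional[float] = None
    sswi_extra_los_days: Optional[float] = None
    dswi_extra_los_days: Optional[float] = None
    provenance: dict[str, Provenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in INPUT_FIELDS:
            if name not in self.provenance:
                value = getattr(self, name)
                self.provenance[name] = (
                    Provenance.MISSING if value is None else Provenance.KNOWN
                )
        self.validate()

    def validate(self) -> None:
        for name in INPUT_FIELDS:
            value = getattr(self, name)
            if value is None:
                if self.provenance[name] is not Provenance.MISSING:
                    raise CountryDataError(
                        f"{self.country_id}.{name}: provenance "
                        f"{self.provenance[name].value} but value is missing"
                    )
                continue
            if not np.isfinite(value):
                raise CountryDataError(
                    f"{self.country_id}.{name}: non-finite value {value!r}"
                )
            if value < 0:
                raise CountryDataError(
                    f"{self.country_id}.{name}: negative value {value}"
                )
            if name in PROPORTION_FIELDS and value > 1:
                raise CountryDataError(
                    f"{self.country_id}.{name}: proportion {value} outside [0, 1]"
                )
            if name == "surveillance_days" and value < 1:
                raise CountryDataError(
                    f"{self.country_id}.{name}: surveillance must be >= 1 day, "
                    f"got {value}"
                )

    @property
    def n_known(self) -> int:
        """Number of fields observed in the source data (0..10)."""
        return sum(
            1 for f in INPUT_FIELDS if self.provenance[f] is Provenance.KNOWN
        )

    @property
    def is_complete(self) -> bool:
        """True when every field carries a value (known, imputed or sampled)."""
        return all(getattr(self, f) is not None for f in INPUT_FIELDS)

    def with_value(
        self, name: str, value: float, provenance: Provenance
    ) -> "CountryInputRecord":
        new_prov = dict(self.provenance)
        new_prov[name] = provenance
        return replace(self, **{name: value, "provenance": new_prov})


class ExcludedCountry(NamedTuple):
    country_id: str
    n_known: int


@dataclass
class CountryDataset:
    """A collection of country records plus the imputation audit trail."""

    records: list[CountryInputRecord]
    imputation_report: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = [r.country_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CountryDataError(f"duplicate country_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, country_id: str) -> CountryInputRecord:
        for rec in self.records:
            if rec.country_id == country_id:
                return rec
        raise KeyError(country_id)

    @property
    def country_ids(self) -> list[str]:
        return [r.country_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by country_id (NaN = missing)."""
        rows = {
            r.country_id: [
                np.nan if getattr(r, f) is None else getattr(r, f)
                for f in INPUT_FIELDS
            ]
            for r in self.records
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(INPUT_FIELDS)
        ).rename_axis("country_id")

    def provenance_frame(self) -> pd.DataFrame:
        rows = {
            r.country_id: [r.provenance[f].value for f in INPUT_FIELDS]
            for r in self.records
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(INPUT_FIELDS)
        ).rename_axis("country_id")

    def known_values(self, name: str) -> np.ndarray:
        """All values of one input whose provenance is KNOWN."""
        vals = [
            getattr(r, name)
            for r in self.records
            if r.provenance[name] is Provenance.KNOWN
        ]
        return np.asarray(vals, dtype=float)


@dataclass
class CostAdjustmentTable:
    """Currency conversion and inflation factors for cost inputs.

    ``currencies`` maps currency code -> {year: year-average EUR per unit};
    ``inflation`` maps country_id -> {year: inflation factor up to 2017};
    ``countries`` maps country_id -> {"currency": code, "cost_year": year}
    identifying how that country's raw cost inputs are denominated.
    Countries absent from ``countries`` are taken to be EUR-2017 already.
    """

    currencies: dict[str, dict[int, float]] = field(default_factory=dict)
    inflation: dict[str, dict[int, float]] = field(default_factory=dict)
    countries: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, by_year in self.currencies.items():
            for year, rate in by_year.items():
                if rate <= 0:
                    raise CountryDataError(
                        f"conversion rate {code}/{year} must be > 0, got {rate}"
                    )
        for cid, by_year in self.inflation.items():
            for year, factor in by_year.items():
                if factor <= 0:
                    raise CountryDataError(
                        f"inflation factor {cid}/{year} must be > 0, got {factor}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostAdjustmentTable":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            currencies={
                str(k): {int(y): float(v) for y, v in d.items()}
                for k, d in (data.get("currencies") or {}).items()
            },
            inflation={
                str(k): {int(y): float(v) for y, v in d.items()}
                for k, d in (data.get("inflation") or {}).items()
            },
            countries=dict(data.get("countries") or {}),
        )

    def factor(self, country_id: str) -> float:
        """Combined EUR-2017 factor for one country's raw cost inputs.

        Conversion at the publication-year average rate first, then
        inflation up to 2017.
        """
        entry = self.countries.get(country_id)
        if entry is None:
            return 1.0
        currency = entry.get("currency", "EUR")
        year = int(entry["cost_year"])
        rate = 1.0
        if currency != "EUR":
            try:
                rate = self.currencies[currency][year]
            except KeyError:
                raise CountryDataError(
                    f"{country_id}: no conversion rate for {currency}/{year}"
                ) from None
        infl = self.inflation.get(country_id, {}).get(year, 1.0)
        return rate * infl


def _parse_cell(raw: str, country_id: str, name: str, row_no: int) -> float | None:
    text = raw.strip() if isinstance(raw, str) else raw
    if text is None or text == "" or (isinstance(text, float) and np.isnan(text)):
        return None
    try:
        return float(text)
    except (TypeError, ValueError):
        raise CountryDataError(
            f"row {row_no} ({country_id}).{name}: cannot parse {raw!r} as a number"
        ) from None


def load_country_table(
    path: str | Path,
    adjustments: CostAdjustmentTable | None = None,
) -> CountryDataset:
    """Read a country input table from CSV.

    The file must have a header with ``country_id`` followed by the ten
    input columns (:data:`INPUT_FIELDS`); blank cells are missing values.
    With an adjustment table, raw local-currency cost columns are converted
    and inflated to EUR-2017 before storage.  A provenance sidecar written
    by :func:`write_country_table` is honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["country_id", *INPUT_FIELDS]
    if list(df.columns) != expected:
        raise CountryDataError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    sidecar = path.with_suffix(path.suffix + ".provenance.csv")
    prov_df = None
    if sidecar.exists():
        prov_df = pd.read_csv(sidecar, dtype=str).set_index("country_id")

    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        cid = (row.country_id or "").strip()
        if not cid:
            raise CountryDataError(f"row {row_no}: empty country_id")
        values: dict[str, float | None] = {}
        provenance: dict[str, Provenance] = {}
        for name in INPUT_FIELDS:
            value = _parse_cell(getattr(row, name), cid, name, row_no)
            if value is not None and adjustments is not None and name in COST_FIELDS:
                value *= adjustments.factor(cid)
            values[name] = value
            if prov_df is not None and cid in prov_df.index:
                provenance[name] = Provenance(prov_df.loc[cid, name])
            else:
                provenance[name] = (
                    Provenance.MISSING if value is None else Provenance.KNOWN
                )
        records.append(
            CountryInputRecord(country_id=cid, provenance=provenance, **values)
        )
    return CountryDataset(records=records)


def write_country_table(dataset: CountryDataset, path: str | Path) -> None:
    """Write a dataset as CSV plus a provenance sidecar for round-tripping."""
    path = Path(path)
    frame = dataset.to_frame().reset_index()
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.csv")
    dataset.provenance_frame().reset_index().to_csv(sidecar, index=False)


def select_included_countries(
    dataset: CountryDataset,
    min_known: int = MIN_KNOWN_FOR_INCLUSION,
) -> tuple[CountryDataset, list[ExcludedCountry]]:
    """Apply the >=5-of-10 known-inputs inclusion rule."""
    if len(dataset) == 0:
        raise CountryDataError("cannot select from an empty dataset")
    included, excluded = [], []
    for rec in dataset:
        if rec.n_known >= min_known:
            included.append(rec)
        else:
            excluded.append(ExcludedCountry(rec.country_id, rec.n_known))
    return CountryDataset(records=included), excluded


def impute_missing(
    included: CountryDataset,
    reference: CountryDataset | None = None,
) -> CountryDataset:
    """Fill missing inputs with the cross-country median of known values.

    Medians (and the IQR recorded in the report) are computed over the
    ``included`` dataset by default; pass ``reference`` to compute them over
    a wider set (e.g. all countries with any data).  Known values are never
    touched; the result carries an imputation report covering exactly the
    filled cells.  The operation is idempotent.
    """
    source = reference if reference is not None else included
    stats: dict[str, tuple[float, float, float]] = {}
    needed = {
        name
        for rec in included
        for name in INPUT_FIELDS
        if getattr(rec, name) is None
    }
    for name in needed:
        known = source.known_values(name)
        if known.size == 0:
            raise CountryDataError(
                f"cannot impute {name!r}: no country has a known value"
            )
        stats[name] = (
            float(np.median(known)),
            float(np.percentile(known, 25)),
            float(np.percentile(known, 75)),
        )

    new_records = []
    report_rows = []
    for rec in included:
        out = rec
        for name in INPUT_FIELDS:
            if getattr(rec, name) is None:
                median, q1, q3 = stats[name]
                out = out.with_value(name, median, Provenance.IMPUTED)
                report_rows.append(
                    {
                        "country_id": rec.country_id,
                        "field": name,
                        "imputed_value": median,
                        "median_used": median,
                        "iqr_low": q1,
                        "iqr_high": q3,
                    }
                )
        new_records.append(out)
    report = pd.DataFrame(
        report_rows,
        columns=[
            "country_id",
            "field",
            "imputed_value",
            "median_used",
            "iqr_low",
            "iqr_high",
        ],
    )
    return CountryDataset(records=new_records, imputation_report=report)
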