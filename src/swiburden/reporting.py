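"""Tabular and JSON report emission for base-case and PSA runs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .country_data import CountryDataset
from .pathway import BurdenResult, EuropeSummary
from .psa import PSASummary

__all__ = [
    "burden_results_frame",
    "write_base_case_reports",
    "write_psa_reports",
]


def burden_results_frame(results: Sequence[BurdenResult]) -> pd.DataFrame:
    """Per-country burden results as a DataFrame (one row per country)."""
    return pd.DataFrame([r.to_dict() for r in results])


def write_base_case_reports(
    out_dir: str | Path,
    results: Sequence[BurdenResult],
    summary: EuropeSummary,
    dataset: CountryDataset,
    log_lines: Sequence[str],
) -> dict[str, Path]:
    """Write results CSV, aggregate JSON, imputation report and run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.csv",
        "summary": out / "summary.json",
        "imputation": out / "imputation_report.csv",
        "log": out / "run.log",
    }
    burden_results_frame(results).to_csv(paths["results"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report = dataset.imputation_report
    if report is None:
        report = pd.DataFrame(
            columns=["country_id", "field", "imputed_value", "median_used",
                     "iqr_low", "iqr_high"]
        )
    report.to_csv(paths["imputation"], index=False)
    paths["log"].write_text("".join(line + "\n" for line in log_lines))
    return paths


def write_psa_reports(
    out_dir: str | Path,
    summary: PSASummary,
    log_lines: Sequence[str],
    dump_runs: bool = False,
) -> dict[str, Path]:
    """Write PSA summary JSON/CSV (and optionally raw runs) plus a log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "psa_summary.json",
        "by_country": out / "psa_by_country.csv",
        "log": out / "psa.log",
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    flat = summary.by_country.copy()
    flat.columns = [f"{output}_{stat}" for output, stat in flat.columns]
    flat.reset_index().to_csv(paths["by_country"], index=False)
    if dump_runs and summary.runs is not None:
        paths["runs"] = out / "psa_runs.csv"
        summary.runs.to_csv(paths["runs"], index=False)
    paths["log"].write_text("".join(line + "\n" for line in log_lines))
    return paths
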