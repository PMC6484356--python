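"""Reading, writing and summarizing the species-level MLE dataset.

One row per species or subspecies: common and scientific name, taxonomic
group, and — for each of the overall, male and female strata — the sample
size, median life expectancy in years, and lower/upper 95% confidence
limits, plus per-sex data-deficiency flags. Missing cells (a stratum that
could not be estimated) stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DatasetRow", "TAXON_GROUPS", "DATASET_COLUMNS",
           "read_dataset", "write_dataset", "rows_to_frame",
           "summarize_by_taxon"]

TAXON_GROUPS = ("Amphibia", "Arachnida", "Aves", "Chondrichthyes",
                "Mammalia", "Reptilia")

_STRATA = ("overall", "male", "female")
_NUMERIC = tuple(
    f"{stratum}_{quantity}" for stratum in _STRATA
    for quantity in ("sample_size", "mle", "lcl", "ucl"))
DATASET_COLUMNS = ("common_name", "scientific_name", "taxon_group",
                   *_NUMERIC, "male_data_deficient", "female_data_deficient")


@dataclass
class DatasetRow:
    """One species' entry in the MLE dataset; NaN marks a missing value."""

    common_name: str
    scientific_name: str
    taxon_group: str
    overall_sample_size: float = np.nan
    overall_mle: float = np.nan
    overall_lcl: float = np.nan
    overall_ucl: float = np.nan
    male_sample_size: float = np.nan
    male_mle: float = np.nan
    male_lcl: float = np.nan
    male_ucl: float = np.nan
    female_sample_size: float = np.nan
    female_mle: float = np.nan
    female_lcl: float = np.nan
    female_ucl: float = np.nan
    male_data_deficient: bool = False
    female_data_deficient: bool = False


def read_dataset(path: str | Path) -> list[DatasetRow]:
    """Parse a dataset file; malformed numeric cells raise with location."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset missing column(s): {', '.join(missing)}")
    rows: list[DatasetRow] = []
    for i, record in frame.iterrows():
        numbers = {}
        for column in _NUMERIC:
            cell = record[column].strip()
            if cell in ("", "NA"):
                numbers[column] = np.nan
                continue
            try:
                numbers[column] = float(cell)
            except ValueError:
                raise ValueError(
                    f"malformed numeric cell in row {i + 1}, column "
                    f"{column!r}: {cell!r}") from None
        rows.append(DatasetRow(
            common_name=record["common_name"],
            scientific_name=record["scientific_name"],
            taxon_group=record["taxon_group"],
            **numbers,
            male_data_deficient=record["male_data_deficient"].strip().lower()
            == "yes",
            female_data_deficient=record["female_data_deficient"].strip()
            .lower() == "yes",
        ))
    return rows


def rows_to_frame(rows: list[DatasetRow]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in rows], columns=DATASET_COLUMNS)
    return frame


def write_dataset(rows: list[DatasetRow], path: str | Path) -> None:
    """Write rows in the dataset schema; missing values become empty cells."""
    frame = rows_to_frame(rows).copy()
    for column in ("male_data_deficient", "female_data_deficient"):
        frame[column] = np.where(frame[column], "yes", "no")
    frame.to_csv(path, index=False, na_rep="")


def _taxon_of(row: DatasetRow) -> str:
    return row.taxon_group if row.taxon_group in TAXON_GROUPS else "other"


def summarize_by_taxon(rows: list[DatasetRow],
                       exclude_deficient: bool = True) -> pd.DataFrame:
    """Count, mean and sample SD of MLE per taxonomic group and stratum.

    Sex-specific values flagged data deficient are dropped when
    ``exclude_deficient`` is True (the recommended setting for formal
    summaries); the overall stratum carries no deficiency flag and always
    summarizes every non-missing value. SD uses the n-1 denominator and is
    missing for groups of fewer than two values.
    """
    frame = rows_to_frame(rows)
    frame["taxon_group"] = [_taxon_of(r) for r in rows]
    out = []
    for taxon, group in frame.groupby("taxon_group", sort=True):
        for stratum in _STRATA:
            values = group[f"{stratum}_mle"]
            if exclude_deficient and stratum != "overall":
                values = values[~group[f"{stratum}_data_deficient"]]
            values = values.dropna()
            out.append({
                "taxon_group": taxon,
                "stratum": stratum,
                "n": len(values),
                "mean_mle": values.mean() if len(values) else np.nan,
                "sd_mle": values.std(ddof=1) if len(values) > 1 else np.nan,
            })
    return pd.DataFrame(out, columns=["taxon_group", "stratum", "n",
                                      "mean_mle", "sd_mle"])
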