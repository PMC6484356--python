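"""Per-stratum survival analysis of one studbook population.

The overall stratum uses every usable exposure — males, females and
unknown-sex individuals alike — while the male and female strata use only
that sex. Sample size per stratum is the number of individuals whose
partial or full lifespans entered the risk sets.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .km import Exposure, fit_survival
from .median import MLEResult, QualityTests, estimate_mle
from .records import AnalysisWindow, IndividualRecord, compute_exposures

__all__ = ["analyze_population", "analyze_exposures", "write_report",
           "STRATA"]

STRATA = ("overall", "male", "female")


def _empty_result(stratum: str) -> MLEResult:
    return MLEResult(stratum=stratum, sample_size=0, n_start=0,
                     tests=QualityTests.all_failed())


def analyze_exposures(exposures: list[Exposure], stratum: str,
                      start_age: int = 365) -> MLEResult:
    """Estimate the stratum MLE; an empty stratum fails every test."""
    if not exposures:
        return _empty_result(stratum)
    curve, table = fit_survival(exposures, start_age=start_age)
    return estimate_mle(curve, table, stratum=stratum,
                        sample_size=len(exposures))


def analyze_population(records: list[IndividualRecord],
                       window: AnalysisWindow) -> dict[str, MLEResult]:
    """Overall, male and female MLE estimates from validated records.

    Raises ``ValueError("no usable individuals")`` when nothing at all is
    analyzable; an empty sex stratum still yields an (all-tests-failed)
    result as long as the overall analysis runs.
    """
    exposures = compute_exposures(records, window)
    if not exposures:
        raise ValueError("no usable individuals")
    results: dict[str, MLEResult] = {}
    for stratum in STRATA:
        subset = (exposures if stratum == "overall"
                  else [e for e in exposures if e.sex == stratum])
        results[stratum] = analyze_exposures(
            subset, stratum, start_age=window.start_age_days)
    return results


def _fmt_years(value: float | None) -> str:
    # 1 decimal in reports; full precision stays on the MLEResult
    return "" if value is None else f"{value:.1f}"


def write_report(results: dict[str, MLEResult], path: str | Path,
                 delimiter: str = ",") -> None:
    """Write the per-stratum survival-statistics report as delimited text."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow([
            "stratum", "sample_size", "n_start", "mle_years", "lcl_years",
            "ucl_years", "test_calculable", "test_first_class_n",
            "test_median_n", "test_ci_defined", "test_ci_precise",
            "data_deficient",
        ])
        for stratum in (s for s in STRATA if s in results):
            r = results[stratum]
            t = r.tests
            writer.writerow([
                r.stratum, r.sample_size, r.n_start,
                _fmt_years(r.mle_years), _fmt_years(r.lcl_years),
                _fmt_years(r.ucl_years),
                *(("pass" if flag else "fail") for flag in
                  (t.calculable, t.first_class_n, t.median_n,
                   t.ci_defined, t.ci_precise)),
                "yes" if r.data_deficient else "no",
            ])
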