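"""Median life expectancy, its 95% confidence limits, and quality gating.

The median life expectancy (MLE) is the age at which the estimated
survivorship crosses 0.5, conditional on surviving to the starting age
(365 days). Unless an estimate falls exactly on 0.5, it is found by linear
interpolation between the last death age with survivorship above 0.5,
``[x0, L0]``, and the first below, ``[x1, L1]``:

    MLE = x0 + (L0 - 0.5) (x1 - x0) / (L0 - L1)

The 95% confidence limits come from inverting the pointwise test of
``L(t) = 0.5`` on the complementary log-log scale:

    Z(t) = (ln[-ln L(t)] - ln[-ln 0.5]) * L(t) ln L(t) / sqrt(V(t))

The confidence set is the collection of death ages where ``|Z| < 1.96``;
its extremes are the limits, each reported only when the data actually
cross the +/-1.96 boundary on that side (otherwise the limit lies beyond
the observed ages and is undefined).

Five data-quality tests gate each estimate: the median must be calculable,
the first-age-class sample must exceed 30, more than 20 individuals must
remain at risk at the median, both confidence limits must be defined, and
the confidence interval must not exceed 33% of the observed maximum
longevity. Failing any test marks the stratum data deficient, though the
point estimate is still reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .km import EventTable, SurvivalCurve

__all__ = [
    "QualityTests", "MLEResult",
    "median_from_curve", "to_years", "z_statistic", "median_ci",
    "quality_tests", "estimate_mle",
]

DAYS_PER_YEAR = 365
Z_CRITICAL = 1.96
#: treat survivorship within this distance of 0.5 as an exact hit
EXACT_HALF_TOL = 1e-12


@dataclass(frozen=True)
class QualityTests:
    """Outcomes of the five data-quality tests (True = pass)."""

    calculable: bool      # 1: the median can be calculated at all
    first_class_n: bool   # 2: > 30 at risk in the first age class
    median_n: bool        # 3: > 20 at risk at the median
    ci_defined: bool      # 4: both 95% confidence limits defined
    ci_precise: bool      # 5: CI length <= 33% of maximum longevity

    def all_pass(self) -> bool:
        return (self.calculable and self.first_class_n and self.median_n
                and self.ci_defined and self.ci_precise)

    @classmethod
    def all_failed(cls) -> "QualityTests":
        return cls(False, False, False, False, False)


@dataclass
class MLEResult:
    """Median life expectancy for one stratum, with its quality gating.

    Ages are kept in days at full precision; the ``*_years`` properties
    divide by 365. ``None`` marks an undefined quantity (e.g. a curve that
    never reaches 0.5, or a confidence limit beyond the observed ages).
    ``data_deficient`` is True whenever any quality test fails; the point
    estimate is still carried so a value can be reported alongside the
    flag.
    """

    stratum: str
    sample_size: int
    n_start: int
    mle_days: float | None = None
    lcl_days: float | None = None
    ucl_days: float | None = None
    n_at_median: int | None = None
    max_longevity: int | None = None
    tests: QualityTests = QualityTests.all_failed()

    @property
    def mle_years(self) -> float | None:
        return to_years(self.mle_days)

    @property
    def lcl_years(self) -> float | None:
        return to_years(self.lcl_days)

    @property
    def ucl_years(self) -> float | None:
        return to_years(self.ucl_days)

    @property
    def data_deficient(self) -> bool:
        return not self.tests.all_pass()


def _death_indices(curve: SurvivalCurve,
                   table: EventTable | None) -> np.ndarray:
    if table is not None:
        return np.flatnonzero(table.deaths > 0)
    return np.flatnonzero(curve.death_mask)


def median_from_curve(curve: SurvivalCurve,
                      table: EventTable | None = None) -> float | None:
    """Age in days at which survivorship crosses 0.5, or None.

    If some estimate falls exactly on 0.5 the earliest age attaining it is
    returned; otherwise the interpolation anchors are the death ages
    bracketing 0.5 (censoring-only ages repeat the previous estimate and
    carry no information about the crossing). Returns None when the curve
    never drops to 0.5 or below.
    """
    deaths = _death_indices(curve, table)
    if len(deaths) == 0:
        return None
    ages = curve.ages[deaths].astype(float)
    surv = curve.survival[deaths]

    exact = np.flatnonzero(np.abs(surv - 0.5) <= EXACT_HALF_TOL)
    if len(exact):
        return float(ages[exact[0]])
    below = np.flatnonzero(surv < 0.5)
    if len(below) == 0:
        return None
    first_below = below[0]
    if first_below == 0:
        # the very first death drops below 0.5: the step crosses at that age
        return float(ages[0])
    x0, survival_above = ages[first_below - 1], surv[first_below - 1]
    x1, survival_below = ages[first_below], surv[first_below]
    return float(x0 + (survival_above - 0.5) * (x1 - x0)
                 / (survival_above - survival_below))


def to_years(age_days: float | None) -> float | None:
    """Convert an age in days to years (365-day years); None propagates."""
    if age_days is None:
        return None
    return age_days / DAYS_PER_YEAR


def z_statistic(curve: SurvivalCurve, index: int) -> float | None:
    """Complementary log-log test statistic of ``L = 0.5`` at one age.

    Undefined (None) when the estimate is 0 or 1 or the Greenwood variance
    is unavailable or zero there.
    """
    survival = float(curve.survival[index])
    variance = float(curve.variance[index])
    if not (0.0 < survival < 1.0):
        return None
    if not math.isfinite(variance) or variance <= 0.0:
        return None
    numerator = math.log(-math.log(survival)) - math.log(-math.log(0.5))
    return numerator * (survival * math.log(survival)) / math.sqrt(variance)


def median_ci(curve: SurvivalCurve,
              table: EventTable | None = None,
              ) -> tuple[float | None, float | None]:
    """95% confidence limits for the median by test inversion.

    Z is evaluated at death ages (where the estimate changes); the
    confidence set collects those with ``|Z| < 1.96`` and its extremes are
    the limits. A limit is reported only when some death age with a
    defined Z lies strictly outside the confidence set on that side —
    otherwise the boundary was never crossed within the observed data and
    the limit is undefined.
    """
    deaths = _death_indices(curve, table)
    z_values = [(i, z_statistic(curve, i)) for i in deaths]
    defined = [(i, z) for i, z in z_values if z is not None]
    if not defined:
        return None, None
    inside = [i for i, z in defined if abs(z) < Z_CRITICAL]
    if not inside:
        return None, None
    low, high = min(inside), max(inside)
    lcl = float(curve.ages[low]) if any(i < low for i, _ in defined) else None
    ucl = float(curve.ages[high]) if any(i > high for i, _ in defined) else None
    return lcl, ucl


def quality_tests(mle_days: float | None,
                  lcl_days: float | None,
                  ucl_days: float | None,
                  n_start: int,
                  n_at_median: int | None,
                  max_longevity: int) -> QualityTests:
    """Apply the five data-quality tests at their published thresholds.

    Thresholds are strict: a first-age-class sample of exactly 30 fails
    test 2, exactly 20 at the median fails test 3, and a CI longer than
    0.33 x maximum longevity fails test 5.
    """
    calculable = mle_days is not None
    first_class_n = n_start > 30
    median_n = n_at_median is not None and n_at_median > 20
    ci_defined = lcl_days is not None and ucl_days is not None
    ci_precise = (ci_defined
                  and (ucl_days - lcl_days) <= 0.33 * max_longevity)
    return QualityTests(calculable=calculable, first_class_n=first_class_n,
                        median_n=median_n, ci_defined=ci_defined,
                        ci_precise=ci_precise)


def n_at_risk_at_median(curve: SurvivalCurve, table: EventTable) -> int | None:
    """At-risk count at the median: at the exact-0.5 age when one exists,
    else at the first death age with survivorship below 0.5."""
    deaths = np.flatnonzero(table.deaths > 0)
    if len(deaths) == 0:
        return None
    surv = curve.survival[deaths]
    exact = np.flatnonzero(np.abs(surv - 0.5) <= EXACT_HALF_TOL)
    if len(exact):
        return int(table.at_risk[deaths[exact[0]]])
    below = np.flatnonzero(surv < 0.5)
    if len(below) == 0:
        return None
    return int(table.at_risk[deaths[below[0]]])


def estimate_mle(curve: SurvivalCurve, table: EventTable,
                 stratum: str = "overall",
                 sample_size: int | None = None) -> MLEResult:
    """Full per-stratum estimate: median, confidence limits, quality tests."""
    if sample_size is None:
        sample_size = int(table.deaths.sum() + table.censored.sum())
    mle = median_from_curve(curve, table)
    lcl, ucl = median_ci(curve, table)
    n_median = n_at_risk_at_median(curve, table)
    tests = quality_tests(mle, lcl, ucl, curve.n_start, n_median,
                          curve.max_longevity)
    return MLEResult(stratum=stratum, sample_size=sample_size,
                     n_start=curve.n_start, mle_days=mle,
                     lcl_days=lcl, ucl_days=ucl, n_at_median=n_median,
                     max_longevity=curve.max_longevity, tests=tests)
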