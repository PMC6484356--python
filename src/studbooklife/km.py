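"""Product-limit (Kaplan-Meier) survivorship with delayed entry.

The estimator handles the two observation patterns typical of studbook
data: right censoring (alive at the end of the analysis window) and left
truncation (entering observation at an age above the starting age). At
every age ``t`` at which some individual dies or is censored the number of
deaths ``d_t`` and the number at risk ``N_t`` are tallied and

    L(t) = prod_{t_i <= t} [1 - d_i / N_i]

over death ages, with survivorship fixed at 1.0 at the starting age.
Greenwood's formula gives the variance of the estimate:

    V(t) = L(t)^2 * sum_{t_i <= t} d_i / (N_i (N_i - d_i)).

Risk-set membership uses the half-open convention ``entry < t <= exit``:
an individual entering at age ``a`` is not at risk for an event at exactly
``a``, which is the standard guard against self-inclusion artifacts under
left truncation. Tied deaths and censorings at one age are resolved deaths
first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Exposure", "EventTable", "SurvivalCurve",
    "build_event_table", "km_curve", "greenwood_variance",
    "first_age_class_size", "fit_survival", "export_curve",
]


@dataclass(frozen=True)
class Exposure:
    """One individual's at-risk interval, in days of age.

    ``event`` is True when the death was observed at ``exit_age``; False
    means the individual was censored there (alive at the window's end, or
    its death fell outside the window).
    """

    individual_id: str
    sex: str
    entry_age: int
    exit_age: int
    event: bool

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise ValueError(
                f"exposure for {self.individual_id!r}: entry_age "
                f"{self.entry_age} must be < exit_age {self.exit_age}")


@dataclass
class EventTable:
    """Tallies at every distinct exit age: deaths, censorings, at-risk."""

    ages: np.ndarray       # strictly increasing integer days
    deaths: np.ndarray     # d_i >= 0
    censored: np.ndarray   # c_i >= 0
    at_risk: np.ndarray    # N_i >= d_i + c_i contributions at that age

    def __len__(self) -> int:
        return len(self.ages)


@dataclass
class SurvivalCurve:
    """Stepwise survivorship estimate with Greenwood variance.

    ``survival`` and ``variance`` are aligned with ``ages``; ``variance``
    is NaN from the first age at which everyone at risk died (the
    Greenwood term is undefined there). ``n_start`` is the largest at-risk
    count during the first one-year age class, recorded for the minimum
    sample-size quality test; ``max_longevity`` is the largest exit age
    observed, beyond which no estimate is made.
    """

    ages: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    start_age: int
    max_longevity: int
    n_start: int

    @property
    def death_mask(self) -> np.ndarray:
        """True at ages where survivorship steps down (d_i >= 1)."""
        steps = np.empty(len(self.ages), dtype=bool)
        prev = 1.0
        for i, value in enumerate(self.survival):
            steps[i] = value < prev
            prev = value
        return steps


def build_event_table(exposures: list[Exposure]) -> EventTable:
    """Tally deaths, censorings and risk sets at every exit age.

    Raises ``ValueError("no usable individuals")`` on an empty list.
    """
    if not exposures:
        raise ValueError("no usable individuals")
    entry = np.array([e.entry_age for e in exposures])
    exit_ = np.array([e.exit_age for e in exposures])
    event = np.array([e.event for e in exposures], dtype=bool)

    ages = np.unique(exit_)
    deaths = np.zeros(len(ages), dtype=int)
    censored = np.zeros(len(ages), dtype=int)
    idx = np.searchsorted(ages, exit_)
    np.add.at(deaths, idx[event], 1)
    np.add.at(censored, idx[~event], 1)

    # N(t) = #{entry < t} - #{exit < t}; exits at t are still at risk at t
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    at_risk = (np.searchsorted(entry_sorted, ages, side="left")
               - np.searchsorted(exit_sorted, ages, side="left"))
    return EventTable(ages=ages, deaths=deaths, censored=censored,
                      at_risk=at_risk)


def first_age_class_size(exposures: list[Exposure],
                         start_age: int = 365) -> int:
    """Largest at-risk count over the first one-year age class.

    The first age class is the interval ``[start_age, start_age + 365)``.
    Under the ``entry < t <= exit`` convention the risk set only grows just
    after an entry age, so the maximum is attained at some ``entry + 1``.
    """
    entry_sorted = np.sort([e.entry_age for e in exposures])
    exit_sorted = np.sort([e.exit_age for e in exposures])
    candidates = np.unique(entry_sorted) + 1
    candidates = candidates[(candidates > start_age)
                            & (candidates < start_age + 365)]
    if len(candidates) == 0:
        return 0
    n = (np.searchsorted(entry_sorted, candidates, side="left")
         - np.searchsorted(exit_sorted, candidates, side="left"))
    return int(n.max())


def km_curve(table: EventTable, start_age: int = 365,
             n_start: int | None = None) -> SurvivalCurve:
    """Product-limit survivorship over the event table's ages.

    Censoring-only ages leave the estimate unchanged but are retained in
    the curve. When ``n_start`` is not supplied (no access to the raw
    exposures) it falls back to the largest tabulated at-risk count in the
    first age class; prefer :func:`fit_survival`, which computes it from
    the exposures exactly.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - table.deaths / table.at_risk
    survival = np.cumprod(factors)
    if n_start is None:
        in_first = (table.ages >= start_age) & (table.ages < start_age + 365)
        n_start = int(table.at_risk[in_first].max()) if in_first.any() else (
            int(table.at_risk[0]) if len(table) else 0)
    curve = SurvivalCurve(
        ages=table.ages,
        survival=survival,
        variance=np.zeros_like(survival),
        start_age=start_age,
        max_longevity=int(table.ages[-1]),
        n_start=n_start,
    )
    curve.variance = greenwood_variance(curve, table)
    return curve


def greenwood_variance(curve: SurvivalCurve,
                       table: EventTable) -> np.ndarray:
    """Greenwood variance sequence aligned with the curve's ages.

    At an age where everyone at risk dies (``N_i == d_i``) the summand
    ``d_i / (N_i (N_i - d_i))`` is undefined; the variance is NaN from that
    age onward.
    """
    deaths = table.deaths.astype(float)
    denominator = table.at_risk * (table.at_risk - table.deaths)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(deaths > 0, deaths / denominator, 0.0)
    cumulative = np.cumsum(terms)
    with np.errstate(invalid="ignore"):
        variance = curve.survival ** 2 * cumulative
    undefined = ~np.isfinite(cumulative)
    variance[undefined] = np.nan
    return variance


def fit_survival(exposures: list[Exposure],
                 start_age: int = 365) -> tuple[SurvivalCurve, EventTable]:
    """Build the event table and fit the survivorship curve in one step."""
    table = build_event_table(exposures)
    n_start = first_age_class_size(exposures, start_age=start_age)
    return km_curve(table, start_age=start_age, n_start=n_start), table


def export_curve(curve: SurvivalCurve, table: EventTable, path,
                 delimiter: str = ",") -> None:
    """Write the curve as delimited text (one row per tabulated age)."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["age_days", "at_risk", "deaths", "censored",
                         "survival", "variance"])
        for i in range(len(table)):
            variance = curve.variance[i]
            writer.writerow([
                int(table.ages[i]), int(table.at_risk[i]),
                int(table.deaths[i]), int(table.censored[i]),
                f"{curve.survival[i]:.10g}",
                "NA" if np.isnan(variance) else f"{variance:.10g}",
            ])
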