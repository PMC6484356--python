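"""Studbook records: parsing, validation and exposure computation.

A studbook is an individual-level registry of an *ex situ* (zoo/aquarium)
population. For survival analysis each usable individual is reduced to an
*exposure*: the interval of ages, in days, during which it was observed
inside a chosen analysis window, together with a flag saying whether its
death was observed. Individuals born before the window or acquired after
birth enter late (left truncation); individuals alive at the window's end
are right censored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from .km import Exposure

UNKNOWN = "UNK"

SEXES = ("male", "female", "unknown")
FATES = ("dead", "alive_or_lost")

#: required header names of the studbook delimited-text format
REQUIRED_COLUMNS = ("id", "sex", "birth_date", "entry_date", "end_date",
                    "fate", "institution")

_FATE_ALIASES = {
    "dead": "dead",
    "death": "dead",
    "alive": "alive_or_lost",
    "lost": "alive_or_lost",
    "alive_or_lost": "alive_or_lost",
}

_SEX_ALIASES = {
    "male": "male", "m": "male",
    "female": "female", "f": "female",
    "unknown": "unknown", "u": "unknown", UNKNOWN.lower(): "unknown",
}


@dataclass(frozen=True)
class IndividualRecord:
    """One animal's dated life events.

    ``birth_date``, ``entry_date`` and ``end_date`` may be ``None`` when the
    studbook recorded them as unknown; such records are rejected later by
    :func:`validate_records`, not at parse time. ``end_date`` is the death
    date when ``fate == "dead"`` and the last-known-alive date otherwise.
    """

    individual_id: str
    sex: str
    birth_date: date | None
    entry_date: date | None
    end_date: date | None
    fate: str
    institution_known: bool = True


@dataclass(frozen=True)
class AnalysisWindow:
    """Calendar window of the analysis and the starting age of survivorship.

    ``start_age_days`` defaults to 365: survivorship is defined conditional
    on reaching the first birthday, because first-year mortality is strongly
    husbandry-dependent and not generalizable across settings. Window
    boundaries are inclusive on both ends.
    """

    start_date: date
    end_date: date
    start_age_days: int = 365

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise ValueError("window start_date must precede end_date")
        if self.start_age_days < 1:
            raise ValueError("start_age_days must be >= 1")


@dataclass
class ExclusionLog:
    """Record of why individuals were dropped before analysis."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, individual_id: str, reason: str, message: str) -> None:
        self.entries.append((individual_id, reason, message))

    def excluded_ids(self) -> set[str]:
        return {individual_id for individual_id, _, _ in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _parse_date(token: str) -> date | None:
    token = token.strip()
    if not token or token.upper() == UNKNOWN:
        return None
    try:
        return date.fromisoformat(token)
    except ValueError:
        return None  # unparseable dates are unknown, not fatal


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as handle:
        header = handle.readline()
    return "\t" if "\t" in header else ","


def parse_studbook(path: str | Path,
                   delimiter: str | None = None) -> list[IndividualRecord]:
    """Read a delimited-text studbook into records.

    The file must carry the columns in :data:`REQUIRED_COLUMNS` (comma- or
    tab-separated; sniffed from the header when ``delimiter`` is None).
    Dates are ISO-8601; ``UNK`` or an unparseable token means unknown.

    Raises
    ------
    ValueError
        If a required column is missing, or two rows share an ``id``.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    records: list[IndividualRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"studbook file missing required column(s): "
                             f"{', '.join(missing)}")
        for row in reader:
            individual_id = (row["id"] or "").strip()
            if individual_id in seen:
                raise ValueError(f"duplicate individual_id: {individual_id!r}")
            seen.add(individual_id)
            sex = _SEX_ALIASES.get((row["sex"] or "").strip().lower())
            if sex is None:
                sex = "unknown"
            fate_raw = (row["fate"] or "").strip().lower()
            fate = _FATE_ALIASES.get(fate_raw)
            if fate is None:
                raise ValueError(f"unrecognized fate {row['fate']!r} for "
                                 f"individual {individual_id!r}")
            institution = (row["institution"] or "").strip()
            records.append(IndividualRecord(
                individual_id=individual_id,
                sex=sex,
                birth_date=_parse_date(row["birth_date"] or ""),
                entry_date=_parse_date(row["entry_date"] or ""),
                end_date=_parse_date(row["end_date"] or ""),
                fate=fate,
                institution_known=bool(institution)
                and institution.upper() != UNKNOWN,
            ))
    return records


def write_studbook(records: list[IndividualRecord], path: str | Path,
                   delimiter: str = ",") -> None:
    """Write records in the studbook delimited-text format."""
    def fmt(d: date | None) -> str:
        return d.isoformat() if d is not None else UNKNOWN

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow([
                r.individual_id, r.sex, fmt(r.birth_date), fmt(r.entry_date),
                fmt(r.end_date), r.fate,
                "INST" if r.institution_known else UNKNOWN,
            ])


def validate_records(
        records: list[IndividualRecord],
) -> tuple[list[IndividualRecord], ExclusionLog]:
    """Drop records too uncertain or inconsistent to analyze.

    Exclusion never hard-fails: each dropped individual is logged once per
    applicable reason. Reasons: ``unknown_birthdate``, ``unknown_end_date``,
    ``unknown_institution``, ``event_before_birth`` (end date precedes birth),
    ``entry_out_of_order`` (entry date outside [birth, end]).
    """
    clean: list[IndividualRecord] = []
    log = ExclusionLog()
    for r in records:
        reasons: list[tuple[str, str]] = []
        if r.birth_date is None:
            reasons.append(("unknown_birthdate", "birth date unknown"))
        if r.end_date is None:
            reasons.append(("unknown_end_date",
                            "death / last-known date unknown"))
        if not r.institution_known:
            reasons.append(("unknown_institution",
                            "event at unknown or unrecognized institution"))
        if (r.birth_date is not None and r.end_date is not None
                and r.end_date < r.birth_date):
            reasons.append(("event_before_birth",
                            "end date precedes birth date"))
        if (r.entry_date is not None and r.birth_date is not None
                and r.end_date is not None
                and not (r.birth_date <= r.entry_date <= r.end_date)):
            reasons.append(("entry_out_of_order",
                            "entry date outside [birth, end]"))
        if reasons:
            for code, msg in reasons:
                log.add(r.individual_id, code, msg)
        else:
            clean.append(r)
    return clean, log


def compute_exposure(record: IndividualRecord,
                     window: AnalysisWindow) -> Exposure | None:
    """Map a validated record to its at-risk interval inside the window.

    Ages are whole-day differences from the birth date. The entry age is
    the latest of the starting age, the age at the window's start, and the
    age at the acquisition date; the exit age is the age at death or at the
    window's end, whichever is earlier. A death is an observed event only
    when it falls inside the window (a death after the window's end is
    censoring at the window's end). Returns ``None`` when the individual
    contributes no observation time: it died or left before the starting
    age, or its entry age is not before its exit age.
    """
    birth = record.birth_date
    assert birth is not None and record.end_date is not None, \
        "compute_exposure requires a validated record"
    start_age = window.start_age_days
    entry_date = record.entry_date if record.entry_date is not None else birth
    entry_age = max(start_age,
                    (window.start_date - birth).days,
                    (entry_date - birth).days)
    exit_age = (min(record.end_date, window.end_date) - birth).days
    event = (record.fate == "dead"
             and window.start_date <= record.end_date <= window.end_date)
    if exit_age <= start_age or entry_age >= exit_age:
        return None
    return Exposure(individual_id=record.individual_id, sex=record.sex,
                    entry_age=entry_age, exit_age=exit_age, event=event)


def compute_exposures(records: list[IndividualRecord],
                      window: AnalysisWindow) -> list[Exposure]:
    """Exposures for every record that contributes observation time."""
    out = []
    for r in records:
        exposure = compute_exposure(r, window)
        if exposure is not None:
            out.append(exposure)
    return out


def read_window_config(path: str | Path) -> AnalysisWindow:
    """Read a key-value window file: start_date, end_date, start_age_days."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    try:
        return AnalysisWindow(
            start_date=date.fromisoformat(values["start_date"]),
            end_date=date.fromisoformat(values["end_date"]),
            start_age_days=int(values.get("start_age_days", "365")),
        )
    except KeyError as exc:
        raise ValueError(f"window config missing key: {exc.args[0]}") from exc
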