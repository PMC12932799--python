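"""Six-rule occurrence-record cleaning.

Records are removed when they carry at least one of six defects:

1. ``INVALID_BINOMIAL`` — the scientific name is not a well-formed
   two-token binomial (``Genus epithet``).
2. ``BAD_BASIS`` — the basis of record is on a configurable reject list.
3. ``COUNTRY_MISMATCH`` — the country the coordinates resolve to differs
   from the stated country code.
4. ``ABSENCE`` — the record documents an absence rather than a presence.
5. ``BAD_LICENSE`` — the license is not on a configurable accept list of
   open licenses.
6. ``OFF_CHECKLIST`` — the species is not on the checklist for the stated
   country.

A rule that cannot be evaluated because the relevant fields are missing
does not flag (conservative retention); the one exception is ABSENCE,
which only fires on an explicit "absent".  Removal uses union semantics: a
record is dropped once however many rules flag it, and every firing rule is
tallied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "RULES",
    "OccurrenceRecord",
    "FilterReport",
    "CleaningConfig",
    "MalformedRecordError",
    "flag_record",
    "clean_dataset",
    "summarize_flags",
    "records_to_frame",
    "frame_to_records",
    "read_occurrences",
    "write_occurrences",
    "checklist_pairs",
]

INVALID_BINOMIAL = "INVALID_BINOMIAL"
BAD_BASIS = "BAD_BASIS"
COUNTRY_MISMATCH = "COUNTRY_MISMATCH"
ABSENCE = "ABSENCE"
BAD_LICENSE = "BAD_LICENSE"
OFF_CHECKLIST = "OFF_CHECKLIST"

RULES: tuple[str, ...] = (
    INVALID_BINOMIAL,
    BAD_BASIS,
    COUNTRY_MISMATCH,
    ABSENCE,
    BAD_LICENSE,
    OFF_CHECKLIST,
)

#: Darwin Core CSV header -> dataclass attribute
DWC_COLUMNS = {
    "scientificName": "scientific_name",
    "decimalLatitude": "decimal_latitude",
    "decimalLongitude": "decimal_longitude",
    "countryCode": "country_code",
    "basisOfRecord": "basis_of_record",
    "occurrenceStatus": "occurrence_status",
    "license": "license",
    "year": "year",
    "speciesKey": "species_key",
}

#: Markers that introduce an infraspecific epithet; tokens from the first
#: marker onward are ignored when validating a binomial.
_INFRASPECIFIC_MARKERS = {"subsp.", "ssp.", "var.", "subvar.", "f.", "forma", "subf."}


class MalformedRecordError(ValueError):
    """A record field is syntactically invalid (e.g. latitude out of range)."""


@dataclass
class OccurrenceRecord:
    """One specimen or observation row with the fields the six filters inspect."""

    scientific_name: str | None = None
    decimal_latitude: float | None = None
    decimal_longitude: float | None = None
    country_code: str | None = None
    basis_of_record: str | None = None
    occurrence_status: str | None = None
    license: str | None = None
    year: int | None = None
    species_key: str | None = None


@dataclass
class FilterReport:
    """Per-rule flag tallies plus input/retained totals for one cleaning run."""

    input: int = 0
    retained: int = 0
    removed: int = 0
    malformed: int = 0
    rule_counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "FilterReport":
        return cls(**json.loads(payload))


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable rule parameters.

    ``basis_reject`` and ``license_accept`` are compared case-insensitively.
    ``enabled`` lets a rule be switched off wholesale.
    """

    basis_reject: frozenset[str] = frozenset(
        {"FOSSIL_SPECIMEN", "LIVING_SPECIMEN", "MATERIAL_CITATION", "UNKNOWN"}
    )
    license_accept: frozenset[str] = frozenset({"CC0", "CC-BY", "CC-BY-NC"})
    enabled: frozenset[str] = frozenset(RULES)


def _is_binomial(name: str | None) -> bool:
    if not name or not name.strip():
        return False
    tokens = name.split()
    kept: list[str] = []
    for tok in tokens:
        if tok.lower() in _INFRASPECIFIC_MARKERS:
            break
        kept.append(tok)
    if len(kept) < 2:
        return False
    genus, epithet = kept[0], kept[1]
    return (
        genus[0].isupper()
        and genus.isalpha()
        and epithet.isalpha()
        and epithet == epithet.lower()
    )


def _validate_coordinates(record: OccurrenceRecord) -> None:
    lat, lon = record.decimal_latitude, record.decimal_longitude
    if lat is not None and not -90.0 <= lat <= 90.0:
        raise MalformedRecordError(f"latitude {lat} outside [-90, 90]")
    if lon is not None and not -180.0 <= lon <= 180.0:
        raise MalformedRecordError(f"longitude {lon} outside [-180, 180]")


def flag_record(
    record: OccurrenceRecord,
    checklist: "set[tuple[str, str]] | pd.DataFrame",
    country_resolver: Callable[[float, float], str | None] | None = None,
    config: CleaningConfig = CleaningConfig(),
) -> set[str]:
    """Evaluate all six rules on one record; return the set of firing rules.

    ``checklist`` is a set of (species, countryCode) pairs or a DataFrame
    with ``species``/``countryCode`` columns.  ``country_resolver`` maps
    (latitude, longitude) to a country code (or None when unresolvable).
    Raises :class:`MalformedRecordError` on out-of-range coordinates.
    """
    _validate_coordinates(record)
    pairs = checklist_pairs(checklist)
    flags: set[str] = set()

    if INVALID_BINOMIAL in config.enabled and not _is_binomial(record.scientific_name):
        flags.add(INVALID_BINOMIAL)

    if (
        BAD_BASIS in config.enabled
        and record.basis_of_record is not None
        and record.basis_of_record.upper() in {b.upper() for b in config.basis_reject}
    ):
        flags.add(BAD_BASIS)

    if (
        COUNTRY_MISMATCH in config.enabled
        and country_resolver is not None
        and record.decimal_latitude is not None
        and record.decimal_longitude is not None
        and record.country_code
    ):
        resolved = country_resolver(record.decimal_latitude, record.decimal_longitude)
        if resolved is not None and resolved != record.country_code:
            flags.add(COUNTRY_MISMATCH)

    if (
        ABSENCE in config.enabled
        and record.occurrence_status is not None
        and record.occurrence_status.strip().lower() == "absent"
    ):
        flags.add(ABSENCE)

    if (
        BAD_LICENSE in config.enabled
        and record.license is not None
        and record.license.strip().upper()
        not in {l.upper() for l in config.license_accept}
    ):
        flags.add(BAD_LICENSE)

    if (
        OFF_CHECKLIST in config.enabled
        and record.species_key
        and record.country_code
        and (record.species_key, record.country_code) not in pairs
    ):
        flags.add(OFF_CHECKLIST)

    return flags


def clean_dataset(
    records: Sequence[OccurrenceRecord],
    checklist,
    country_resolver: Callable[[float, float], str | None] | None = None,
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[OccurrenceRecord], FilterReport]:
    """Apply the six-rule filter to a dataset.

    Returns the retained records (input order preserved) and a
    :class:`FilterReport`.  Records with malformed coordinates are removed
    and counted separately in ``report.malformed`` — reported, never
    silently dropped.  Cleaning is idempotent and each record is judged
    independently of the others.
    """
    pairs = checklist_pairs(checklist)
    retained: list[OccurrenceRecord] = []
    report = FilterReport(input=len(records))
    for record in records:
        try:
            flags = flag_record(record, pairs, country_resolver, config)
        except MalformedRecordError:
            report.malformed += 1
            report.removed += 1
            continue
        for rule in flags:
            report.rule_counts[rule] += 1
        if flags:
            report.removed += 1
        else:
            retained.append(record)
    report.retained = len(retained)
    return retained, report


def summarize_flags(report: FilterReport) -> dict:
    """JSON-stable summary of a cleaning run; totals reconcile by construction."""
    summary = {
        "input": report.input,
        "retained": report.retained,
        "removed": report.removed,
        "malformed": report.malformed,
        "rule_counts": dict(report.rule_counts),
        "message": f"{report.removed} removed of {report.input} records",
    }
    assert summary["retained"] + summary["removed"] == summary["input"]
    return summary


def checklist_pairs(checklist) -> set[tuple[str, str]]:
    """Normalise a checklist to a set of (species, countryCode) pairs."""
    if isinstance(checklist, set):
        return checklist
    if isinstance(checklist, pd.DataFrame):
        return set(zip(checklist["species"], checklist["countryCode"]))
    return set(checklist)


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    rows = [{dwc: getattr(r, attr) for dwc, attr in DWC_COLUMNS.items()} for r in records]
    return pd.DataFrame(rows, columns=list(DWC_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[OccurrenceRecord]:
    records = []
    for row in frame.to_dict("records"):
        kwargs = {}
        for dwc, attr in DWC_COLUMNS.items():
            value = row.get(dwc)
            if pd.isna(value):
                value = None
            elif attr == "year":
                value = int(value)
            elif attr in ("decimal_latitude", "decimal_longitude"):
                value = float(value)
            kwargs[attr] = value
        records.append(OccurrenceRecord(**kwargs))
    return records


def read_occurrences(path) -> list[OccurrenceRecord]:
    """Read a Darwin-Core-style occurrence CSV."""
    return frame_to_records(pd.read_csv(path))


def write_occurrences(records: Iterable[OccurrenceRecord], path) -> None:
    """Write occurrence records as a Darwin-Core-style CSV (UTF-8, RFC 4180)."""
    records_to_frame(records).to_csv(path, index=False)
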