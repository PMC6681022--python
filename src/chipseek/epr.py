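"""Domain types and I/O for electronic patient record (EPR) corpora.

An EPR corpus is a flat table with one row per consultation line: patient
and clinic identifiers, demographics, the raw microchip field as entered by
clinic staff, the visit date, and the free-text examination record. In
Australia a valid companion-animal microchip number is exactly 15 numeric
characters; everything else (blank, truncated, malformed) is pooled as
"invalid".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Species",
    "Sex",
    "ChipReason",
    "MicrochipValidity",
    "EPRRecord",
    "CorpusCounts",
    "SchemaError",
    "RowParseError",
    "validate_microchip",
    "read_corpus",
    "write_corpus",
    "split_cohorts",
    "count_corpus",
    "CORPUS_COLUMNS",
]

CORPUS_COLUMNS = (
    "patient_id",
    "clinic_id",
    "species",
    "breed",
    "sex",
    "date_of_birth",
    "microchip",
    "visit_date",
    "examination_text",
    "is_litter_record",
)


class Species(str, enum.Enum):
    DOG = "dog"
    CAT = "cat"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class ChipReason(str, enum.Enum):
    """Why a microchip field is (in)valid."""

    OK = "ok"
    WRONG_LENGTH = "wrong_length"
    NON_NUMERIC = "non_numeric"
    BLANK = "blank"


@dataclass(frozen=True)
class MicrochipValidity:
    valid: bool
    reason: ChipReason

    def __post_init__(self) -> None:
        if self.valid != (self.reason is ChipReason.OK):
            raise ValueError("valid must hold exactly when reason is 'ok'")


@dataclass
class EPRRecord:
    """One consultation row.

    ``date_of_birth`` may be absent; ``microchip_raw`` and
    ``examination_text`` may be empty strings. ``is_litter_record`` marks
    rows belonging to a dam's record or a group litter ID rather than an
    individual patient.
    """

    patient_id: str
    clinic_id: str
    species: Species
    breed: str
    sex: Sex
    date_of_birth: date | None
    microchip_raw: str
    visit_date: date
    examination_text: str
    is_litter_record: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.species, str):
            self.species = Species(self.species)
        if isinstance(self.sex, str):
            self.sex = Sex(self.sex)
        if (
            self.date_of_birth is not None
            and self.visit_date < self.date_of_birth
        ):
            raise ValueError(
                f"visit_date {self.visit_date} precedes date_of_birth "
                f"{self.date_of_birth} for patient {self.patient_id}"
            )


@dataclass(frozen=True)
class CorpusCounts:
    n_rows: int
    n_unique_patients: int
    n_unique_chips: int
    n_dogs: int
    n_cats: int

    def __post_init__(self) -> None:
        if not (self.n_unique_chips <= self.n_unique_patients <= self.n_rows):
            raise ValueError("require n_unique_chips <= n_unique_patients <= n_rows")
        if self.n_dogs + self.n_cats != self.n_unique_patients:
            raise ValueError("n_dogs + n_cats must equal n_unique_patients")


class SchemaError(ValueError):
    """A mandatory corpus column is missing."""


class RowParseError(ValueError):
    """A row holds an unparseable value; message cites the file row number."""


_DIGITS = frozenset("0123456789")


def validate_microchip(raw: str) -> MicrochipValidity:
    """Validate a raw microchip field against the 15-numeric-character rule.

    Leading/trailing whitespace is trimmed first. A field is valid iff the
    trimmed text is exactly 15 ASCII decimal digits; internal spaces or
    hyphens invalidate it. Blank, wrong-length and non-numeric fields are
    all invalid, with the reason recorded.
    """
    trimmed = raw.strip()
    if not trimmed:
        return MicrochipValidity(False, ChipReason.BLANK)
    if len(trimmed) != 15:
        return MicrochipValidity(False, ChipReason.WRONG_LENGTH)
    if not all(c in _DIGITS for c in trimmed):
        return MicrochipValidity(False, ChipReason.NON_NUMERIC)
    return MicrochipValidity(True, ChipReason.OK)


def _parse_date(text: str, *, row: int, column: str) -> date | None:
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise RowParseError(
            f"row {row}: cannot parse {column} {text!r} as an ISO-8601 date"
        ) from exc


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"true", "1", "yes"}


def read_corpus(path: str | Path) -> list[EPRRecord]:
    """Read an EPR corpus from CSV.

    Expects a UTF-8 CSV with header columns exactly :data:`CORPUS_COLUMNS`
    and ISO-8601 dates. Missing dates and empty text fields become absent
    values; a missing mandatory column raises :class:`SchemaError` and an
    unparseable date raises :class:`RowParseError` citing the file row
    number (the header is row 1).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CORPUS_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"corpus is missing mandatory column(s): {', '.join(missing)}")

    records: list[EPRRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        file_row = i + 2  # header occupies row 1
        dob = _parse_date(row.date_of_birth, row=file_row, column="date_of_birth")
        visit = _parse_date(row.visit_date, row=file_row, column="visit_date")
        if visit is None:
            raise RowParseError(f"row {file_row}: visit_date is mandatory")
        try:
            rec = EPRRecord(
                patient_id=row.patient_id,
                clinic_id=row.clinic_id,
                species=Species(row.species),
                breed=row.breed,
                sex=Sex(row.sex) if row.sex else Sex.UNKNOWN,
                date_of_birth=dob,
                microchip_raw=row.microchip,
                visit_date=visit,
                examination_text=row.examination_text,
                is_litter_record=_parse_bool(row.is_litter_record),
            )
        except ValueError as exc:
            raise RowParseError(f"row {file_row}: {exc}") from exc
        records.append(rec)
    return records


def write_corpus(records: Iterable[EPRRecord], path: str | Path) -> None:
    """Write records to CSV so that ``read_corpus`` round-trips exactly."""
    rows = [
        {
            "patient_id": r.patient_id,
            "clinic_id": r.clinic_id,
            "species": r.species.value,
            "breed": r.breed,
            "sex": r.sex.value,
            "date_of_birth": r.date_of_birth.isoformat() if r.date_of_birth else "",
            "microchip": r.microchip_raw,
            "visit_date": r.visit_date.isoformat(),
            "examination_text": r.examination_text,
            "is_litter_record": "true" if r.is_litter_record else "false",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CORPUS_COLUMNS)).to_csv(path, index=False)


def split_cohorts(
    corpus: Sequence[EPRRecord],
) -> tuple[list[EPRRecord], list[EPRRecord]]:
    """Partition a corpus into (valid-chip, invalid-chip) cohorts.

    Every record lands in exactly one cohort according to
    :func:`validate_microchip`, so the two sizes always sum to the corpus
    size.
    """
    valid: list[EPRRecord] = []
    invalid: list[EPRRecord] = []
    for rec in corpus:
        (valid if validate_microchip(rec.microchip_raw).valid else invalid).append(rec)
    return valid, invalid


def count_corpus(corpus: Sequence[EPRRecord]) -> CorpusCounts:
    """Row, unique-patient, unique-valid-chip and per-species patient counts.

    Chips are counted over trimmed valid values only; a patient's species is
    taken from their first row.
    """
    patients: dict[str, Species] = {}
    chips: set[str] = set()
    for rec in corpus:
        patients.setdefault(rec.patient_id, rec.species)
        v = validate_microchip(rec.microchip_raw)
        if v.valid:
            chips.add(rec.microchip_raw.strip())
    n_dogs = sum(1 for s in patients.values() if s is Species.DOG)
    return CorpusCounts(
        n_rows=len(corpus),
        n_unique_patients=len(patients),
        n_unique_chips=len(chips),
        n_dogs=n_dogs,
        n_cats=len(patients) - n_dogs,
    )
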