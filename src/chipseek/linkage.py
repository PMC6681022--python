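"""Linkage of patient IDs that share a microchip number.

A microchip is a permanent identifier, so the same animal presenting at
several clinics acquires several patient IDs that share one chip number.
This module groups records by valid chip value and classifies each
multi-ID group by demographic concordance: full match, breed mismatch,
sex mismatch, breed-and-sex mismatch, or species mismatch (the last most
likely a data-entry error). For groups of more than two patients the
group takes the worst pairwise class, with severity ordered
species > breed-and-sex > sex > breed > full match.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import pandas as pd

from .epr import EPRRecord, validate_microchip

__all__ = [
    "Concordance",
    "DuplicateGroup",
    "LinkageReport",
    "classify_pair",
    "group_by_chip",
    "linkage_report",
]


class Concordance(str, enum.Enum):
    FULL_MATCH = "full_match"
    BREED_MISMATCH = "breed_mismatch"
    SEX_MISMATCH = "sex_mismatch"
    BREED_AND_SEX_MISMATCH = "breed_and_sex_mismatch"
    SPECIES_MISMATCH = "species_mismatch"


# Higher = worse; a multi-patient group takes its worst pairwise class.
_SEVERITY = {
    Concordance.FULL_MATCH: 0,
    Concordance.BREED_MISMATCH: 1,
    Concordance.SEX_MISMATCH: 2,
    Concordance.BREED_AND_SEX_MISMATCH: 3,
    Concordance.SPECIES_MISMATCH: 4,
}

_WS = re.compile(r"\s+")


def _norm_breed(breed: str) -> str:
    return _WS.sub(" ", breed.strip().lower())


def classify_pair(rec_a: EPRRecord, rec_b: EPRRecord) -> Concordance:
    """Demographic concordance of two records sharing a chip number.

    Species difference dominates; otherwise breed and sex are compared,
    breed by exact text equality after lowercasing and whitespace
    collapse — so 'Labrador' vs 'Labrador cross' is a breed mismatch even
    though it plausibly names the same animal. Symmetric in its arguments.
    """
    if rec_a.species != rec_b.species:
        return Concordance.SPECIES_MISMATCH
    breed_differs = _norm_breed(rec_a.breed) != _norm_breed(rec_b.breed)
    sex_differs = rec_a.sex != rec_b.sex
    if breed_differs and sex_differs:
        return Concordance.BREED_AND_SEX_MISMATCH
    if sex_differs:
        return Concordance.SEX_MISMATCH
    if breed_differs:
        return Concordance.BREED_MISMATCH
    return Concordance.FULL_MATCH


@dataclass(frozen=True)
class DuplicateGroup:
    """One chip number shared by >= 2 patient IDs (one record per patient)."""

    chip: str
    members: tuple[EPRRecord, ...]
    concordance: Concordance

    @property
    def multiplicity(self) -> int:
        return len(self.members)


def group_by_chip(corpus: Sequence[EPRRecord]) -> list[DuplicateGroup]:
    """Duplicate-chip groups over valid chip values only.

    Keeps the first record seen for each (chip, patient) pair and emits a
    group per chip value associated with at least two distinct patient
    IDs, classified by worst pairwise concordance. Groups are ordered by
    chip value.
    """
    reps: dict[str, dict[str, EPRRecord]] = {}
    for rec in corpus:
        chip = rec.microchip_raw.strip()
        if not validate_microchip(chip).valid:
            continue
        reps.setdefault(chip, {}).setdefault(rec.patient_id, rec)
    groups: list[DuplicateGroup] = []
    for chip in sorted(reps):
        members = tuple(reps[chip].values())
        if len(members) < 2:
            continue
        worst = max(
            (classify_pair(x, y) for x, y in combinations(members, 2)),
            key=_SEVERITY.__getitem__,
        )
        groups.append(DuplicateGroup(chip=chip, members=members, concordance=worst))
    return groups


@dataclass(frozen=True)
class LinkageReport:
    """Counts of duplicate-chip groups by concordance class and multiplicity."""

    n_groups: int
    class_counts: dict[Concordance, int]
    multiplicity_counts: dict[int, int]

    def percentages(self) -> dict[Concordance, float]:
        if self.n_groups == 0:
            return {c: 0.0 for c in Concordance}
        return {
            c: 100.0 * self.class_counts.get(c, 0) / self.n_groups for c in Concordance
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame(
            {
                "concordance": [c.value for c in Concordance],
                "n_groups": [self.class_counts.get(c, 0) for c in Concordance],
                "pct_of_groups": [pct[c] for c in Concordance],
            }
        )


def linkage_report(corpus: Sequence[EPRRecord]) -> LinkageReport:
    """Summarise duplicate-chip groups; class counts partition the groups."""
    groups = group_by_chip(corpus)
    class_counts: dict[Concordance, int] = {}
    mult_counts: dict[int, int] = {}
    for g in groups:
        class_counts[g.concordance] = class_counts.get(g.concordance, 0) + 1
        mult_counts[g.multiplicity] = mult_counts.get(g.multiplicity, 0) + 1
    return LinkageReport(
        n_groups=len(groups), class_counts=class_counts, multiplicity_counts=mult_counts
    )
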