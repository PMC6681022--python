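"""Case-insensitive substring search over examination text.

The search strategy is deliberately primitive: a term is a literal string
and a record is a hit whenever the term occurs anywhere in its examination
text, ignoring case — so 'microc' finds 'Microchipped' as well as the
confounder 'microcytic'. No tokenisation, stemming or fuzzy matching is
performed. On top of the raw search sit term ranking (which term returns
the most records, and how much its patient set overlaps a reference term's)
and broad-vs-narrow differential-word extraction (which words a broader
term catches that a narrower refinement would miss).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .epr import EPRRecord

__all__ = [
    "DEFAULT_TERMS",
    "HitSet",
    "TermRanking",
    "TermRankingRow",
    "WordFrequencyTable",
    "HitConsistencyError",
    "find_hits",
    "rank_terms",
    "differential_words",
]

#: The seven simple search terms trialled for implantation-event retrieval.
DEFAULT_TERMS = ("implant", "mchip", "m chip", "microc", "m/c", "micro-c", "micro c")


@dataclass(frozen=True)
class HitSet:
    """Records matched by one term: indices into the corpus plus patient IDs."""

    term: str
    record_refs: frozenset[int]
    patient_ids: frozenset[str]

    @property
    def n_records(self) -> int:
        return len(self.record_refs)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


class TermRankingRow(NamedTuple):
    term: str
    n_records: int
    n_patients: int
    n_patients_shared_with_reference: int | None  # None for the reference itself


@dataclass(frozen=True)
class TermRanking:
    """Terms ordered by record count (desc), ties broken lexicographically."""

    reference: str
    rows: tuple[TermRankingRow, ...]

    @property
    def best_term(self) -> str:
        return self.rows[0].term

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=TermRankingRow._fields)


@dataclass(frozen=True)
class WordFrequencyTable:
    """Alphabetically sorted (token, record count) pairs."""

    broad: str
    narrow: str
    entries: tuple[tuple[str, int], ...]

    @property
    def total(self) -> int:
        return sum(c for _, c in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["word", "n_records"])


class HitConsistencyError(ValueError):
    """The narrow term's hits are not a subset of the broad term's."""


def find_hits(corpus: Sequence[EPRRecord], term: str) -> HitSet:
    """All records whose examination text contains ``term``, ignoring case."""
    if not term:
        raise ValueError("search term must be non-empty")
    needle = term.lower()
    refs: set[int] = set()
    patients: set[str] = set()
    for i, rec in enumerate(corpus):
        if needle in rec.examination_text.lower():
            refs.add(i)
            patients.add(rec.patient_id)
    return HitSet(term=term, record_refs=frozenset(refs), patient_ids=frozenset(patients))


def rank_terms(
    corpus: Sequence[EPRRecord], terms: Sequence[str], reference: str
) -> TermRanking:
    """Rank terms by number of records returned.

    The first row is the argmax over record counts (ties broken
    lexicographically by term); each row also reports how many of the
    term's patients were already found by the ``reference`` term's search.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    if reference not in terms:
        raise ValueError(f"reference term {reference!r} must be one of the terms")
    hitsets = {t: find_hits(corpus, t) for t in terms}
    ref_patients = hitsets[reference].patient_ids
    rows = [
        TermRankingRow(
            term=t,
            n_records=hs.n_records,
            n_patients=hs.n_patients,
            n_patients_shared_with_reference=(
                None if t == reference else len(hs.patient_ids & ref_patients)
            ),
        )
        for t, hs in hitsets.items()
    ]
    rows.sort(key=lambda r: (-r.n_records, r.term))
    return TermRanking(reference=reference, rows=tuple(rows))


def _token_at(text: str, pos: int) -> str:
    """Maximal run of alphabetic characters containing position ``pos``."""
    start, end = pos, pos
    while start > 0 and text[start - 1].isalpha():
        start -= 1
    while end < len(text) and text[end].isalpha():
        end += 1
    return text[start:end]


def differential_words(
    corpus: Sequence[EPRRecord], broad: str, narrow: str
) -> WordFrequencyTable:
    """Words caught by ``broad`` on records that ``narrow`` misses.

    For each record hit by the broad term but not the narrow one, the
    maximal alphabetic token around the first match is extracted and
    lowercased, counting one per record (not per occurrence). Counts
    therefore sum to ``|hits(broad)| - |hits(narrow)|``. Raises
    :class:`HitConsistencyError` when the narrow hits are not a subset of
    the broad hits.
    """
    broad_hits = find_hits(corpus, broad)
    narrow_hits = find_hits(corpus, narrow)
    if not narrow_hits.record_refs <= broad_hits.record_refs:
        raise HitConsistencyError(
            f"hits({narrow!r}) is not a subset of hits({broad!r}); "
            "differential words are undefined"
        )
    counts: dict[str, int] = {}
    needle = broad.lower()
    for ref in broad_hits.record_refs - narrow_hits.record_refs:
        text = corpus[ref].examination_text
        pos = text.lower().find(needle)
        token = _token_at(text, pos).lower()
        counts[token] = counts.get(token, 0) + 1
    entries = tuple(sorted(counts.items()))
    return WordFrequencyTable(broad=broad, narrow=narrow, entries=entries)
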