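"""Rule-based classification of search hits.

Each record returned by the keyword search is assigned exactly one of 17
categories: a genuine microchip implantation event on that visit date, or
one of 16 reasons the search string appears without an implantation
(blank pre-populated forms, confirmations of a pre-existing chip, plans
for future chipping, stray identification, confounder words such as
'microcytic', and so on).

Where a chart-review study would code these hits manually, this module
applies an ordered first-match-wins pattern table (:class:`RuleSet`),
shipped as configuration and serialisable to YAML, so results are
deterministic and auditable. Litter detection (implantation recorded in a
dam's record or under a group litter ID) and concurrent-interaction
extraction (vaccination, neutering surgery, ... on the same visit) use
dedicated pattern sections of the same rule set.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .epr import EPRRecord
from .search import HitSet

__all__ = [
    "HitCategory",
    "ConcurrentEvent",
    "Rule",
    "RuleSet",
    "ClassificationTable",
    "default_ruleset",
    "classify_hit",
    "sample_hits",
    "detect_litter",
    "extract_concurrent",
    "tabulate_classifications",
]


class HitCategory(str, enum.Enum):
    """Why a record was returned by the search (17 mutually exclusive classes)."""

    IMPLANTATION_EVENT = "implantation_event"
    BLANK_PREPOPULATED_FORM = "blank_prepopulated_form"
    PREEXISTING_CHIP_CONFIRMATION = "preexisting_chip_confirmation"
    FUTURE_PLAN = "future_plan"
    ADMIN_ASSISTANCE = "admin_assistance"
    INTERNAL_NUMBER_REQUEST = "internal_number_request"
    STRAY_ID_SUCCESSFUL = "stray_id_successful"
    STRAY_ID_ATTEMPTED = "stray_id_attempted"
    TRAVEL_REQUIREMENTS = "travel_requirements"
    TECHNICAL_PROBLEM = "technical_problem"
    CONTACT_PREVIOUS_OWNER = "contact_previous_owner"
    IMPLANTATION_COMPLICATION = "implantation_complication"
    OTHER_WORD_OR_TYPO = "other_word_or_typo"
    REPORTED_LOST = "reported_lost"
    ABSENCE_NOTED = "absence_noted"
    OWNER_REFUSAL = "owner_refusal"
    NONE_OF_THE_ABOVE = "none_of_the_above"


class ConcurrentEvent(str, enum.Enum):
    """Veterinary interaction recorded on the same visit as an implantation."""

    VACCINATION = "vaccination"
    SPAY = "spay"
    CASTRATION = "castration"
    OTHER_SURGERY = "other_surgery"
    OTHER_CONSULT = "other_consult"
    NONE = "none"


@dataclass(frozen=True)
class Rule:
    """One ordered classification rule: a case-insensitive regex pattern."""

    pattern: str
    category: HitCategory

    def compiled(self) -> re.Pattern[str]:
        return re.compile(self.pattern, re.IGNORECASE)


# Misspellings of 'microchip' that still contain the search string 'microc'.
CHIP_MISSPELLINGS = ("microcip", "microcjip", "microcchip", "microchpi")

# Confounder vocabulary: real clinical words containing 'microc' that have
# nothing to do with microchips ('microcope' standing for misspelled
# 'microscope').
CONFOUNDER_WORDS = (
    "microcardia",
    "microcautery",
    "microcilia",
    "microclimate",
    "microclone",
    "microclot",
    "microconidia",
    "microconvex",
    "microcrystals",
    "microcysts",
    "microcytes",
    "microcytic",
    "microcytosis",
    "microcope",
)

_OTHER_WORD_PATTERN = "|".join(CONFOUNDER_WORDS + CHIP_MISSPELLINGS)

# Ordered: first match wins; specific phrasings precede the broad
# implantation rule so e.g. a complication note mentioning the implantation
# site is not read as a fresh implantation.
_DEFAULT_RULES: tuple[tuple[str, HitCategory], ...] = (
    (r"microchip:\s*_", HitCategory.BLANK_PREPOPULATED_FORM),
    (
        r"microchip implantation site|microchip site swelling|chip migrat",
        HitCategory.IMPLANTATION_COMPLICATION,
    ),
    (
        r"stray.*(owner contacted|owner collected|reunited)",
        HitCategory.STRAY_ID_SUCCESSFUL,
    ),
    (
        r"stray.*(no registered owner|unable to identify|not registered)",
        HitCategory.STRAY_ID_ATTEMPTED,
    ),
    (r"reported (as )?lost|reports .*lost|animal lost", HitCategory.REPORTED_LOST),
    (r"no microchip (found|detected|present)", HitCategory.ABSENCE_NOTED),
    (r"(owner|client) (declined|refused) microchip", HitCategory.OWNER_REFUSAL),
    (
        r"plan:? microchip|microchip at next visit|book microchip|to microchip at",
        HitCategory.FUTURE_PLAN,
    ),
    (r"export certificate|travel (requires|certificate)", HitCategory.TRAVEL_REQUIREMENTS),
    (
        r"microchip not reading|chip failure|faulty microchip",
        HitCategory.TECHNICAL_PROBLEM,
    ),
    (r"previous owner", HitCategory.CONTACT_PREVIOUS_OWNER),
    (
        r"change of ownership|change of details|transfer of registration",
        HitCategory.ADMIN_ASSISTANCE,
    ),
    (
        r"microchip number for (the )?clinic",
        HitCategory.INTERNAL_NUMBER_REQUEST,
    ),
    (
        r"existing microchip|microchip already present|microchip confirmed",
        HitCategory.PREEXISTING_CHIP_CONFIRMATION,
    ),
    (
        r"microchip implanted|microchipped (today|at|prior)|microchip inserted"
        r"|all microchipped|litter .*microchipped",
        HitCategory.IMPLANTATION_EVENT,
    ),
    (_OTHER_WORD_PATTERN, HitCategory.OTHER_WORD_OR_TYPO),
)

_DEFAULT_LITTER_PATTERNS = (r"litter", r"pups all", r"kittens (all )?microchipped")

_DEFAULT_CONCURRENT_PATTERNS: tuple[tuple[str, ConcurrentEvent], ...] = (
    (r"vaccinat|\bc3\b|\bc5\b|\bf3\b|booster", ConcurrentEvent.VACCINATION),
    (r"spay|ovariohysterectomy", ConcurrentEvent.SPAY),
    (r"castrat", ConcurrentEvent.CASTRATION),
    (r"lump removal|dental|surgery", ConcurrentEvent.OTHER_SURGERY),
    (r"presented for|consult for|examination for", ConcurrentEvent.OTHER_CONSULT),
)


@dataclass
class RuleSet:
    """Ordered classification rules plus litter and concurrent-event patterns.

    Rule order is part of the configuration: the first matching rule wins
    and ``default`` applies when no rule fires. The set round-trips through
    YAML so a run's exact coding scheme can be serialized with its results.
    """

    rules: list[Rule]
    default: HitCategory = HitCategory.NONE_OF_THE_ABOVE
    litter_patterns: list[str] = field(default_factory=list)
    concurrent_patterns: list[tuple[str, ConcurrentEvent]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._compiled = [(r.compiled(), r.category) for r in self.rules]
        self._litter = [re.compile(p, re.IGNORECASE) for p in self.litter_patterns]
        self._concurrent = [
            (re.compile(p, re.IGNORECASE), ev) for p, ev in self.concurrent_patterns
        ]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "rules": [{"pattern": r.pattern, "category": r.category.value} for r in self.rules],
            "default": self.default.value,
            "litter_patterns": list(self.litter_patterns),
            "concurrent_patterns": [
                {"pattern": p, "event": ev.value} for p, ev in self.concurrent_patterns
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            rules=[Rule(d["pattern"], HitCategory(d["category"])) for d in payload["rules"]],
            default=HitCategory(payload.get("default", "none_of_the_above")),
            litter_patterns=list(payload.get("litter_patterns", [])),
            concurrent_patterns=[
                (d["pattern"], ConcurrentEvent(d["event"]))
                for d in payload.get("concurrent_patterns", [])
            ],
        )


def default_ruleset() -> RuleSet:
    """The package's default coding scheme for search hits."""
    return RuleSet(
        rules=[Rule(p, c) for p, c in _DEFAULT_RULES],
        litter_patterns=list(_DEFAULT_LITTER_PATTERNS),
        concurrent_patterns=list(_DEFAULT_CONCURRENT_PATTERNS),
    )


def classify_hit(record: EPRRecord, rules: RuleSet) -> HitCategory:
    """Assign a search hit its category: first matching rule wins."""
    text = record.examination_text
    for pattern, category in rules._compiled:
        if pattern.search(text):
            return category
    return rules.default


def sample_hits(hits: HitSet, n: int, seed: int) -> list[int]:
    """Sample ``n`` record references uniformly without replacement.

    Uses a Mersenne-Twister generator so the draw is reproducible from the
    seed; the candidate references are sorted first so the result does not
    depend on set iteration order.
    """
    refs = sorted(hits.record_refs)
    if n > len(refs):
        raise ValueError(f"cannot sample {n} from {len(refs)} hits")
    rng = np.random.RandomState(seed)
    picked = rng.choice(len(refs), size=n, replace=False)
    return [refs[i] for i in picked]


def detect_litter(record: EPRRecord, rules: RuleSet) -> bool:
    """Whether an implantation hit is a litter event.

    True when the row is flagged as belonging to a dam's record / group
    litter ID, or when a litter text pattern fires.
    """
    if record.is_litter_record:
        return True
    return any(p.search(record.examination_text) for p in rules._litter)


def extract_concurrent(record: EPRRecord, rules: RuleSet) -> set[ConcurrentEvent]:
    """Concurrent veterinary interactions recorded with an implantation.

    Returns ``{NONE}`` when no interaction pattern matches, so the result
    is never empty.
    """
    found = {
        ev for pattern, ev in rules._concurrent if pattern.search(record.examination_text)
    }
    return found or {ConcurrentEvent.NONE}


@dataclass(frozen=True)
class ClassificationTable:
    """Per-category hit counts for one cohort; counts sum to the sample size."""

    counts: dict[HitCategory, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts must sum to the sample total")

    def __getitem__(self, category: HitCategory) -> int:
        return self.counts.get(category, 0)

    def proportions(self) -> dict[HitCategory, float]:
        if self.total == 0:
            return {c: 0.0 for c in HitCategory}
        return {c: self[c] / self.total for c in HitCategory}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": [c.value for c in HitCategory], "count": [self[c] for c in HitCategory]}
        )


def tabulate_classifications(labels: Iterable[HitCategory]) -> ClassificationTable:
    """Count category labels into a table; total equals the number of labels."""
    counts: dict[HitCategory, int] = {c: 0 for c in HitCategory}
    n = 0
    for lab in labels:
        counts[lab] += 1
        n += 1
    return ClassificationTable(counts={c: k for c, k in counts.items() if k}, total=n)
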