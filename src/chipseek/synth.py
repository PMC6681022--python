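"""Seeded synthetic EPR corpus generator with ground-truth labels.

Real primary-care veterinary databases cannot be redistributed, so the
package ships a generator that emulates the statistical structure the
analysis assumes: a dog-heavy species mix, a blend of valid 15-digit and
invalid/blank microchip fields, examination texts rendered from the
17-category hit taxonomy (every hit text contains the 'microc' string),
confounder vocabulary ('microcytic', 'microconvex', ...), right-skewed
log-normal age-at-implantation distributions with species-specific
medians, litter events, and duplicate chip numbers injected across
patient IDs with controlled demographic discordance.

Every draw flows from a single seeded generator, so a configuration
reproduces its corpus byte for byte, and the generator emits per-record
ground truth (true category, litter flag, concurrent events, injected
duplicate class) against which the rule-based classifier is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .classify import (
    CHIP_MISSPELLINGS,
    CONFOUNDER_WORDS,
    ConcurrentEvent,
    HitCategory,
)
from .epr import EPRRecord, Sex, Species
from .linkage import Concordance

__all__ = [
    "AgeModel",
    "GeneratorConfig",
    "GroundTruth",
    "valid_cohort_mixture",
    "invalid_cohort_mixture",
    "generate",
    "render_text",
    "sample_age",
]

# Per-cohort hit-category counts used as default mixtures (valid cohort
# normalised over 1000 sampled hits, invalid over its printed 999).
_VALID_COUNTS = {
    HitCategory.IMPLANTATION_EVENT: 257,
    HitCategory.BLANK_PREPOPULATED_FORM: 458,
    HitCategory.PREEXISTING_CHIP_CONFIRMATION: 203,
    HitCategory.FUTURE_PLAN: 25,
    HitCategory.ADMIN_ASSISTANCE: 9,
    HitCategory.INTERNAL_NUMBER_REQUEST: 8,
    HitCategory.STRAY_ID_SUCCESSFUL: 2,
    HitCategory.STRAY_ID_ATTEMPTED: 0,
    HitCategory.TRAVEL_REQUIREMENTS: 4,
    HitCategory.TECHNICAL_PROBLEM: 1,
    HitCategory.CONTACT_PREVIOUS_OWNER: 2,
    HitCategory.IMPLANTATION_COMPLICATION: 6,
    HitCategory.OTHER_WORD_OR_TYPO: 2,
    HitCategory.REPORTED_LOST: 0,
    HitCategory.ABSENCE_NOTED: 5,
    HitCategory.OWNER_REFUSAL: 0,
    HitCategory.NONE_OF_THE_ABOVE: 18,
}
_INVALID_COUNTS = {
    HitCategory.IMPLANTATION_EVENT: 155,
    HitCategory.BLANK_PREPOPULATED_FORM: 385,
    HitCategory.PREEXISTING_CHIP_CONFIRMATION: 164,
    HitCategory.FUTURE_PLAN: 73,
    HitCategory.ADMIN_ASSISTANCE: 7,
    HitCategory.INTERNAL_NUMBER_REQUEST: 9,
    HitCategory.STRAY_ID_SUCCESSFUL: 39,
    HitCategory.STRAY_ID_ATTEMPTED: 27,
    HitCategory.TRAVEL_REQUIREMENTS: 2,
    HitCategory.TECHNICAL_PROBLEM: 1,
    HitCategory.CONTACT_PREVIOUS_OWNER: 1,
    HitCategory.IMPLANTATION_COMPLICATION: 0,
    HitCategory.OTHER_WORD_OR_TYPO: 7,
    HitCategory.REPORTED_LOST: 11,
    HitCategory.ABSENCE_NOTED: 87,
    HitCategory.OWNER_REFUSAL: 19,
    HitCategory.NONE_OF_THE_ABOVE: 12,
}

_CATEGORIES = tuple(HitCategory)


def valid_cohort_mixture() -> dict[HitCategory, float]:
    """Default hit-category mixture for records with valid chip fields."""
    total = sum(_VALID_COUNTS.values())
    return {c: _VALID_COUNTS[c] / total for c in _CATEGORIES}


def invalid_cohort_mixture() -> dict[HitCategory, float]:
    """Hit-category mixture preset for records with invalid chip fields."""
    total = sum(_INVALID_COUNTS.values())
    return {c: _INVALID_COUNTS[c] / total for c in _CATEGORIES}


_Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class AgeModel:
    """Log-normal age-at-implantation model pinned to a (median, IQR) target.

    For a log-normal with log-mean mu and log-sd sigma the median is
    exp(mu) and the IQR is 2*median*sinh(sigma*z75), so the parameters
    follow in closed form: mu = ln(median),
    sigma = asinh(IQR / (2*median)) / z75.
    """

    median_days: float
    iqr_days: float

    @property
    def mu(self) -> float:
        return math.log(self.median_days)

    @property
    def sigma(self) -> float:
        return math.asinh(self.iqr_days / (2.0 * self.median_days)) / _Z75


_DOG_BREEDS = (
    "Labrador Retriever",
    "Kelpie",
    "Border Collie",
    "Staffordshire Bull Terrier",
    "Jack Russell Terrier",
    "German Shepherd Dog",
    "Cavalier King Charles Spaniel",
    "Maltese cross",
    "Golden Retriever",
    "Poodle",
)
_CAT_BREEDS = (
    "Domestic Short Hair",
    "Domestic Medium Hair",
    "Domestic Long Hair",
    "Burmese",
    "Ragdoll",
    "Siamese",
    "British Short Hair",
    "Bengal",
)

_INVALID_CHIP_VARIANTS = ("", "", "956000123", "95600001234567", "NO CHIP", "pending")

_NEUTRAL_TEXTS = (
    "Annual health check, all parameters within normal limits.",
    "Presented with itchy skin, prescribed medicated wash.",
    "Vomited twice overnight, bland diet advised, recheck if ongoing.",
    "Nail trim and anal gland expression performed.",
    "Mild dental tartar noted, discussed home care.",
    "Weight check, body condition score 5/9.",
    "Ear cleaning demonstrated to owner, drops dispensed.",
)

_IMPLANT_PHRASES = (
    "Microchip implanted today, number recorded in file.",
    "New microchip inserted between the shoulder blades, sticker in file.",
    "Microchipped today, certificate issued to owner.",
)

_CONCURRENT_PHRASES: dict[ConcurrentEvent, tuple[str, ...]] = {
    ConcurrentEvent.VACCINATION: (
        "C5 vaccination given.",
        "F3 vaccination given.",
        "Booster vaccination administered.",
    ),
    ConcurrentEvent.SPAY: ("Spay performed under GA.", "Ovariohysterectomy completed."),
    ConcurrentEvent.CASTRATION: ("Castration performed under GA.",),
    ConcurrentEvent.OTHER_SURGERY: (
        "Lump removal surgery under GA.",
        "Dental extraction under GA.",
    ),
    ConcurrentEvent.OTHER_CONSULT: (
        "Presented for skin check.",
        "Presented for ear infection.",
    ),
    ConcurrentEvent.NONE: ("No other procedures today.",),
}

_CATEGORY_TEMPLATES: dict[HitCategory, tuple[str, ...]] = {
    HitCategory.BLANK_PREPOPULATED_FORM: (
        "Temp: ___ Weight: ___ Microchip: ___ Vacc: ___",
        "Admission form. Microchip: ______ Desexed: ___ Diet: ___",
    ),
    HitCategory.PREEXISTING_CHIP_CONFIRMATION: (
        "Scanned on admission, existing microchip confirmed.",
        "Microchip already present, number matches records.",
    ),
    HitCategory.FUTURE_PLAN: (
        "Plan: microchip at next visit with second vaccination.",
        "Owner to book microchip at desexing next month.",
    ),
    HitCategory.ADMIN_ASSISTANCE: (
        "Assisted owner with microchip change of ownership paperwork.",
        "Completed microchip change of details form for new address.",
    ),
    HitCategory.INTERNAL_NUMBER_REQUEST: (
        "Reminder: obtain microchip number for clinic records, not yet completed.",
    ),
    HitCategory.STRAY_ID_SUCCESSFUL: (
        "Stray brought in by member of public, microchip scanned, owner contacted and animal collected.",
    ),
    HitCategory.STRAY_ID_ATTEMPTED: (
        "Stray presented, scanned for microchip, no registered owner found on database.",
    ),
    HitCategory.TRAVEL_REQUIREMENTS: (
        "Export certificate for travel requires microchip and rabies vaccination.",
    ),
    HitCategory.TECHNICAL_PROBLEM: (
        "Microchip not reading on scanner, possible chip failure, re-scan next visit.",
    ),
    HitCategory.CONTACT_PREVIOUS_OWNER: (
        "Attempted to contact previous owner using microchip registry history.",
    ),
    HitCategory.IMPLANTATION_COMPLICATION: (
        "Swelling at microchip implantation site, monitor and recheck in one week.",
    ),
    HitCategory.REPORTED_LOST: (
        "Owner reports animal lost, microchip details provided to council.",
    ),
    HitCategory.ABSENCE_NOTED: (
        "Scanned, no microchip found.",
        "No microchip detected on full body scan.",
    ),
    HitCategory.OWNER_REFUSAL: (
        "Owner declined microchip implantation, no future plan recorded.",
    ),
    HitCategory.NONE_OF_THE_ABOVE: (
        "Microchip brochure provided in new puppy pack.",
        "Discussed microchip legislation leaflet with owner.",
    ),
}


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent or infeasible."""


def _check_mixture(name: str, mixture: Mapping, tol: float = 1e-9) -> None:
    total = sum(mixture.values())
    if abs(total - 1.0) > tol:
        raise ConfigError(f"{name} must sum to 1 (got {total!r})")
    if any(v < 0 for v in mixture.values()):
        raise ConfigError(f"{name} has negative probabilities")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate the cohort structure the analysis targets: 77.1%
    dogs, ~73.4% valid chip fields, a hit fraction of ~2.66% of rows,
    per-cohort category mixtures, per-species concurrent-event mixtures,
    log-normal ages with dog/cat medians of 74.4/127.0 days, per-cohort
    litter fractions, and a small set of injected duplicate-chip groups.
    ``duplicate_injection`` maps each concordance class to a tuple of
    group multiplicities (``(2, 2, 3)`` = two pairs and one triple).
    """

    n_patients: int = 1000
    dog_fraction: float = 0.771
    valid_chip_fraction: float = 0.734
    hit_fraction: float = 0.0266
    category_mixture: dict[HitCategory, float] = field(default_factory=valid_cohort_mixture)
    invalid_category_mixture: dict[HitCategory, float] = field(
        default_factory=invalid_cohort_mixture
    )
    concurrent_mixture: dict[Species, dict[ConcurrentEvent, float]] = field(
        default_factory=lambda: {
            Species.DOG: {
                ConcurrentEvent.VACCINATION: 179 / 226,
                ConcurrentEvent.SPAY: 14 / 226,
                ConcurrentEvent.CASTRATION: 15 / 226,
                ConcurrentEvent.OTHER_SURGERY: 3 / 226,
                ConcurrentEvent.OTHER_CONSULT: 6 / 226,
                ConcurrentEvent.NONE: 9 / 226,
            },
            Species.CAT: {
                ConcurrentEvent.VACCINATION: 57 / 139,
                ConcurrentEvent.SPAY: 30 / 139,
                ConcurrentEvent.CASTRATION: 41 / 139,
                ConcurrentEvent.OTHER_SURGERY: 2 / 139,
                ConcurrentEvent.OTHER_CONSULT: 2 / 139,
                ConcurrentEvent.NONE: 7 / 139,
            },
        }
    )
    age_model: dict[Species, AgeModel] = field(
        default_factory=lambda: {
            Species.DOG: AgeModel(median_days=74.4, iqr_days=95.23),
            Species.CAT: AgeModel(median_days=127.0, iqr_days=131.45),
        }
    )
    dam_age_model: AgeModel = field(default_factory=lambda: AgeModel(730.0, 500.0))
    litter_fraction_valid: float = 11 / 257
    litter_fraction_invalid: float = 36 / 155
    duplicate_injection: dict[Concordance, tuple[int, ...]] = field(
        default_factory=lambda: {
            Concordance.FULL_MATCH: (2, 2, 2, 2),
            Concordance.BREED_MISMATCH: (2, 2),
            Concordance.SEX_MISMATCH: (2,),
            Concordance.BREED_AND_SEX_MISMATCH: (2,),
            Concordance.SPECIES_MISMATCH: (2,),
        }
    )
    confounder_rate: float = 1e-4
    typo_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dog_fraction",
            "valid_chip_fraction",
            "hit_fraction",
            "litter_fraction_valid",
            "litter_fraction_invalid",
            "confounder_rate",
            "typo_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        _check_mixture("category_mixture", self.category_mixture)
        _check_mixture("invalid_category_mixture", self.invalid_category_mixture)
        for sp, mix in self.concurrent_mixture.items():
            _check_mixture(f"concurrent_mixture[{sp.value}]", mix)
        n_dup = sum(
            m for mults in self.duplicate_injection.values() for m in mults
        )
        if any(
            m < 2 for mults in self.duplicate_injection.values() for m in mults
        ):
            raise ConfigError("duplicate group multiplicities must be >= 2")
        if n_dup > self.n_patients:
            raise ConfigError(
                f"duplicate injection needs {n_dup} patients but only "
                f"{self.n_patients} are generated"
            )


@dataclass
class GroundTruth:
    """Per-record truth aligned with the generated corpus by index."""

    category: list[HitCategory | None]
    litter: list[bool]
    concurrent: list[frozenset[ConcurrentEvent] | None]
    duplicate_class: list[Concordance | None]

    def hit_refs(self) -> list[int]:
        return [i for i, c in enumerate(self.category) if c is not None]


def sample_age(species: Species, age_model: Mapping[Species, AgeModel], rng) -> int:
    """One age-at-implantation draw in whole days (>= 1)."""
    model = age_model[species]
    if model.sigma == 0.0:
        return max(1, round(model.median_days))
    return max(1, round(float(rng.lognormal(model.mu, model.sigma))))


def _choice(rng, mixture: Mapping) -> object:
    keys = list(mixture.keys())
    probs = np.array([mixture[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _apply_typo(text: str, rng) -> str:
    """Replace the first 'microchip' with a misspelling that still contains
    the 'microc' search string (so the record stays a hit)."""
    lower = text.lower()
    pos = lower.find("microchip")
    if pos < 0:
        return text
    typo = CHIP_MISSPELLINGS[rng.integers(len(CHIP_MISSPELLINGS))]
    return text[:pos] + typo + text[pos + len("microchip") :]


def render_text(
    category: HitCategory,
    rng,
    *,
    species: Species = Species.DOG,
    concurrent: ConcurrentEvent | None = None,
    litter: bool = False,
) -> str:
    """Render an examination text whose category pattern fires on it.

    Every rendered hit text contains a 'microc' match (the taxonomy
    classifies search hits, so hit categories must be findable);
    ``other_word_or_typo`` texts carry a confounder word and no
    chip-related phrase.
    """
    if category is HitCategory.IMPLANTATION_EVENT:
        if litter:
            n_young = int(rng.integers(3, 9))
            young = "pups" if species is Species.DOG else "kittens"
            return f"Litter of {n_young} {young} all microchipped prior to sale."
        phrase = _IMPLANT_PHRASES[rng.integers(len(_IMPLANT_PHRASES))]
        ev = concurrent if concurrent is not None else ConcurrentEvent.NONE
        options = _CONCURRENT_PHRASES[ev]
        ev_phrase = options[rng.integers(len(options))]
        if ev is ConcurrentEvent.NONE:
            return f"{phrase} {ev_phrase}"
        return f"{ev_phrase} {phrase}"
    if category is HitCategory.OTHER_WORD_OR_TYPO:
        word = CONFOUNDER_WORDS[rng.integers(len(CONFOUNDER_WORDS))]
        return f"Bloods reviewed, {word} noted."
    options = _CATEGORY_TEMPLATES[category]
    return options[rng.integers(len(options))]


def _fresh_chip(counter: int) -> str:
    return f"9{counter:014d}"


def _invalid_chip(rng) -> str:
    return _INVALID_CHIP_VARIANTS[rng.integers(len(_INVALID_CHIP_VARIANTS))]


def _other_breed(breeds: Sequence[str], current: str, rng) -> str:
    pool = [b for b in breeds if b != current]
    return pool[rng.integers(len(pool))]


_EPOCH = date(2014, 1, 1)
_DOB_SPAN_DAYS = 1246  # up to mid-2017


def generate(config: GeneratorConfig) -> tuple[list[EPRRecord], GroundTruth]:
    """Generate a corpus and its ground truth, deterministically from the seed.

    One consultation row per patient. Demographics and chip fields are
    drawn first; duplicate-chip groups are then carved out of the tail of
    the patient list (shared fresh valid chips, demographics forced to the
    configured concordance class); finally each record's hit status,
    category, litter flag, concurrent events, age and examination text are
    drawn, with visit_date = date_of_birth + age so the date invariant
    always holds.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    species = np.where(
        rng.random(n) < config.dog_fraction, Species.DOG.value, Species.CAT.value
    )
    sexes = np.where(rng.random(n) < 0.5, Sex.MALE.value, Sex.FEMALE.value)
    chip_valid = rng.random(n) < config.valid_chip_fraction

    breeds: list[str] = []
    chips: list[str] = []
    chip_counter = 0
    for i in range(n):
        pool = _DOG_BREEDS if species[i] == Species.DOG.value else _CAT_BREEDS
        breeds.append(pool[rng.integers(len(pool))])
        if chip_valid[i]:
            chips.append(_fresh_chip(chip_counter))
            chip_counter += 1
        else:
            chips.append(_invalid_chip(rng))

    # Duplicate injection: consume patients from the tail, in a fixed
    # class order, overriding chips and demographics.
    duplicate_class: list[Concordance | None] = [None] * n
    cursor = n
    for cls in Concordance:
        for mult in config.duplicate_injection.get(cls, ()):
            members = list(range(cursor - mult, cursor))
            cursor -= mult
            shared = _fresh_chip(chip_counter)
            chip_counter += 1
            lead = members[0]
            lead_pool = _DOG_BREEDS if species[lead] == Species.DOG.value else _CAT_BREEDS
            for j, idx in enumerate(members):
                chips[idx] = shared
                chip_valid[idx] = True
                duplicate_class[idx] = cls
                if j == 0:
                    continue
                species[idx] = species[lead]
                breeds[idx] = breeds[lead]
                sexes[idx] = sexes[lead]
                if j == 1:
                    if cls is Concordance.SPECIES_MISMATCH:
                        flipped = (
                            Species.CAT.value
                            if species[lead] == Species.DOG.value
                            else Species.DOG.value
                        )
                        species[idx] = flipped
                        other_pool = (
                            _DOG_BREEDS if flipped == Species.DOG.value else _CAT_BREEDS
                        )
                        breeds[idx] = other_pool[rng.integers(len(other_pool))]
                    elif cls is Concordance.BREED_MISMATCH:
                        breeds[idx] = _other_breed(lead_pool, breeds[lead], rng)
                    elif cls is Concordance.SEX_MISMATCH:
                        sexes[idx] = (
                            Sex.FEMALE.value
                            if sexes[lead] == Sex.MALE.value
                            else Sex.MALE.value
                        )
                    elif cls is Concordance.BREED_AND_SEX_MISMATCH:
                        breeds[idx] = _other_breed(lead_pool, breeds[lead], rng)
                        sexes[idx] = (
                            Sex.FEMALE.value
                            if sexes[lead] == Sex.MALE.value
                            else Sex.MALE.value
                        )

    records: list[EPRRecord] = []
    truth = GroundTruth(
        category=[None] * n,
        litter=[False] * n,
        concurrent=[None] * n,
        duplicate_class=duplicate_class,
    )
    for i in range(n):
        sp = Species(species[i])
        dob = _EPOCH + timedelta(days=int(rng.integers(_DOB_SPAN_DAYS)))
        is_hit = rng.random() < config.hit_fraction
        mixture = (
            config.category_mixture if chip_valid[i] else config.invalid_category_mixture
        )
        litter = False
        concurrent: ConcurrentEvent | None = None
        is_litter_row = False
        if is_hit:
            category: HitCategory | None = _choice(rng, mixture)
            if category is HitCategory.IMPLANTATION_EVENT:
                lf = (
                    config.litter_fraction_valid
                    if chip_valid[i]
                    else config.litter_fraction_invalid
                )
                litter = bool(rng.random() < lf)
                if litter:
                    is_litter_row = True
                    age = sample_age(sp, {sp: config.dam_age_model}, rng)
                else:
                    concurrent = _choice(rng, config.concurrent_mixture[sp])
                    age = sample_age(sp, config.age_model, rng)
            else:
                age = int(rng.integers(30, 2500))
            text = render_text(
                category, rng, species=sp, concurrent=concurrent, litter=litter
            )
            if config.typo_rate and rng.random() < config.typo_rate:
                text = _apply_typo(text, rng)
        else:
            category = None
            age = int(rng.integers(30, 2500))
            text = _NEUTRAL_TEXTS[rng.integers(len(_NEUTRAL_TEXTS))]
            if config.confounder_rate and rng.random() < config.confounder_rate:
                word = CONFOUNDER_WORDS[rng.integers(len(CONFOUNDER_WORDS))]
                text = f"{text} Ultrasound with {word} probe."
                category = HitCategory.OTHER_WORD_OR_TYPO

        truth.category[i] = category
        truth.litter[i] = litter
        if category is HitCategory.IMPLANTATION_EVENT and not litter:
            truth.concurrent[i] = frozenset(
                {concurrent if concurrent is not None else ConcurrentEvent.NONE}
            )

        records.append(
            EPRRecord(
                patient_id=f"P{i:06d}",
                clinic_id=f"C{int(rng.integers(1, 21)):02d}",
                species=sp,
                breed=breeds[i],
                sex=Sex(sexes[i]),
                date_of_birth=dob,
                microchip_raw=chips[i],
                visit_date=dob + timedelta(days=age),
                examination_text=text,
                is_litter_record=is_litter_row,
            )
        )
    return records, truth
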