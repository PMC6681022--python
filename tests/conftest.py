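from datetime import date

import pytest

from chipseek.classify import RuleSet, default_ruleset
from chipseek.epr import EPRRecord, Sex, Species
from chipseek.synth import GeneratorConfig, generate


def make_record(
    text: str = "",
    *,
    patient_id: str = "P1",
    species: Species = Species.DOG,
    breed: str = "Kelpie",
    sex: Sex = Sex.MALE,
    chip: str = "956000012345678",
    dob: date | None = date(2017, 1, 1),
    visit: date = date(2017, 3, 16),
    litter: bool = False,
) -> EPRRecord:
    return EPRRecord(
        patient_id=patient_id,
        clinic_id="C01",
        species=species,
        breed=breed,
        sex=sex,
        date_of_birth=dob,
        microchip_raw=chip,
        visit_date=visit,
        examination_text=text,
        is_litter_record=litter,
    )


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return default_ruleset()


@pytest.fixture(scope="session")
def default_corpus_10k():
    """The default synthetic study corpus: 10,000 patients, fixed seed."""
    return generate(GeneratorConfig(n_patients=10_000, seed=11))
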