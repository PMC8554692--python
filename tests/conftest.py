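"""Shared builders for hand-written cohort scenarios."""

from __future__ import annotations

from typing import Optional

import pytest

from lfspectrum.cohort_model import (
    ClinSig,
    Cohort,
    Diagnosis,
    Individual,
    Morphology,
    Sex,
    Site,
    VariantCall,
)


def plp(hgvs="p.R248Q", mosaic=False, ch=False) -> VariantCall:
    return VariantCall(
        hgvs_p=hgvs,
        clinsig=ClinSig.P_LP,
        mosaic=mosaic,
        clonal_hematopoiesis_suspected=ch,
    )


def person(
    iid: str,
    fam: str = "FAM1",
    father: Optional[str] = None,
    mother: Optional[str] = None,
    sex: Sex = Sex.unknown,
    variant: Optional[VariantCall] = None,
    proband: bool = False,
) -> Individual:
    return Individual(
        individual_id=iid,
        family_id=fam,
        father_id=father,
        mother_id=mother,
        sex=sex,
        variant=variant,
        is_proband=proband,
    )


def dx(
    iid: str,
    site: Site,
    age: float,
    morphology: Optional[Morphology] = None,
    premenopausal: Optional[bool] = None,
) -> Diagnosis:
    return Diagnosis(
        individual_id=iid,
        site=site,
        morphology=morphology,
        age_at_dx=age,
        premenopausal_flag=premenopausal,
    )


@pytest.fixture
def three_generation_family() -> Cohort:
    """Paternal grandparents, father + uncle, married-in mother,
    proband 'kid' and sibling. No diagnoses."""
    inds = [
        person("gf", sex=Sex.male),
        person("gm", sex=Sex.female),
        person("dad", father="gf", mother="gm", sex=Sex.male),
        person("uncle", father="gf", mother="gm", sex=Sex.male),
        person("mom", sex=Sex.female),
        person("kid", father="dad", mother="mom", sex=Sex.female, proband=True),
        person("sib", father="dad", mother="mom", sex=Sex.male),
    ]
    return Cohort(individuals=inds, diagnoses=[])


def with_diagnoses(cohort: Cohort, *diagnoses: Diagnosis) -> Cohort:
    return Cohort(
        individuals=list(cohort.individuals),
        diagnoses=list(cohort.diagnoses) + list(diagnoses),
    )
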