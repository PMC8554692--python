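"""Assignment of Li-Fraumeni spectrum categories.

Carriers of a pathogenic/likely pathogenic (P/LP) germline or germline
mosaic TP53 variant are placed in LFS, attenuated LFS or incidental LFS;
non-carriers with a classic / Chompret-A family presentation are
phenotypic LFS. Variants of uncertain significance, conflicting, likely
benign/benign or unknown classifications do not define spectrum
membership: those individuals are treated as non-carriers here while
remaining in the analysis tables. Suspected clonal hematopoiesis is
excluded from the spectrum outright.

Cancer-free carriers need their relatives' final categories, so cohort
classification runs in two passes and reaches a fixed point.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from lfspectrum.cohort_model import ClinSig, Cohort, Individual, Morphology
from lfspectrum.criteria_engine import (
    CriteriaConfig,
    DEFAULT_CONFIG,
    childhood_cancer,
    meets_chompret_A,
    meets_classic,
    meets_testing_criteria,
)
from lfspectrum.pedigree import Pedigree


class SpectrumCategory(str, enum.Enum):
    LFS = "LFS"
    attenuated_LFS = "attenuated_LFS"
    incidental_LFS = "incidental_LFS"
    phenotypic_LFS = "phenotypic_LFS"
    carrier_cancer_free_LFS_family = "carrier_cancer_free_LFS_family"
    carrier_cancer_free_attenuated_family = "carrier_cancer_free_attenuated_family"
    not_in_spectrum = "not_in_spectrum"


#: Categories defined by carriage of a P/LP variant.
HERITABLE_CATEGORIES = frozenset(
    {
        SpectrumCategory.LFS,
        SpectrumCategory.attenuated_LFS,
        SpectrumCategory.incidental_LFS,
        SpectrumCategory.carrier_cancer_free_LFS_family,
        SpectrumCategory.carrier_cancer_free_attenuated_family,
    }
)

#: Family-summary severity ranking (most severe first).
SEVERITY_ORDER = (
    SpectrumCategory.LFS,
    SpectrumCategory.carrier_cancer_free_LFS_family,
    SpectrumCategory.attenuated_LFS,
    SpectrumCategory.carrier_cancer_free_attenuated_family,
    SpectrumCategory.incidental_LFS,
    SpectrumCategory.phenotypic_LFS,
    SpectrumCategory.not_in_spectrum,
)


@dataclass(frozen=True)
class SpectrumAssignment:
    individual_id: str
    category: SpectrumCategory
    heritable_tp53_related: bool
    rationale: tuple[str, ...] = ()


def is_plp_carrier(ind: Individual) -> bool:
    """P/LP germline or germline mosaic carrier, clonal hematopoiesis
    suspects excluded."""
    v = ind.variant
    return (
        v is not None
        and v.clinsig is ClinSig.P_LP
        and not v.clonal_hematopoiesis_suspected
    )


def _qualifying_extra_tumor(cohort: Cohort, individual_id: str) -> Optional[str]:
    """Additional carrier-associated tumor types that confer LFS on a
    P/LP carrier: osteosarcoma, childhood hypodiploid ALL,
    SHH-medulloblastoma."""
    for d in cohort.diagnoses_of(individual_id):
        if d.morphology is Morphology.osteosarcoma:
            return "osteosarcoma"
        if d.morphology is Morphology.hypodiploid_all and d.age_at_dx < 18:
            return "childhood hypodiploid ALL"
        if d.morphology is Morphology.shh_medulloblastoma:
            return "SHH-medulloblastoma"
    return None


def classify_individual(
    pedigree: Pedigree,
    cohort: Cohort,
    individual: str,
    cfg: CriteriaConfig = DEFAULT_CONFIG,
    relative_categories: Optional[dict[str, SpectrumCategory]] = None,
) -> SpectrumAssignment:
    """Classify one person.

    ``relative_categories`` supplies blood relatives' categories for the
    cancer-free carrier rules; when omitted, a cancer-free carrier whose
    relatives are unknown is classified incidental.
    """
    ind = cohort.individual(individual)
    has_cancer = bool(cohort.diagnoses_of(individual))

    if is_plp_carrier(ind):
        if has_cancer:
            if childhood_cancer(cohort, individual):
                return _make(individual, SpectrumCategory.LFS, "cancer before age 18")
            testing = meets_testing_criteria(pedigree, cohort, individual, cfg)
            if testing.met:
                return _make(
                    individual,
                    SpectrumCategory.LFS,
                    "meets testing criteria: " + ", ".join(testing.trace),
                )
            extra = _qualifying_extra_tumor(cohort, individual)
            if extra is not None:
                return _make(
                    individual, SpectrumCategory.LFS, f"qualifying tumor: {extra}"
                )
            return _make(
                individual,
                SpectrumCategory.attenuated_LFS,
                "carrier with cancer, criteria not met, no cancer before 18",
            )
        # cancer-free carrier: look at blood relatives' categories
        relative_categories = relative_categories or {}
        related = {
            b
            for b in pedigree.members
            if b != individual and pedigree.kinship_degree(individual, b) is not None
        }
        rel_cats = {relative_categories.get(b) for b in related}
        if SpectrumCategory.LFS in rel_cats:
            return _make(
                individual,
                SpectrumCategory.carrier_cancer_free_LFS_family,
                "cancer-free carrier, LFS in the family",
            )
        if SpectrumCategory.attenuated_LFS in rel_cats:
            return _make(
                individual,
                SpectrumCategory.carrier_cancer_free_attenuated_family,
                "cancer-free carrier, attenuated LFS in the family",
            )
        return _make(
            individual,
            SpectrumCategory.incidental_LFS,
            "cancer-free carrier, no LFS/attenuated LFS in the family",
        )

    # non-carrier: phenotypic LFS needs classic or Chompret A
    classic = meets_classic(pedigree, cohort, individual, cfg)
    if classic.met:
        return _make(
            individual, SpectrumCategory.phenotypic_LFS, "classic criteria met"
        )
    cha = meets_chompret_A(pedigree, cohort, individual, cfg)
    if cha.met:
        return _make(
            individual, SpectrumCategory.phenotypic_LFS, "Chompret category A met"
        )
    return _make(
        individual,
        SpectrumCategory.not_in_spectrum,
        "no P/LP variant; classic/Chompret-A not met",
    )


def _make(individual_id: str, category: SpectrumCategory, *why: str) -> SpectrumAssignment:
    return SpectrumAssignment(
        individual_id=individual_id,
        category=category,
        heritable_tp53_related=category in HERITABLE_CATEGORIES,
        rationale=tuple(why),
    )


def classify_cohort(
    cohort: Cohort, cfg: CriteriaConfig = DEFAULT_CONFIG
) -> tuple[dict[str, SpectrumAssignment], dict[str, SpectrumCategory]]:
    """Classify everyone; returns (assignments by id, family summaries).

    Two passes: affected individuals and non-carriers first, then
    cancer-free carriers against their relatives' resolved categories.
    The family summary is the most severe category present.
    """
    pedigrees = Pedigree.from_cohort(cohort)
    assignments: dict[str, SpectrumAssignment] = {}

    for ind in cohort.individuals:
        ped = pedigrees[ind.family_id]
        if is_plp_carrier(ind) and not cohort.diagnoses_of(ind.individual_id):
            continue  # second pass
        assignments[ind.individual_id] = classify_individual(
            ped, cohort, ind.individual_id, cfg
        )

    categories = {i: a.category for i, a in assignments.items()}
    for ind in cohort.individuals:
        if ind.individual_id in assignments:
            continue
        ped = pedigrees[ind.family_id]
        assignments[ind.individual_id] = classify_individual(
            ped, cohort, ind.individual_id, cfg, relative_categories=categories
        )

    family_summary: dict[str, SpectrumCategory] = {}
    rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    for fid in cohort.family_ids():
        cats = [
            assignments[m.individual_id].category
            for m in cohort.family_members(fid)
        ]
        family_summary[fid] = min(cats, key=lambda c: rank[c])
    return assignments, family_summary


@dataclass
class Strata:
    """Partition of the cohort for the two-group tumor-pattern analysis."""

    met_patient_ids: list[str]
    not_met_patient_ids: list[str]
    unaffected_met_family_ids: list[str]
    unaffected_other_ids: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "met_criteria_or_childhood": len(self.met_patient_ids),
            "not_met": len(self.not_met_patient_ids),
            "unaffected_relatives_of_met": len(self.unaffected_met_family_ids),
            "unaffected_other": len(self.unaffected_other_ids),
        }


def stratify_for_analysis(
    cohort: Cohort, cfg: CriteriaConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, pd.DataFrame, Strata]:
    """Split diagnoses into met / not-met case sets.

    The met group holds every individual fulfilling testing criteria or
    with any cancer before 18 (their diagnoses are the met cases); the
    not-met group holds the remaining individuals with cancer. Cancer-
    free individuals contribute no cases and are reported as strata
    counts only.
    """
    pedigrees = Pedigree.from_cohort(cohort)
    met_ids: list[str] = []
    not_met_ids: list[str] = []
    unaffected: list[str] = []
    for ind in cohort.individuals:
        iid = ind.individual_id
        if not cohort.diagnoses_of(iid):
            unaffected.append(iid)
            continue
        ped = pedigrees[ind.family_id]
        if childhood_cancer(cohort, iid) or meets_testing_criteria(
            ped, cohort, iid, cfg
        ):
            met_ids.append(iid)
        else:
            not_met_ids.append(iid)

    met_families = {cohort.individual(i).family_id for i in met_ids}
    unaff_met = [
        i for i in unaffected if cohort.individual(i).family_id in met_families
    ]
    unaff_other = [i for i in unaffected if i not in set(unaff_met)]

    def _cases(ids: list[str]) -> pd.DataFrame:
        idset = set(ids)
        rows = [
            {
                "individual_id": d.individual_id,
                "site": d.site.value,
                "morphology": d.morphology.value if d.morphology else None,
                "age_at_dx": d.age_at_dx,
            }
            for d in cohort.diagnoses
            if d.individual_id in idset
        ]
        return pd.DataFrame(
            rows, columns=["individual_id", "site", "morphology", "age_at_dx"]
        )

    strata = Strata(met_ids, not_met_ids, unaff_met, unaff_other)
    return _cases(met_ids), _cases(not_met_ids), strata


def assignments_to_frame(
    assignments: dict[str, SpectrumAssignment]
) -> pd.DataFrame:
    """One row per person: id, category, heritable flag, joined rationale."""
    rows = [
        {
            "individual_id": a.individual_id,
            "category": a.category.value,
            "heritable_tp53_related": a.heritable_tp53_related,
            "rationale": "; ".join(a.rationale),
        }
        for a in assignments.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["individual_id", "category", "heritable_tp53_related", "rationale"],
    )
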