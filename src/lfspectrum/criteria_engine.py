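"""Clinical genetic-testing criteria for Li-Fraumeni syndrome.

Implements the classic (1988) family-history criteria and the 2015
revision of the Chompret criteria, split into category A (familial
presentation or multiple primary tumors) and category B (specific tumor
types irrespective of family history), plus their union as used for
testing eligibility, and the under-18 childhood-cancer rule.

All age thresholds and tumor lists live in :class:`CriteriaConfig`, so
published variants of the criteria can be swapped without code changes.
Ages gate strictly: "before age N" means ``age_at_dx < N``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from lfspectrum.cohort_model import Cohort, Diagnosis, Morphology, Site
from lfspectrum.pedigree import Pedigree


class Criterion(str, enum.Enum):
    classic = "classic"
    chompret_A = "chompret_A"
    chompret_B = "chompret_B"
    any_testing = "any_testing"
    childhood_cancer = "childhood_cancer"


@dataclass(frozen=True)
class CriteriaResult:
    met: bool
    criterion: Criterion
    trace: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.met


@dataclass
class CriteriaConfig:
    # classic criteria ages
    classic_proband_sarcoma_age: float = 45.0
    classic_relative_age: float = 45.0
    # Chompret ages
    chompret_proband_age: float = 46.0
    chompret_relative_age: float = 56.0
    chompret_breast_age: float = 31.0
    # premenopausal fallback when the flag is absent
    premenopausal_age_fallback: float = 50.0
    # require an explicit anaplastic-subtype flag for category B RMS?
    require_anaplastic_rms: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CriteriaConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def __post_init__(self) -> None:
        for name in (
            "classic_proband_sarcoma_age",
            "classic_relative_age",
            "chompret_proband_age",
            "chompret_relative_age",
            "chompret_breast_age",
            "premenopausal_age_fallback",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = CriteriaConfig()

SARCOMA_SITES = frozenset({Site.soft_tissues, Site.bones})


def is_sarcoma(dx: Diagnosis) -> bool:
    return dx.site in SARCOMA_SITES


def is_premenopausal_breast(dx: Diagnosis, cfg: CriteriaConfig) -> bool:
    if dx.site is not Site.breast:
        return False
    if dx.premenopausal_flag is not None:
        return dx.premenopausal_flag
    return dx.age_at_dx < cfg.premenopausal_age_fallback


def is_core_tumor(dx: Diagnosis, cfg: CriteriaConfig) -> bool:
    """Narrow-spectrum tumor for the Chompret familial/multiple rules:
    premenopausal breast cancer, soft tissue sarcoma, osteosarcoma,
    CNS tumor, or adrenocortical carcinoma."""
    if is_premenopausal_breast(dx, cfg):
        return True
    if dx.site is Site.soft_tissues:
        return True
    if dx.site is Site.bones:
        # osteosarcoma; registry "bones" rows without detail pass too
        return dx.morphology in (None, Morphology.osteosarcoma, Morphology.other)
    if dx.site is Site.brain:
        return True
    if dx.site is Site.adrenal_gland:
        return True
    return False


def _fmt_dx(dx: Diagnosis) -> str:
    morph = f"/{dx.morphology.value}" if dx.morphology else ""
    return f"{dx.site.value}{morph}@{dx.age_at_dx:g}"


def meets_classic(
    pedigree: Pedigree,
    cohort: Cohort,
    proband: str,
    cfg: CriteriaConfig = DEFAULT_CONFIG,
) -> CriteriaResult:
    """Classic criteria: sarcoma proband before 45, a first-degree
    relative with any cancer before 45, and an additional first- or
    second-degree relative with cancer before 45 or sarcoma at any age.
    """
    trace: list[str] = []
    proband_sarcomas = [
        d
        for d in cohort.diagnoses_of(proband)
        if is_sarcoma(d) and d.age_at_dx < cfg.classic_proband_sarcoma_age
    ]
    if not proband_sarcomas:
        return CriteriaResult(False, Criterion.classic)
    trace.append(f"proband {proband}: {_fmt_dx(proband_sarcomas[0])}")

    first_degree = pedigree.relatives_within_degree(proband, 1)
    second_or_first = pedigree.relatives_within_degree(proband, 2)

    fd_hit: Optional[str] = None
    for rel in sorted(first_degree):
        for d in cohort.diagnoses_of(rel):
            if d.age_at_dx < cfg.classic_relative_age:
                fd_hit = rel
                trace.append(f"first-degree relative {rel}: {_fmt_dx(d)}")
                break
        if fd_hit:
            break
    if fd_hit is None:
        return CriteriaResult(False, Criterion.classic)

    for rel in sorted(second_or_first - {fd_hit}):
        for d in cohort.diagnoses_of(rel):
            if d.age_at_dx < cfg.classic_relative_age or is_sarcoma(d):
                trace.append(
                    f"additional 1st/2nd-degree relative {rel}: {_fmt_dx(d)}"
                )
                return CriteriaResult(True, Criterion.classic, tuple(trace))
    return CriteriaResult(False, Criterion.classic)


def _core_primary_count(diagnoses: list[Diagnosis], cfg: CriteriaConfig) -> int:
    """Count core primaries for the multiple-tumor rule; multiple breast
    tumors collapse to one so that several breast primaries alone never
    qualify."""
    core = [d for d in diagnoses if is_core_tumor(d, cfg)]
    breast = [d for d in core if d.site is Site.breast]
    other = [d for d in core if d.site is not Site.breast]
    return len(other) + min(1, len(breast))


def meets_chompret_A(
    pedigree: Pedigree,
    cohort: Cohort,
    proband: str,
    cfg: CriteriaConfig = DEFAULT_CONFIG,
) -> CriteriaResult:
    """Chompret category A: familial presentation or multiple primaries.

    (i) a core tumor in the proband before 46 plus a first- or
    second-degree relative with a core tumor before 56 or with multiple
    tumors; or (ii) multiple primaries in the proband (multiple breast
    tumors excepted), at least two of them core, the first before 46.
    """
    trace: list[str] = []
    dxs = cohort.diagnoses_of(proband)

    # (i) familial presentation
    proband_core = [
        d
        for d in dxs
        if is_core_tumor(d, cfg) and d.age_at_dx < cfg.chompret_proband_age
    ]
    if proband_core:
        for rel in sorted(pedigree.relatives_within_degree(proband, 2)):
            rel_dxs = cohort.diagnoses_of(rel)
            rel_core = [
                d
                for d in rel_dxs
                if is_core_tumor(d, cfg)
                and d.age_at_dx < cfg.chompret_relative_age
            ]
            if rel_core:
                trace.append(f"proband {proband}: {_fmt_dx(proband_core[0])}")
                trace.append(f"relative {rel}: {_fmt_dx(rel_core[0])}")
                return CriteriaResult(True, Criterion.chompret_A, tuple(trace))
            if len(rel_dxs) >= 2:
                trace.append(f"proband {proband}: {_fmt_dx(proband_core[0])}")
                trace.append(f"relative {rel}: multiple tumors")
                return CriteriaResult(True, Criterion.chompret_A, tuple(trace))

    # (ii) multiple primaries
    if len(dxs) >= 2 and _core_primary_count(dxs, cfg) >= 2:
        first = dxs[0]  # diagnoses_of sorts by age
        if first.age_at_dx < cfg.chompret_proband_age:
            trace.append(
                f"proband {proband}: multiple core primaries, first "
                f"{_fmt_dx(first)}"
            )
            return CriteriaResult(True, Criterion.chompret_A, tuple(trace))
    return CriteriaResult(False, Criterion.chompret_A)


def meets_chompret_B(
    cohort: Cohort,
    proband: str,
    cfg: CriteriaConfig = DEFAULT_CONFIG,
) -> CriteriaResult:
    """Chompret category B: specific tumor types, family history ignored.

    Adrenocortical carcinoma or choroid plexus carcinoma at any age,
    anaplastic embryonal rhabdomyosarcoma at any age, or breast cancer
    before 31.
    """
    trace: list[str] = []
    for d in cohort.diagnoses_of(proband):
        if d.site is Site.adrenal_gland:
            trace.append(f"adrenocortical carcinoma: {_fmt_dx(d)}")
        elif d.morphology is Morphology.choroid_plexus_carcinoma:
            trace.append(f"choroid plexus carcinoma: {_fmt_dx(d)}")
        elif (
            d.morphology is Morphology.rhabdomyosarcoma
            and not cfg.require_anaplastic_rms
        ):
            # morphology coding cannot distinguish the anaplastic
            # embryonal subtype; qualify any RMS unless configured off
            trace.append(f"rhabdomyosarcoma: {_fmt_dx(d)}")
        elif d.site is Site.breast and d.age_at_dx < cfg.chompret_breast_age:
            trace.append(f"early-onset breast cancer: {_fmt_dx(d)}")
    return CriteriaResult(bool(trace), Criterion.chompret_B, tuple(trace))


def meets_testing_criteria(
    pedigree: Pedigree,
    cohort: Cohort,
    proband: str,
    cfg: CriteriaConfig = DEFAULT_CONFIG,
) -> CriteriaResult:
    """Union of classic, Chompret A and Chompret B, in that order."""
    trace: list[str] = []
    results = (
        meets_classic(pedigree, cohort, proband, cfg),
        meets_chompret_A(pedigree, cohort, proband, cfg),
        meets_chompret_B(cohort, proband, cfg),
    )
    for res in results:
        if res.met:
            trace.append(res.criterion.value)
    return CriteriaResult(bool(trace), Criterion.any_testing, tuple(trace))


def childhood_cancer(cohort: Cohort, individual: str, age_limit: float = 18.0) -> bool:
    """True iff any diagnosis occurred strictly before ``age_limit``."""
    return any(d.age_at_dx < age_limit for d in cohort.diagnoses_of(individual))
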