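"""Synthetic family-history generator.

Builds cohorts of two-to-three generation families from templates that
force a known criteria/classification outcome by construction — a
classic-pattern sarcoma family, a Chompret-A familial presentation, a
category-B-only presentation without a qualifying variant, an attenuated
adult-onset carrier, a cancer-free incidental-finding family, a p.R337H
founder family, and a variant-negative phenotypic family — so the rule
engine and the two-group statistics can be exercised end-to-end with no
external data.

Tumor types follow the age-phase structure of the syndrome: a childhood
phase (0-15: adrenocortical carcinoma, choroid plexus carcinoma,
rhabdomyosarcoma, medulloblastoma), a childhood-to-young-adult
transition (osteosarcoma, leukemia, glioma; ages 10-25 by default — the
bounds of this phase are an assumption, configurable), an early
adulthood phase (16-50: breast, gastrointestinal and lung cancer,
sarcomas) and a late adulthood phase (51-80: pancreatic and prostate
cancer). Ages are sampled uniformly within the phase window.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

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
from lfspectrum.criteria_engine import CriteriaConfig, DEFAULT_CONFIG
from lfspectrum.spectrum_classifier import (
    SpectrumCategory,
    classify_cohort,
)


class FamilyTemplate(str, enum.Enum):
    classic_LFS = "classic_LFS"
    chompret_A = "chompret_A"
    chompret_B_only = "chompret_B_only"
    attenuated = "attenuated"
    incidental = "incidental"
    founder_r337h = "founder_r337h"
    phenotypic_no_variant = "phenotypic_no_variant"


#: Family-summary category each template is built to produce.
TEMPLATE_EXPECTED_CATEGORY = {
    FamilyTemplate.classic_LFS: SpectrumCategory.LFS,
    FamilyTemplate.chompret_A: SpectrumCategory.LFS,
    FamilyTemplate.chompret_B_only: SpectrumCategory.not_in_spectrum,
    FamilyTemplate.attenuated: SpectrumCategory.attenuated_LFS,
    FamilyTemplate.incidental: SpectrumCategory.incidental_LFS,
    FamilyTemplate.founder_r337h: SpectrumCategory.LFS,
    FamilyTemplate.phenotypic_no_variant: SpectrumCategory.phenotypic_LFS,
}

#: Age phases -> (window, categorical tumor distribution).
DEFAULT_PHASES: dict[str, dict] = {
    "childhood": {
        "window": (0.0, 15.0),
        "tumors": [
            (Site.adrenal_gland, None, 0.25),
            (Site.brain, Morphology.choroid_plexus_carcinoma, 0.2),
            (Site.soft_tissues, Morphology.rhabdomyosarcoma, 0.35),
            (Site.brain, Morphology.medulloblastoma, 0.2),
        ],
    },
    "transition": {
        # numeric bounds for this phase are not published; 10-25 assumed
        "window": (10.0, 25.0),
        "tumors": [
            (Site.bones, Morphology.osteosarcoma, 0.4),
            (Site.hematopoietic, None, 0.3),
            (Site.brain, Morphology.glioblastoma_glioma, 0.3),
        ],
    },
    "early_adult": {
        "window": (16.0, 50.0),
        "tumors": [
            (Site.breast, Morphology.breast_carcinoma, 0.4),
            (Site.colon_rectum, None, 0.15),
            (Site.stomach, None, 0.1),
            (Site.lung, None, 0.15),
            (Site.soft_tissues, Morphology.leiomyosarcoma, 0.1),
            (Site.soft_tissues, Morphology.sarcoma_nos, 0.1),
        ],
    },
    "late_adult": {
        "window": (51.0, 80.0),
        "tumors": [
            (Site.pancreas, None, 0.5),
            (Site.prostate, None, 0.5),
        ],
    },
}

#: Default P/LP pool: hotspot missense plus variants reported only in
#: fully expressed disease; p.R110L is the attenuated-associated allele.
DEFAULT_PLP_POOL = [
    "p.R175H", "p.G245S", "p.R248Q", "p.R248W", "p.R273H", "p.R282W",
    "p.M133T", "p.P152L", "p.C275Y", "p.C275*", "p.R337C", "p.R342*",
    "p.R342P",
]
ATTENUATED_POOL = ["p.R110L", "p.R273H", "p.R248Q"]
VUS_POOL = ["p.E285K", "p.N235S", "p.V31I"]


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_families: int = 50
    seed: int = 0
    template_mixture: dict[str, float] = field(
        default_factory=lambda: {
            FamilyTemplate.classic_LFS.value: 0.2,
            FamilyTemplate.chompret_A.value: 0.2,
            FamilyTemplate.chompret_B_only.value: 0.1,
            FamilyTemplate.attenuated.value: 0.2,
            FamilyTemplate.incidental.value: 0.1,
            FamilyTemplate.founder_r337h.value: 0.1,
            FamilyTemplate.phenotypic_no_variant.value: 0.1,
        }
    )
    #: per-carrier probability of an extra phase tumor (criteria-forcing
    #: templates only; additive tumors cannot break their guarantees)
    penetrance_by_phase: dict[str, float] = field(
        default_factory=lambda: {
            "childhood": 0.05,
            "transition": 0.05,
            "early_adult": 0.15,
            "late_adult": 0.05,
        }
    )
    phases: dict[str, dict] = field(default_factory=lambda: DEFAULT_PHASES)

    def __post_init__(self) -> None:
        if self.n_families < 0:
            raise SimConfigError("n_families must be non-negative")
        total = sum(self.template_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(
                f"template mixture must sum to 1, got {total}"
            )
        for name in self.template_mixture:
            FamilyTemplate(name)  # raises on unknown template
        for phase, spec_ in self.phases.items():
            w = sum(t[2] for t in spec_["tumors"])
            if abs(w - 1.0) > 1e-9:
                raise SimConfigError(
                    f"phase {phase!r} tumor distribution must sum to 1"
                )

    def to_yaml(self, path) -> None:
        data = {
            "n_families": self.n_families,
            "seed": self.seed,
            "template_mixture": dict(self.template_mixture),
            "penetrance_by_phase": dict(self.penetrance_by_phase),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# family construction


class _FamilyBuilder:
    """Accumulates one family's members and diagnoses."""

    def __init__(self, family_id: str):
        self.family_id = family_id
        self.individuals: list[Individual] = []
        self.diagnoses: list[Diagnosis] = []
        self._n = 0

    def add(
        self,
        sex: Sex,
        father: Optional[str] = None,
        mother: Optional[str] = None,
        variant: Optional[VariantCall] = None,
        proband: bool = False,
    ) -> str:
        self._n += 1
        iid = f"{self.family_id}-{self._n}"
        self.individuals.append(
            Individual(
                individual_id=iid,
                family_id=self.family_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                variant=variant,
                is_proband=proband,
            )
        )
        return iid

    def diagnose(
        self,
        iid: str,
        site: Site,
        age: float,
        morphology: Optional[Morphology] = None,
        premenopausal: Optional[bool] = None,
    ) -> None:
        self.diagnoses.append(
            Diagnosis(
                individual_id=iid,
                site=site,
                morphology=morphology,
                age_at_dx=round(float(age), 1),
                premenopausal_flag=premenopausal,
            )
        )


def _plp(rng: np.random.Generator, pool: Sequence[str]) -> VariantCall:
    return VariantCall(
        hgvs_p=str(rng.choice(pool)), clinsig=ClinSig.P_LP
    )


def _nuclear(
    b: _FamilyBuilder,
    rng: np.random.Generator,
    carrier_variant: Optional[VariantCall],
    with_grandparents: bool = True,
) -> dict[str, str]:
    """Standard scaffold: (grandparents ->) father + uncle, married-in
    mother, proband and sibling. The carrier lineage is paternal."""
    ids: dict[str, str] = {}
    gf = gm = None
    if with_grandparents:
        gf = b.add(Sex.male, variant=carrier_variant)
        gm = b.add(Sex.female)
        ids["grandfather"], ids["grandmother"] = gf, gm
    father = b.add(Sex.male, father=gf, mother=gm, variant=carrier_variant)
    mother = b.add(Sex.female)
    ids["father"], ids["mother"] = father, mother
    if with_grandparents:
        ids["uncle"] = b.add(Sex.male, father=gf, mother=gm)
    proband_sex = Sex.female if rng.random() < 0.5 else Sex.male
    ids["proband"] = b.add(
        proband_sex, father=father, mother=mother,
        variant=carrier_variant, proband=True,
    )
    ids["sibling"] = b.add(
        Sex.male if proband_sex is Sex.female else Sex.female,
        father=father, mother=mother,
    )
    return ids


def _build_family(
    b: _FamilyBuilder, template: FamilyTemplate, rng: np.random.Generator
) -> None:
    if template is FamilyTemplate.classic_LFS:
        variant = _plp(rng, DEFAULT_PLP_POOL)
        ids = _nuclear(b, rng, variant)
        # proband sarcoma <45, first-degree relative cancer <45,
        # additional second-degree relative with sarcoma: classic by
        # construction
        b.diagnose(
            ids["proband"], Site.soft_tissues,
            rng.uniform(2, 12), Morphology.rhabdomyosarcoma,
        )
        b.diagnose(ids["father"], Site.colon_rectum, rng.uniform(25, 44))
        b.diagnose(
            ids["uncle"], Site.bones, rng.uniform(12, 30), Morphology.osteosarcoma
        )
    elif template is FamilyTemplate.chompret_A:
        variant = _plp(rng, DEFAULT_PLP_POOL)
        ids = _nuclear(b, rng, variant)
        # premenopausal breast proband <46 plus core tumor <56 in a
        # first-degree relative
        b.diagnose(
            ids["proband"], Site.breast, rng.uniform(25, 40),
            Morphology.breast_carcinoma, premenopausal=True,
        )
        b.diagnose(
            ids["father"], Site.soft_tissues, rng.uniform(20, 50),
            Morphology.leiomyosarcoma,
        )
    elif template is FamilyTemplate.chompret_B_only:
        # adrenocortical carcinoma, no family history, no P/LP variant:
        # meets only category B, hence outside the spectrum
        vus = VariantCall(hgvs_p=str(rng.choice(VUS_POOL)), clinsig=ClinSig.VUS)
        ids = _nuclear(b, rng, None, with_grandparents=False)
        proband = ids["proband"]
        b.individuals = [
            ind if ind.individual_id != proband
            else Individual(
                individual_id=ind.individual_id, family_id=ind.family_id,
                father_id=ind.father_id, mother_id=ind.mother_id,
                sex=ind.sex, variant=vus, is_proband=True,
            )
            for ind in b.individuals
        ]
        b.diagnose(proband, Site.adrenal_gland, rng.uniform(0.5, 10))
    elif template is FamilyTemplate.attenuated:
        variant = _plp(rng, ATTENUATED_POOL)
        ids = _nuclear(b, rng, variant, with_grandparents=False)
        # single adult-onset postmenopausal breast cancer, cancer-free
        # relatives: no criterion fires, no cancer before 18
        b.diagnose(
            ids["proband"], Site.breast, rng.uniform(52, 70),
            Morphology.breast_carcinoma, premenopausal=False,
        )
    elif template is FamilyTemplate.incidental:
        variant = _plp(rng, DEFAULT_PLP_POOL)
        _nuclear(b, rng, variant, with_grandparents=False)
        # no diagnoses at all
    elif template is FamilyTemplate.founder_r337h:
        variant = VariantCall(hgvs_p="p.R337H", clinsig=ClinSig.P_LP)
        ids = _nuclear(b, rng, variant)
        b.diagnose(ids["proband"], Site.adrenal_gland, rng.uniform(0.5, 6))
    elif template is FamilyTemplate.phenotypic_no_variant:
        ids = _nuclear(b, rng, None)
        b.diagnose(
            ids["proband"], Site.soft_tissues,
            rng.uniform(5, 30), Morphology.fibrosarcoma,
        )
        b.diagnose(ids["mother"], Site.breast, rng.uniform(28, 44))
        b.diagnose(
            ids["uncle"], Site.soft_tissues, rng.uniform(30, 60),
            Morphology.sarcoma_nos,
        )
    else:  # pragma: no cover
        raise SimConfigError(f"unknown template {template}")


_EXTRA_TUMOR_TEMPLATES = {
    FamilyTemplate.classic_LFS,
    FamilyTemplate.chompret_A,
    FamilyTemplate.founder_r337h,
}


def _extra_phase_tumors(
    b: _FamilyBuilder, cfg: SimConfig, rng: np.random.Generator
) -> None:
    """Sprinkle phase-distributed tumors on carriers; only applied where
    additional tumors cannot change the family's intended outcome."""
    carriers = [
        i.individual_id
        for i in b.individuals
        if i.variant is not None and i.variant.clinsig is ClinSig.P_LP
    ]
    for iid in carriers:
        for phase, pen in cfg.penetrance_by_phase.items():
            if rng.random() >= pen:
                continue
            spec_ = cfg.phases[phase]
            tumors = spec_["tumors"]
            weights = np.array([t[2] for t in tumors], dtype=float)
            idx = int(rng.choice(len(tumors), p=weights / weights.sum()))
            site, morph, _ = tumors[idx]
            lo, hi = spec_["window"]
            b.diagnose(iid, site, rng.uniform(lo, hi), morph)


def generate(cfg: SimConfig) -> tuple[Cohort, dict[str, str]]:
    """Generate a cohort; returns it with per-family ground-truth labels.

    Deterministic for a fixed config (seed included): the same config
    yields an identical cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = sorted(cfg.template_mixture)
    probs = np.array([cfg.template_mixture[t] for t in templates])
    individuals: list[Individual] = []
    diagnoses: list[Diagnosis] = []
    labels: dict[str, str] = {}
    for i in range(cfg.n_families):
        fid = f"F{i + 1:04d}"
        template = FamilyTemplate(str(rng.choice(templates, p=probs)))
        b = _FamilyBuilder(fid)
        _build_family(b, template, rng)
        if template in _EXTRA_TUMOR_TEMPLATES:
            _extra_phase_tumors(b, cfg, rng)
        individuals.extend(b.individuals)
        diagnoses.extend(b.diagnoses)
        labels[fid] = template.value
    return Cohort(individuals=individuals, diagnoses=diagnoses), labels


def recovery_report(
    cohort: Cohort,
    labels: dict[str, str],
    criteria_cfg: CriteriaConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Confusion table: intended template vs classified family summary.

    One row per (template, assigned family category) with counts and the
    per-template recovery rate (fraction of that template's families
    whose summary matches the template's intended category).
    """
    _, family_summary = classify_cohort(cohort, criteria_cfg)
    rows = []
    for fid, template_name in labels.items():
        template = FamilyTemplate(template_name)
        rows.append(
            {
                "family_id": fid,
                "template": template.value,
                "assigned": family_summary[fid].value,
                "expected": TEMPLATE_EXPECTED_CATEGORY[template].value,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["template", "assigned"], as_index=False)
        .agg(n=("family_id", "count"))
    )
    recovery = (
        df.assign(hit=df["assigned"] == df["expected"])
        .groupby("template")["hit"]
        .mean()
        .rename("recovery_rate")
    )
    return out.merge(recovery, on="template")
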