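"""Domain types and table IO for pedigree-structured cancer cohorts.

Two delimited tables describe a cohort: an *individuals* table (one row
per person, with family links, sex and germline TP53 variant call) and a
long-format *diagnoses* table (one row per tumor event). The enums here
are the closed vocabulary used by the tabulation and criteria layers.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

INDIVIDUAL_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "hgvs_p",
    "clinsig",
    "mosaic",
    "clonal_hematopoiesis",
    "proband",
]
DIAGNOSIS_COLUMNS = [
    "individual_id",
    "site",
    "morphology",
    "age_at_dx",
    "premenopausal",
]


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed value."""


class IntegrityError(ValueError):
    """A reference (parent or diagnosis) does not resolve."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Site(str, enum.Enum):
    """Organ/tissue vocabulary (one member per tabulated organ row)."""

    breast = "breast"
    soft_tissues = "soft_tissues"
    adrenal_gland = "adrenal_gland"
    brain = "brain"
    bones = "bones"
    hematopoietic = "hematopoietic"
    lung = "lung"
    colon_rectum = "colon_rectum"
    ovary = "ovary"
    liver = "liver"
    prostate = "prostate"
    skin = "skin"
    stomach = "stomach"
    kidney = "kidney"
    pancreas = "pancreas"
    not_specified = "not_specified"


class Morphology(str, enum.Enum):
    """Histology vocabulary for sarcoma/brain detail rows."""

    fibrosarcoma = "fibrosarcoma"
    leiomyosarcoma = "leiomyosarcoma"
    liposarcoma = "liposarcoma"
    rhabdomyosarcoma = "rhabdomyosarcoma"
    malignant_fibrous_histiocytoma = "malignant_fibrous_histiocytoma"
    sarcoma_other = "sarcoma_other"
    sarcoma_nos = "sarcoma_nos"
    astrocytoma = "astrocytoma"
    choroid_plexus_carcinoma = "choroid_plexus_carcinoma"
    ependymoma = "ependymoma"
    glioblastoma_glioma = "glioblastoma_glioma"
    medulloblastoma = "medulloblastoma"
    pnet = "pnet"
    brain_other = "brain_other"
    cancer_nos = "cancer_nos"
    osteosarcoma = "osteosarcoma"
    hypodiploid_all = "hypodiploid_all"
    shh_medulloblastoma = "shh_medulloblastoma"
    breast_carcinoma = "breast_carcinoma"
    other = "other"


class ClinSig(str, enum.Enum):
    P_LP = "P_LP"
    VUS = "VUS"
    conflicting = "conflicting"
    LB_B = "LB_B"
    unknown = "unknown"


#: Required site per morphology; ``None`` means any site is admissible.
MORPHOLOGY_SITE: dict[Morphology, Optional[Site]] = {
    Morphology.fibrosarcoma: Site.soft_tissues,
    Morphology.leiomyosarcoma: Site.soft_tissues,
    Morphology.liposarcoma: Site.soft_tissues,
    Morphology.rhabdomyosarcoma: Site.soft_tissues,
    Morphology.malignant_fibrous_histiocytoma: Site.soft_tissues,
    Morphology.sarcoma_other: Site.soft_tissues,
    Morphology.sarcoma_nos: Site.soft_tissues,
    Morphology.astrocytoma: Site.brain,
    Morphology.choroid_plexus_carcinoma: Site.brain,
    Morphology.ependymoma: Site.brain,
    Morphology.glioblastoma_glioma: Site.brain,
    Morphology.medulloblastoma: Site.brain,
    Morphology.pnet: Site.brain,
    Morphology.brain_other: Site.brain,
    Morphology.shh_medulloblastoma: Site.brain,
    Morphology.osteosarcoma: Site.bones,
    Morphology.hypodiploid_all: Site.hematopoietic,
    Morphology.breast_carcinoma: Site.breast,
    Morphology.cancer_nos: None,
    Morphology.other: None,
}


@dataclass(frozen=True)
class VariantCall:
    """A germline TP53 variant in protein (HGVS p.) shorthand."""

    hgvs_p: str
    clinsig: ClinSig = ClinSig.unknown
    mosaic: bool = False
    clonal_hematopoiesis_suspected: bool = False


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.unknown
    variant: Optional[VariantCall] = None
    is_proband: bool = False


@dataclass(frozen=True)
class Diagnosis:
    """One tumor event attached to an individual.

    ``premenopausal_flag`` only applies to breast cancers and may be
    missing, in which case age-based fallbacks decide menopausal status
    downstream.
    """

    individual_id: str
    site: Site
    age_at_dx: float
    morphology: Optional[Morphology] = None
    premenopausal_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_at_dx < 0:
            raise SchemaError(
                f"age_at_dx must be non-negative, got {self.age_at_dx!r} "
                f"for individual {self.individual_id!r}"
            )
        if self.morphology is not None:
            required = MORPHOLOGY_SITE.get(self.morphology)
            if required is not None and required is not self.site:
                raise SchemaError(
                    f"morphology {self.morphology.value} requires site "
                    f"{required.value}, got {self.site.value} "
                    f"(individual {self.individual_id!r})"
                )


@dataclass
class Cohort:
    individuals: list[Individual] = field(default_factory=list)
    diagnoses: list[Diagnosis] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------

    def individual(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise IntegrityError(f"unknown individual {individual_id!r}") from None

    def diagnoses_of(self, individual_id: str) -> list[Diagnosis]:
        """All diagnoses of one person, sorted by age at diagnosis."""
        return sorted(
            (d for d in self.diagnoses if d.individual_id == individual_id),
            key=lambda d: d.age_at_dx,
        )

    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def family_members(self, family_id: str) -> list[Individual]:
        return [i for i in self.individuals if i.family_id == family_id]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        ids = [i.individual_id for i in self.individuals]
        self._by_id = {i.individual_id: i for i in self.individuals}
        if len(ids) != len(self._by_id):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise IntegrityError(f"duplicate individual ids: {dupes}")
        dangling: list[str] = []
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None or parent.family_id != ind.family_id:
                    dangling.append(pid)
        for dx in self.diagnoses:
            if dx.individual_id not in self._by_id:
                dangling.append(dx.individual_id)
        if dangling:
            raise IntegrityError(
                f"unresolved references: {sorted(set(dangling))}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bool(value: str, column: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes", "t"}:
        return True
    if v in {"false", "0", "no", "f", ""}:
        return False
    raise SchemaError(f"cannot parse boolean {value!r} in column {column!r}")


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _read_table(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_cohort(individuals_path, diagnoses_path) -> Cohort:
    """Load and validate a cohort from the two-table CSV schema.

    Unknown site/morphology strings are coerced to ``not_specified`` /
    ``other`` with a logged warning; missing columns raise
    :class:`SchemaError` and dangling references :class:`IntegrityError`.
    """
    idf = _read_table(individuals_path, INDIVIDUAL_COLUMNS)
    ddf = _read_table(diagnoses_path, DIAGNOSIS_COLUMNS)

    individuals = []
    for row in idf.itertuples(index=False):
        hgvs = _opt(row.hgvs_p)
        variant = None
        if hgvs is not None or _opt(row.clinsig) is not None:
            clinsig_raw = _opt(row.clinsig) or "unknown"
            try:
                clinsig = ClinSig(clinsig_raw)
            except ValueError:
                logger.warning("unknown clinsig %r -> unknown", clinsig_raw)
                clinsig = ClinSig.unknown
            variant = VariantCall(
                hgvs_p=hgvs or "",
                clinsig=clinsig,
                mosaic=_parse_bool(row.mosaic, "mosaic"),
                clonal_hematopoiesis_suspected=_parse_bool(
                    row.clonal_hematopoiesis, "clonal_hematopoiesis"
                ),
            )
        sex_raw = _opt(row.sex) or "unknown"
        try:
            sex = Sex(sex_raw.lower())
        except ValueError:
            logger.warning("unknown sex %r -> unknown", sex_raw)
            sex = Sex.unknown
        individuals.append(
            Individual(
                individual_id=str(row.individual_id),
                family_id=str(row.family_id),
                father_id=_opt(row.father_id),
                mother_id=_opt(row.mother_id),
                sex=sex,
                variant=variant,
                is_proband=_parse_bool(row.proband, "proband"),
            )
        )

    diagnoses = []
    for row in ddf.itertuples(index=False):
        site_raw = _opt(row.site) or "not_specified"
        try:
            site = Site(site_raw)
        except ValueError:
            logger.warning("unknown site %r -> not_specified", site_raw)
            site = Site.not_specified
        morph_raw = _opt(row.morphology)
        morphology: Optional[Morphology] = None
        if morph_raw is not None:
            try:
                morphology = Morphology(morph_raw)
            except ValueError:
                logger.warning("unknown morphology %r -> other", morph_raw)
                morphology = Morphology.other
        try:
            age = float(row.age_at_dx)
        except ValueError:
            raise SchemaError(
                f"cannot parse age_at_dx {row.age_at_dx!r}"
            ) from None
        premeno_raw = _opt(row.premenopausal)
        diagnoses.append(
            Diagnosis(
                individual_id=str(row.individual_id),
                site=site,
                morphology=morphology,
                age_at_dx=age,
                premenopausal_flag=(
                    None
                    if premeno_raw is None
                    else _parse_bool(premeno_raw, "premenopausal")
                ),
            )
        )
    return Cohort(individuals=individuals, diagnoses=diagnoses)


def _fmt_bool(b: Optional[bool]) -> str:
    if b is None:
        return ""
    return "true" if b else "false"


def write_cohort(cohort: Cohort, out_dir) -> tuple[str, str]:
    """Write the two-table CSV schema; inverse of :func:`read_cohort`."""
    os.makedirs(out_dir, exist_ok=True)
    ipath = os.path.join(out_dir, "individuals.csv")
    dpath = os.path.join(out_dir, "diagnoses.csv")

    irows = []
    for ind in cohort.individuals:
        v = ind.variant
        irows.append(
            {
                "family_id": ind.family_id,
                "individual_id": ind.individual_id,
                "father_id": ind.father_id or "",
                "mother_id": ind.mother_id or "",
                "sex": ind.sex.value,
                "hgvs_p": v.hgvs_p if v else "",
                "clinsig": v.clinsig.value if v else "",
                "mosaic": _fmt_bool(v.mosaic) if v else "",
                "clonal_hematopoiesis": (
                    _fmt_bool(v.clonal_hematopoiesis_suspected) if v else ""
                ),
                "proband": _fmt_bool(ind.is_proband),
            }
        )
    drows = []
    for dx in cohort.diagnoses:
        drows.append(
            {
                "individual_id": dx.individual_id,
                "site": dx.site.value,
                "morphology": dx.morphology.value if dx.morphology else "",
                "age_at_dx": repr(float(dx.age_at_dx)),
                "premenopausal": _fmt_bool(dx.premenopausal_flag),
            }
        )
    pd.DataFrame(irows, columns=INDIVIDUAL_COLUMNS).to_csv(ipath, index=False)
    pd.DataFrame(drows, columns=DIAGNOSIS_COLUMNS).to_csv(dpath, index=False)
    return ipath, dpath


def write_ped(cohort: Cohort, path) -> str:
    """Export a PED-dialect file (family, id, father, mother, sex, affection)."""
    sex_code = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}
    affected = {d.individual_id for d in cohort.diagnoses}
    with open(path, "w", encoding="utf-8") as fh:
        for ind in cohort.individuals:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_code[ind.sex],
                        "2" if ind.individual_id in affected else "1",
                    ]
                )
                + "\n"
            )
    return str(path)
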