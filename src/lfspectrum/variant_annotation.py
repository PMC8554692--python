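"""TP53 protein-shorthand variant parsing and annotation.

Handles the HGVS p. notations used in germline TP53 registries:
``p.R337H`` (missense), ``p.C275*`` (nonsense) and codon-only mentions
like ``p.R175``. Three-letter residue names (``p.Arg337His``) are
normalized to one-letter form. Annotation covers the recurrent hotspot
codons, protein domains, and the cohort-level exclusion filters
(Brazilian p.R337H founder carriers; suspected clonal hematopoiesis).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Optional

from lfspectrum.cohort_model import Cohort

TP53_LENGTH = 393

#: Recurrently mutated codons seen in both met/not-met testing groups.
HOTSPOT_CODONS = frozenset({175, 245, 248, 273, 282})

FOUNDER_R337H = "p.R337H"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "TER": "*",
}

_ONE = r"[ACDEFGHIKLMNPQRSTVWY]"
_THREE = r"(?:%s)" % "|".join(AA3_TO_1)
_PATTERN = re.compile(
    rf"^(?:P\.)?"
    rf"(?P<ref>{_ONE}|{_THREE})"
    rf"(?P<codon>\d+)"
    rf"(?P<alt>{_ONE}|{_THREE}|\*|X)?$",
    re.IGNORECASE,
)


class VariantParseError(ValueError):
    def __init__(self, text: str, reason: str = "unrecognized HGVS p. form"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


class VariantKind(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    codon_only = "codon_only"


@dataclass(frozen=True)
class ParsedVariant:
    ref_aa: str
    codon: int
    alt: Optional[str]  # one-letter AA, "*", or None for codon-only
    kind: VariantKind

    def __post_init__(self) -> None:
        if not 1 <= self.codon <= TP53_LENGTH:
            raise VariantParseError(
                str(self.codon), f"codon outside 1..{TP53_LENGTH}"
            )

    def format(self) -> str:
        """Canonical one-letter shorthand, inverse of :func:`parse_hgvs_p`."""
        return f"p.{self.ref_aa}{self.codon}{self.alt or ''}"


def _norm_aa(token: str) -> str:
    token = token.upper()
    if token in {"*", "X"}:
        return "*"
    if len(token) == 1:
        return token
    return AA3_TO_1[token]


def parse_hgvs_p(text: str) -> ParsedVariant:
    """Parse protein-level shorthand into a structured record.

    Accepts missense (``p.R337H``), nonsense (``p.C275*``) and
    codon-only (``p.R175``) forms, with or without the ``p.`` prefix,
    case-insensitively, in one- or three-letter residue notation.
    """
    if not text or not text.strip():
        raise VariantParseError(text, "empty input")
    m = _PATTERN.match(text.strip())
    if m is None:
        raise VariantParseError(text)
    ref = _norm_aa(m.group("ref"))
    if ref == "*":
        raise VariantParseError(text, "reference residue cannot be a stop")
    alt = m.group("alt")
    alt = _norm_aa(alt) if alt is not None else None
    if alt is None:
        kind = VariantKind.codon_only
    elif alt == "*":
        kind = VariantKind.nonsense
    else:
        kind = VariantKind.missense
    return ParsedVariant(ref_aa=ref, codon=int(m.group("codon")), alt=alt, kind=kind)


def is_hotspot(v: ParsedVariant) -> bool:
    """True iff the variant sits on one of the recurrent hotspot codons."""
    return v.codon in HOTSPOT_CODONS


def is_founder_r337h(hgvs_p: str) -> bool:
    try:
        v = parse_hgvs_p(hgvs_p)
    except VariantParseError:
        return False
    return v.format() == FOUNDER_R337H


# ---------------------------------------------------------------------------
# protein domains


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping codon intervals labelled TAD/PR/DNAB/OD/CT."""

    intervals: tuple[tuple[str, int, int], ...]

    LABELS = ("TAD", "PR", "DNAB", "OD", "CT")

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.intervals]
        if sorted(labels) != sorted(self.LABELS):
            raise ValueError(f"domain labels must be exactly {self.LABELS}")
        prev_end = 0
        for lab, start, end in self.intervals:
            if not (prev_end < start <= end <= TP53_LENGTH):
                raise ValueError(
                    f"interval {lab} [{start},{end}] overlaps or is out of order"
                )
            prev_end = end

    @classmethod
    def default(cls) -> "DomainMap":
        # canonical TP53 domain boundaries (UniProt P04637)
        return cls(
            intervals=(
                ("TAD", 1, 61),
                ("PR", 64, 92),
                ("DNAB", 94, 312),
                ("OD", 323, 356),
                ("CT", 364, 393),
            )
        )

    @classmethod
    def from_rows(cls, rows) -> "DomainMap":
        """Build from (label, start, end) rows, e.g. a config CSV."""
        return cls(
            intervals=tuple(
                sorted(
                    ((str(l), int(s), int(e)) for l, s, e in rows),
                    key=lambda t: t[1],
                )
            )
        )


def assign_domain(v: ParsedVariant, domain_map: Optional[DomainMap] = None) -> str:
    """Domain label containing the codon, or ``"linker"`` between domains."""
    domain_map = domain_map or DomainMap.default()
    for label, start, end in domain_map.intervals:
        if start <= v.codon <= end:
            return label
    return "linker"


# ---------------------------------------------------------------------------
# cohort-level exclusions


@dataclass(frozen=True)
class ExclusionReport:
    r337h: int = 0
    clonal_hematopoiesis: int = 0
    removed_ids: tuple[str, ...] = ()

    @property
    def total_removed(self) -> int:
        return len(self.removed_ids)


def apply_exclusions(
    cohort: Cohort,
    exclude_r337h_founder: bool = True,
    exclude_clonal_hematopoiesis: bool = True,
) -> tuple[Cohort, ExclusionReport]:
    """Drop founder-variant carriers and/or suspected clonal hematopoiesis.

    Removal is by individual: their diagnoses are dropped too. Founder
    exclusion keys on the normalized shorthand equalling p.R337H.
    """
    removed: dict[str, str] = {}
    n_r337h = n_ch = 0
    for ind in cohort.individuals:
        v = ind.variant
        if v is None:
            continue
        if exclude_r337h_founder and is_founder_r337h(v.hgvs_p):
            removed[ind.individual_id] = "r337h"
            n_r337h += 1
        elif exclude_clonal_hematopoiesis and v.clonal_hematopoiesis_suspected:
            removed[ind.individual_id] = "clonal_hematopoiesis"
            n_ch += 1
    kept = [i for i in cohort.individuals if i.individual_id not in removed]
    kept_ids = {i.individual_id for i in kept}
    # drop parent links pointing at removed individuals
    kept = [
        replace(
            i,
            father_id=i.father_id if i.father_id in kept_ids else None,
            mother_id=i.mother_id if i.mother_id in kept_ids else None,
        )
        for i in kept
    ]
    diagnoses = [d for d in cohort.diagnoses if d.individual_id in kept_ids]
    report = ExclusionReport(
        r337h=n_r337h,
        clonal_hematopoiesis=n_ch,
        removed_ids=tuple(sorted(removed)),
    )
    return Cohort(individuals=kept, diagnoses=diagnoses), report
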