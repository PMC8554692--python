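"""Two-group tumor-pattern tabulation and 2x2 comparisons.

Reproduces the case-level organ/tissue and histology tables: per-label
counts and percentages per group, and for each label a 2x2 comparison
(label vs all other cases) using the uncorrected Pearson chi-square test
or, when any expected cell count falls below 5, the two-sided Fisher
exact test (point-probability method). No continuity correction and no
multiple-testing adjustment are applied; significance is flagged at
p < .01.

The Fisher implementation sums exact hypergeometric probabilities using
integer binomial coefficients, so it is exact for any table size and is
verified in the test suite against a full enumeration oracle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from lfspectrum.cohort_model import Morphology, Site

SIGNIFICANCE_LEVEL = 0.01

SOFT_TISSUE_MORPHOLOGIES = [
    Morphology.fibrosarcoma,
    Morphology.leiomyosarcoma,
    Morphology.liposarcoma,
    Morphology.rhabdomyosarcoma,
    Morphology.malignant_fibrous_histiocytoma,
    Morphology.sarcoma_other,
    Morphology.sarcoma_nos,
]
BRAIN_MORPHOLOGIES = [
    Morphology.astrocytoma,
    Morphology.choroid_plexus_carcinoma,
    Morphology.ependymoma,
    Morphology.glioblastoma_glioma,
    Morphology.medulloblastoma,
    Morphology.pnet,
    Morphology.brain_other,
    Morphology.cancer_nos,
]


class TabulationLevel(str, enum.Enum):
    organ = "organ"
    soft_tissue_histology = "soft_tissue_histology"
    brain_histology = "brain_histology"


class TestKind(str, enum.Enum):
    pearson_chi2 = "pearson_chi2"
    fisher_exact = "fisher_exact"


class MarginError(ValueError):
    """A zero margin makes the chi-square test undefined; use Fisher."""


@dataclass(frozen=True)
class ContingencyResult:
    label: str
    a: int  # group 1 with trait
    b: int  # group 1 without
    c: int  # group 2 with trait
    d: int  # group 2 without
    test_used: TestKind
    statistic: Optional[float]
    p_value: float

    @property
    def pct1(self) -> Optional[float]:
        return 100.0 * self.a / (self.a + self.b) if self.a + self.b else None

    @property
    def pct2(self) -> Optional[float]:
        return 100.0 * self.c / (self.c + self.d) if self.c + self.d else None

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


# ---------------------------------------------------------------------------
# elementary tests


def pearson_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table, 1 df.

    Statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); raises
    :class:`MarginError` on a zero margin.
    """
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise MarginError(
            "zero margin in 2x2 table; the chi-square test is undefined "
            "here, use fisher_exact"
        )
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(stat), float(chi2.sf(stat, df=1))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value, point-probability method.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than that of the observed table. Computed
    with exact integer binomial coefficients (all tables share the
    denominator C(N, a+c)), so ties are handled exactly.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # single possible table
    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= observed:
            total += w
    return total / math.comb(n, c1)


# ---------------------------------------------------------------------------
# tabulation


@dataclass
class Tabulation:
    """Per-label counts for two groups plus each group's denominator."""

    level: TabulationLevel
    labels: list[str]
    counts1: dict[str, int]
    counts2: dict[str, int]
    denominator1: int
    denominator2: int

    def pct(self, label: str, group: int, ndigits: Optional[int] = None):
        count = (self.counts1 if group == 1 else self.counts2).get(label, 0)
        denom = self.denominator1 if group == 1 else self.denominator2
        if denom == 0:
            return None  # undefined, not 0
        value = 100.0 * count / denom
        return round(value, ndigits) if ndigits is not None else value

    @classmethod
    def from_counts(
        cls,
        level: TabulationLevel,
        rows: Sequence[tuple[str, int, int]],
        denominator1: Optional[int] = None,
        denominator2: Optional[int] = None,
    ) -> "Tabulation":
        """Build directly from printed per-label counts (label, n1, n2);
        denominators default to the column sums."""
        labels = [r[0] for r in rows]
        c1 = {r[0]: int(r[1]) for r in rows}
        c2 = {r[0]: int(r[2]) for r in rows}
        return cls(
            level=level,
            labels=labels,
            counts1=c1,
            counts2=c2,
            denominator1=(
                denominator1 if denominator1 is not None else sum(c1.values())
            ),
            denominator2=(
                denominator2 if denominator2 is not None else sum(c2.values())
            ),
        )


def _level_rows(cases: pd.DataFrame, level: TabulationLevel) -> tuple[pd.Series, int]:
    if level is TabulationLevel.organ:
        return cases["site"], len(cases)
    site = (
        Site.soft_tissues
        if level is TabulationLevel.soft_tissue_histology
        else Site.brain
    )
    sub = cases[(cases["site"] == site.value) & cases["morphology"].notna()]
    return sub["morphology"], len(sub)


def tabulate(
    cases1: pd.DataFrame,
    cases2: pd.DataFrame,
    level: TabulationLevel = TabulationLevel.organ,
    denominator1: Optional[int] = None,
    denominator2: Optional[int] = None,
) -> Tabulation:
    """Count cases per label for two case sets.

    Organ-level denominators are the total cases per group; histology
    denominators are the group's cases of that organ for which
    morphology is available. Explicit denominators may be supplied to
    reproduce externally fixed group totals.
    """
    if level is TabulationLevel.organ:
        labels = [s.value for s in Site]
    elif level is TabulationLevel.soft_tissue_histology:
        labels = [m.value for m in SOFT_TISSUE_MORPHOLOGIES]
    else:
        labels = [m.value for m in BRAIN_MORPHOLOGIES]
    vals1, den1 = _level_rows(cases1, level)
    vals2, den2 = _level_rows(cases2, level)
    vc1, vc2 = vals1.value_counts(), vals2.value_counts()
    return Tabulation(
        level=level,
        labels=labels,
        counts1={lab: int(vc1.get(lab, 0)) for lab in labels},
        counts2={lab: int(vc2.get(lab, 0)) for lab in labels},
        denominator1=denominator1 if denominator1 is not None else den1,
        denominator2=denominator2 if denominator2 is not None else den2,
    )


def compare_groups(
    tab: Tabulation, min_expected: float = 5.0
) -> list[ContingencyResult]:
    """One 2x2 comparison per label (label vs remaining cases, by group).

    Chooses the Fisher exact test when any expected cell count is below
    ``min_expected``, else the uncorrected Pearson chi-square test.
    """
    out = []
    for label in tab.labels:
        a = tab.counts1.get(label, 0)
        c = tab.counts2.get(label, 0)
        b = tab.denominator1 - a
        d = tab.denominator2 - c
        n = a + b + c + d
        use_fisher = n == 0
        if not use_fisher:
            expected = [
                (a + b) * (a + c) / n,
                (a + b) * (b + d) / n,
                (c + d) * (a + c) / n,
                (c + d) * (b + d) / n,
            ]
            use_fisher = min(expected) < min_expected
        if use_fisher:
            stat: Optional[float] = None
            p = fisher_exact(a, b, c, d)
            kind = TestKind.fisher_exact
        else:
            stat, p = pearson_chi2(a, b, c, d)
            kind = TestKind.pearson_chi2
        out.append(
            ContingencyResult(
                label=label, a=a, b=b, c=c, d=d,
                test_used=kind, statistic=stat, p_value=p,
            )
        )
    return out


def format_p(p: float) -> str:
    """Table-style p formatting: '<.001', '>.99', else 2-3 decimals."""
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    r3 = round(p, 3)
    r2 = round(p, 2)
    text = f"{r3:.3f}" if abs(r3 - r2) > 1e-12 else f"{r2:.2f}"
    return text.lstrip("0")


def results_to_frame(
    results: Iterable[ContingencyResult], pct_digits: int = 2
) -> pd.DataFrame:
    """Table-style output: label, per-group "n (pct)", p, test used."""
    rows = []
    for r in results:
        pct1, pct2 = r.pct1, r.pct2
        rows.append(
            {
                "label": r.label,
                "group1": (
                    f"{r.a} ({pct1:.{pct_digits}f})" if pct1 is not None else str(r.a)
                ),
                "group2": (
                    f"{r.c} ({pct2:.{pct_digits}f})" if pct2 is not None else str(r.c)
                ),
                "p_value": format_p(r.p_value),
                "test_used": r.test_used.value,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "group1", "group2", "p_value", "test_used", "significant"]
    )


def summarize_ages(ages: Sequence[float]) -> Optional[dict[str, float]]:
    """Median / min / max of per-individual first-event ages."""
    if len(ages) == 0:
        return None
    arr = np.asarray(ages, dtype=float)
    return {
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": int(arr.size),
    }


def first_event_ages(cases: pd.DataFrame) -> list[float]:
    """Age at first diagnosis per individual in a case set."""
    if cases.empty:
        return []
    return cases.groupby("individual_id")["age_at_dx"].min().tolist()
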