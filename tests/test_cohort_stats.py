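import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lfspectrum import reference_counts as ref
from lfspectrum.cohort_stats import (
    MarginError,
    TabulationLevel,
    Tabulation,
    TestKind as StatTest,
    compare_groups,
    fisher_exact,
    first_event_ages,
    format_p,
    pearson_chi2,
    results_to_frame,
    summarize_ages,
    tabulate,
)
from lfspectrum.spectrum_classifier import stratify_for_analysis
from lfspectrum.synthetic_cohort import SimConfig, generate


# ---------------------------------------------------------------------------
# oracles


def chi2_oracle(a, b, c, d):
    """Direct observed-vs-expected summation, Sum (O-E)^2/E."""
    n = a + b + c + d
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    total = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            total += (obs[i][j] - e) ** 2 / e
    return total


def fisher_oracle(a, b, c, d):
    """Full enumeration with exact rational hypergeometric probabilities
    in factorial form."""
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        return Fraction(1)

    def prob(x):
        # table (x, r1-x, c1-x, r2-c1+x)
        cells = (x, r1 - x, c1 - x, r2 - c1 + x)
        num = (
            math.factorial(r1)
            * math.factorial(r2)
            * math.factorial(c1)
            * math.factorial(c2)
        )
        den = math.factorial(n)
        for cell in cells:
            den *= math.factorial(cell)
        return Fraction(num, den)

    observed = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= observed:
            total += p
    return total


tables = st.tuples(
    st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
)


# ---------------------------------------------------------------------------
# pearson_chi2


class TestPearsonChi2:
    def test_prostate_row_rounds_to_098(self):
        _, p = pearson_chi2(33, 2543 - 33, 10, 762 - 10)
        assert round(p, 2) == 0.98

    def test_equal_proportions_give_zero(self):
        stat, p = pearson_chi2(10, 20, 30, 60)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @given(tables)
    @settings(max_examples=300, deadline=None)
    def test_matches_observed_expected_oracle(self, t):
        a, b, c, d = t
        margins = (a + b, c + d, a + c, b + d)
        if any(m == 0 for m in margins):
            with pytest.raises(MarginError):
                pearson_chi2(a, b, c, d)
            return
        stat, _ = pearson_chi2(a, b, c, d)
        assert stat == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-12)

    @given(tables)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_under_group_and_trait_swap(self, t):
        a, b, c, d = t
        if any(m == 0 for m in (a + b, c + d, a + c, b + d)):
            return
        base = pearson_chi2(a, b, c, d)
        assert pearson_chi2(c, d, a, b) == pytest.approx(base)
        assert pearson_chi2(b, a, d, c) == pytest.approx(base)


# ---------------------------------------------------------------------------
# fisher_exact


class TestFisherExact:
    def test_enumerated_example(self):
        assert fisher_exact(3, 1, 1, 3) == pytest.approx(34 / 70)

    def test_zero_margin_single_table(self):
        assert fisher_exact(0, 0, 5, 7) == 1.0
        assert fisher_exact(0, 5, 0, 7) == 1.0

    def test_exhaustive_small_tables(self):
        # every 2x2 table with N <= 24
        limit = 24
        for a in range(limit + 1):
            for b in range(limit + 1 - a):
                for c in range(limit + 1 - a - b):
                    for d in range(limit + 1 - a - b - c):
                        got = fisher_exact(a, b, c, d)
                        want = float(fisher_oracle(a, b, c, d))
                        assert got == pytest.approx(want, abs=1e-12), (a, b, c, d)

    @given(
        st.tuples(
            st.integers(0, 60), st.integers(0, 60),
            st.integers(0, 60), st.integers(0, 60),
        ).filter(lambda t: sum(t) <= 60)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle_to_n60(self, t):
        a, b, c, d = t
        assert fisher_exact(a, b, c, d) == pytest.approx(
            float(fisher_oracle(a, b, c, d)), abs=1e-12
        )

    def test_scipy_agreement_on_moderate_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher

        for table in [(8, 2, 1, 5), (12, 5, 7, 9), (2, 7, 8, 2), (1, 9, 11, 3)]:
            a, b, c, d = table
            assert fisher_exact(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], rel=1e-9
            )


# ---------------------------------------------------------------------------
# tabulation and group comparison


class TestTabulate:
    def test_soft_tissue_histology_reference_counts(self):
        tab = Tabulation.from_counts(
            TabulationLevel.soft_tissue_histology, ref.SOFT_TISSUE_ROWS
        )
        assert tab.denominator1 == 303
        assert tab.pct("rhabdomyosarcoma", 1, ndigits=1) == 38.3

    def test_brain_histology_sums_to_organ_row(self):
        organ = dict((r[0], (r[1], r[2])) for r in ref.ORGAN_ROWS)
        brain_met = sum(r[1] for r in ref.BRAIN_ROWS)
        brain_not_met = sum(r[2] for r in ref.BRAIN_ROWS)
        assert (brain_met, brain_not_met) == organ["brain"]

    def test_single_case_is_hundred_percent(self):
        cases = pd.DataFrame(
            [{"individual_id": "p", "site": "breast", "morphology": None,
              "age_at_dx": 40.0}]
        )
        tab = tabulate(cases, cases.iloc[:0], TabulationLevel.organ)
        assert tab.pct("breast", 1) == 100.0

    def test_empty_denominator_undefined_not_zero(self):
        empty = pd.DataFrame(
            columns=["individual_id", "site", "morphology", "age_at_dx"]
        )
        tab = tabulate(empty, empty, TabulationLevel.organ)
        assert tab.pct("breast", 1) is None

    def test_histology_denominator_is_morphology_subset(self):
        rows = [
            {"individual_id": "a", "site": "soft_tissues",
             "morphology": "rhabdomyosarcoma", "age_at_dx": 4.0},
            {"individual_id": "b", "site": "soft_tissues",
             "morphology": None, "age_at_dx": 30.0},
            {"individual_id": "c", "site": "breast",
             "morphology": None, "age_at_dx": 40.0},
        ]
        cases = pd.DataFrame(rows)
        tab = tabulate(cases, cases.iloc[:0], TabulationLevel.soft_tissue_histology)
        assert tab.denominator1 == 1
        assert tab.pct("rhabdomyosarcoma", 1) == 100.0

    def test_organ_counts_sum_to_group_totals(self):
        cohort, _ = generate(SimConfig(n_families=40, seed=21))
        met, not_met, _ = stratify_for_analysis(cohort)
        tab = tabulate(met, not_met, TabulationLevel.organ)
        assert sum(tab.counts1.values()) == tab.denominator1 == len(met)
        assert sum(tab.counts2.values()) == tab.denominator2 == len(not_met)


@pytest.fixture(scope="module")
def organ_results():
    tab = Tabulation.from_counts(
        TabulationLevel.organ,
        ref.ORGAN_ROWS,
        denominator1=ref.MET_TOTAL_CASES,
        denominator2=ref.NOT_MET_TOTAL_CASES,
    )
    return {r.label: r for r in compare_groups(tab)}


class TestCompareGroups:

    def test_breast_below_001(self, organ_results):
        r = organ_results["breast"]
        assert r.test_used is StatTest.pearson_chi2
        assert r.p_value < 0.001 and r.significant

    def test_lung_rounds_to_003(self, organ_results):
        assert round(organ_results["lung"].p_value, 3) == 0.003

    def test_prostate_rounds_to_098(self, organ_results):
        assert round(organ_results["prostate"].p_value, 2) == 0.98
        assert not organ_results["prostate"].significant

    def test_identical_groups_all_p_one(self):
        rows = [("breast", 5, 5), ("lung", 3, 3), ("skin", 2, 2)]
        tab = Tabulation.from_counts(TabulationLevel.organ, rows)
        for r in compare_groups(tab):
            assert r.p_value == pytest.approx(1.0)
            assert not r.significant

    def test_fisher_chosen_for_small_expected(self):
        tab = Tabulation.from_counts(
            TabulationLevel.organ,
            [("breast", 2, 1), ("lung", 30, 28), ("skin", 30, 28)],
        )
        results = {r.label: r for r in compare_groups(tab)}
        assert results["breast"].test_used is StatTest.fisher_exact
        assert results["lung"].test_used is StatTest.pearson_chi2

    def test_contingency_invariants(self, organ_results):
        for r in organ_results.values():
            assert r.a + r.b == ref.MET_TOTAL_CASES
            assert r.c + r.d == ref.NOT_MET_TOTAL_CASES
            assert r.pct1 == pytest.approx(100 * r.a / ref.MET_TOTAL_CASES)
            assert 0 <= r.p_value <= 1

    def test_results_frame_formatting(self, organ_results):
        frame = results_to_frame(organ_results.values(), pct_digits=2)
        breast = frame[frame["label"] == "breast"].iloc[0]
        assert breast["group1"] == "700 (27.53)"
        assert breast["p_value"] == "<.001"


class TestFormatP:
    @pytest.mark.parametrize(
        "p,text",
        [(0.0005, "<.001"), (0.9951, ">.99"), (0.003, ".003"),
         (0.55, ".55"), (0.975, ".975")],
    )
    def test_table_style(self, p, text):
        assert format_p(p) == text


class TestSummarizeAges:
    def test_median_and_range(self):
        s = summarize_ages([0, 26, 90])
        assert (s["median"], s["min"], s["max"]) == (26.0, 0.0, 90.0)

    def test_single_member(self):
        assert summarize_ages([41.5])["median"] == 41.5

    def test_empty_group_undefined(self):
        assert summarize_ages([]) is None

    def test_first_event_age_per_individual(self):
        cases = pd.DataFrame(
            [
                {"individual_id": "a", "site": "breast", "morphology": None,
                 "age_at_dx": 40.0},
                {"individual_id": "a", "site": "lung", "morphology": None,
                 "age_at_dx": 55.0},
                {"individual_id": "b", "site": "skin", "morphology": None,
                 "age_at_dx": 30.0},
            ]
        )
        assert sorted(first_event_ages(cases)) == [30.0, 40.0]

    def test_synthetic_age_window_respected(self):
        # attenuated template draws onset uniformly in 52-70
        cfg = SimConfig(
            n_families=120,
            seed=33,
            template_mixture={"attenuated": 1.0},
        )
        cohort, _ = generate(cfg)
        _, not_met, _ = stratify_for_analysis(cohort)
        summary = summarize_ages(first_event_ages(not_met))
        assert 52 <= summary["min"] <= summary["max"] <= 70
        assert 55 <= summary["median"] <= 67  # well inside the window
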