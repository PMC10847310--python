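"""Event classification, rates, characteristic tables, TTO and tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import reference_tables as ref
from conftest import make_case, make_cases
from pvkit import (
    PartialDate,
    Vocabulary,
    chi_square,
    classify_event,
    format_percent,
    median_tto_comparison,
    overlap_analysis,
    rank_test,
    reporting_rate,
    summarize_characteristics,
    time_to_onset,
)
from pvkit.cleaning import CaseDrug
from pvkit.event_analysis import DAYS_PER_MONTH


class TestClassifyEvent:
    def test_intracranial_implies_hemorrhagic(self):
        c = classify_event("Cerebral haemorrhage")
        assert c.is_hemorrhagic and c.is_intracranial

    def test_hemorrhagic_not_intracranial(self):
        c = classify_event("Cystitis haemorrhagic")
        assert c.is_hemorrhagic and not c.is_intracranial

    def test_unrelated_term(self):
        c = classify_event("Headache")
        assert not (c.is_hemorrhagic or c.is_intracranial or c.is_thrombocytopenia)

    def test_whitelist_covers_haemorrhoids(self):
        assert classify_event("Haemorrhoids").is_hemorrhagic

    def test_american_spelling(self):
        assert classify_event("Hemorrhagic stroke").is_hemorrhagic

    def test_thrombocytopenia_terms(self):
        assert classify_event("Platelet count decreased").is_thrombocytopenia
        assert classify_event("Thrombocytopenia").is_thrombocytopenia

    @pytest.mark.parametrize("pt", [row[0] for row in ref.PT])
    def test_full_reference_roster_is_hemorrhagic(self, pt):
        """Every PT in the reference hemorrhagic-case table is recognised."""
        assert classify_event(pt).is_hemorrhagic


class TestFormatPercent:
    @pytest.mark.parametrize(
        "count,expected",
        [(count, pct) for _, count, pct in ref.REGIMEN + ref.AGE + ref.SEX + ref.OUTCOME + ref.SOC]
        + [(count, pct) for _, _, count, pct in ref.PT],
    )
    def test_reference_table_percents(self, count, expected):
        assert format_percent(count, ref.N_CASES) == expected

    def test_zero_count(self):
        assert format_percent(0, 100) == "0%"

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            format_percent(1, 0)


def reference_cases():
    """Reconstruct the N=1,274 characteristic table as an assembled case set."""
    def spread(levels):
        out = []
        for level, count, _ in levels:
            out.extend([level] * count)
        return out

    regimens = spread(ref.REGIMEN)
    ages = spread(ref.AGE)
    sexes = spread(ref.SEX)
    outcomes = spread(ref.OUTCOME)
    pts = []
    for pt, _, count, _ in ref.PT:
        pts.extend([pt] * count)
    age_value = {"<18": 10, "18–44": 30, "45–64": 50, "65–74": 70, "≥75": 80, "Unknown": None}
    rows = []
    for i in range(ref.N_CASES):
        exposure = (
            {"trastuzumab"}
            if regimens[i] == "Monotherapy"
            else {"trastuzumab", "pertuzumab"}
        )
        rows.append(
            make_case(
                i + 1,
                exposure=exposure,
                reactions={pts[i]},
                outcomes=set() if outcomes[i] == "Unknown" else {outcomes[i]},
                age_years=age_value[ages[i]],
                sex="unknown" if sexes[i] == "Unknown" else sexes[i],
            )
        )
    return make_cases(rows)


def reference_vocabulary():
    return Vocabulary({pt: soc for pt, soc, _, _ in ref.PT})


class TestSummarizeCharacteristics:
    def test_reproduces_reference_table(self):
        """Counts and percent strings match the printed table in every group."""
        table = summarize_characteristics(
            reference_cases(), vocabulary=reference_vocabulary()
        )
        got = {
            (row.group, row.level): (row.count, row.percent)
            for row in table.itertuples()
        }
        expected = {}
        for level, count, pct in ref.REGIMEN:
            expected[("Regimen", level)] = (count, pct)
        for level, count, pct in ref.AGE:
            expected[("Age", level)] = (count, pct)
        for level, count, pct in ref.SEX:
            expected[("Sex", level)] = (count, pct)
        for level, count, pct in ref.OUTCOME:
            expected[("OUTC_COD", level)] = (count, pct)
        for level, count, pct in ref.SOC:
            expected[("soc_name", level)] = (count, pct)
        for pt, _, count, pct in ref.PT:
            expected[("pt_name", pt)] = (count, pct)
        assert got == expected

    def test_partition_groups_sum_to_n(self):
        table = summarize_characteristics(
            reference_cases(), vocabulary=reference_vocabulary()
        )
        for group in ("Regimen", "Age", "Sex"):
            assert table.loc[table.group == group, "count"].sum() == ref.N_CASES


class TestReportingRate:
    def test_toy_soc_rate(self, vocabulary):
        rows = [
            make_case(i, exposure={"trastuzumab"}, reactions=r)
            for i, r in enumerate(
                [
                    {"Cardiac failure"},
                    {"Cardiac failure", "Diarrhoea"},
                    {"Diarrhoea"},
                    {"Headache"},
                    set(),
                    set(),
                    set(),
                    set(),
                ]
            )
        ]
        cases = make_cases(rows)
        rate = reporting_rate(cases, "trastuzumab", "Cardiac disorders", vocabulary)
        assert (rate.numerator, rate.denominator) == (2, 8)
        assert rate.percent == 25.0

    def test_repeated_pt_counts_once(self):
        cases = make_cases(
            [make_case(1, exposure={"TDM-1"}, reactions={"Nausea"})]
        )
        rate = reporting_rate(cases, "TDM-1", "Nausea")
        assert (rate.numerator, rate.denominator) == (1, 1)

    def test_zero_hits(self):
        cases = make_cases([make_case(1, exposure={"TDM-1"}, reactions={"Nausea"})])
        assert reporting_rate(cases, "TDM-1", "Rash").percent == 0.0

    def test_unexposed_drug_is_error(self):
        cases = make_cases([make_case(1, exposure={"TDM-1"})])
        with pytest.raises(ValueError):
            reporting_rate(cases, "lapatinib", "Nausea")


class TestOverlap:
    def test_worked_proportion(self):
        """44 cases with both, 66 hemorrhage-only: 40% of bleeders overlap."""
        rows = []
        pid = 0
        for _ in range(44):
            pid += 1
            rows.append(
                make_case(
                    pid,
                    exposure={"TDM-1"},
                    reactions={"Gastric haemorrhage", "Thrombocytopenia"},
                )
            )
        for _ in range(66):
            pid += 1
            rows.append(make_case(pid, exposure={"TDM-1"}, reactions={"Gastric haemorrhage"}))
        for _ in range(10):
            pid += 1
            rows.append(make_case(pid, exposure={"TDM-1"}, reactions={"Nausea"}))
        table = overlap_analysis(make_cases(rows), drugs=["TDM-1"])
        row = table.iloc[0]
        assert (row.both, row.hemorrhage_only) == (44, 66)
        assert row.pct_hemorrhage_with_thrombocytopenia == pytest.approx(40.0)

    def test_partition_sums_to_exposed_total(self, toy_cases):
        table = overlap_analysis(toy_cases)
        for row in table.itertuples():
            exposed = sum(row.drug in e for e in toy_cases["exposure"])
            total = row.both + row.hemorrhage_only + row.thrombocytopenia_only + row.neither
            assert total == exposed

    def test_no_thrombocytopenia(self, toy_cases):
        table = overlap_analysis(toy_cases)
        assert (table["both"] == 0).all()


def tto_case(start, event, drug="TDM-1"):
    return make_case(
        1,
        exposure={drug},
        reactions={"Cerebral haemorrhage"},
        event_dt=event,
        drugs=(CaseDrug(drug, drug, "PS", start),),
    )


class TestTimeToOnset:
    def test_fifteen_days(self):
        case = tto_case(PartialDate(2020, 1, 1), PartialDate(2020, 1, 16))
        tto = time_to_onset(make_cases([case]).iloc[0], "TDM-1")
        assert tto.months == pytest.approx(15 / DAYS_PER_MONTH)
        assert tto.months == pytest.approx(0.493, abs=1e-3)

    def test_negative_interval_missing(self):
        case = tto_case(PartialDate(2020, 2, 1), PartialDate(2020, 1, 1))
        assert time_to_onset(make_cases([case]).iloc[0], "TDM-1") is None

    def test_year_only_start_missing(self):
        case = tto_case(PartialDate(2020), PartialDate(2020, 6, 1))
        assert time_to_onset(make_cases([case]).iloc[0], "TDM-1") is None

    def test_day_imputed_to_mid_month(self):
        case = tto_case(PartialDate(2020, 1), PartialDate(2020, 2, 15))
        tto = time_to_onset(make_cases([case]).iloc[0], "TDM-1")
        assert tto.months == pytest.approx(31 / DAYS_PER_MONTH)

    @given(st.integers(0, 3000), st.integers(0, 400))
    def test_translation_invariance(self, base, gap):
        """Shifting both dates by the same number of days preserves months."""
        import datetime

        d0 = datetime.date(2005, 1, 1) + datetime.timedelta(days=base)
        d1 = d0 + datetime.timedelta(days=gap)
        for shift in (0, 37):
            s = d0 + datetime.timedelta(days=shift)
            e = d1 + datetime.timedelta(days=shift)
            case = tto_case(
                PartialDate(s.year, s.month, s.day), PartialDate(e.year, e.month, e.day)
            )
            tto = time_to_onset(make_cases([case]).iloc[0], "TDM-1")
            assert tto.months == pytest.approx(gap / DAYS_PER_MONTH)


def chi_square_oracle(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    return float(((table - expected) ** 2 / expected).sum())


class TestChiSquare:
    def test_worked_example(self):
        result = chi_square([[10, 20], [30, 40]])
        assert result.statistic == pytest.approx(0.79365, abs=1e-4)
        assert result.df == 1

    def test_no_departure(self):
        result = chi_square([[10, 10], [10, 10]])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_zero_expected_is_error(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])

    @given(
        st.lists(
            st.lists(st.integers(1, 10), min_size=2, max_size=3),
            min_size=2,
            max_size=3,
        ).filter(lambda t: len({len(r) for r in t}) == 1)
    )
    def test_matches_direct_formula(self, table):
        result = chi_square(table)
        assert result.statistic == pytest.approx(chi_square_oracle(table), rel=1e-9)

    def test_monotone_departure(self):
        base = chi_square([[10, 10], [10, 10]]).statistic
        perturbed = chi_square([[12, 8], [8, 12]]).statistic
        assert perturbed > base


def wilcoxon_enumeration_p(x, y):
    """Two-sided exact rank-sum p over all assignments of ranks to group x."""
    combined = sorted(x + y)
    # midranks
    rank_of = {}
    i = 0
    while i < len(combined):
        j = i
        while j < len(combined) and combined[j] == combined[i]:
            j += 1
        mid = (i + 1 + j) / 2
        rank_of[combined[i]] = mid
        i = j
    all_ranks = [rank_of[v] for v in combined]
    obs = sum(rank_of[v] for v in x)
    mean = sum(all_ranks) * len(x) / len(combined)
    sums = [sum(c) for c in itertools.combinations(all_ranks, len(x))]
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(sums)


class TestRankTest:
    def test_exact_small_sample(self):
        result = rank_test([[1, 2], [3, 4]])
        assert result.method == "wilcoxon"
        assert result.p_value == pytest.approx(1 / 3)

    def test_identical_groups(self):
        result = rank_test([[5, 5], [5, 5, 5]])
        assert result.p_value == 1.0 and result.statistic == 0.0

    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=5),
        st.lists(st.integers(0, 30), min_size=2, max_size=5),
    )
    def test_matches_enumeration_oracle(self, x, y):
        if len(set(x + y)) == 1:
            return
        result = rank_test([x, y])
        assert result.p_value == pytest.approx(wilcoxon_enumeration_p(x, y), abs=1e-9)

    def test_exact_and_asymptotic_agree_moderately(self):
        rng = np.random.default_rng(5)
        x = list(rng.normal(size=5))
        y = list(rng.normal(1.0, size=5))
        exact = rank_test([x, y]).p_value
        approx = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
        )
        assert abs(exact - approx) < 0.05

    def test_three_groups_kruskal(self):
        result = rank_test([[1, 2, 3], [2, 3, 4], [10, 11, 12]])
        assert result.method == "kruskal_wallis"
        assert result.df == 2
        h = stats.kruskal([1, 2, 3], [2, 3, 4], [10, 11, 12]).statistic
        assert result.statistic == pytest.approx(float(h))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([[1.0], []])


class TestMedianTto:
    def test_separated_strata(self):
        medians, result = median_tto_comparison(
            {"mono": [1.0, 2.0, 3.0], "combo": [10.0, 20.0, 30.0]}
        )
        assert medians == {"mono": 2.0, "combo": 20.0}
        assert result.p_value == pytest.approx(0.1)  # exact enumeration, n=3+3

    def test_single_value_stratum(self):
        medians, _ = median_tto_comparison({"a": [7.0], "b": [1.0, 2.0]})
        assert medians["a"] == 7.0

    def test_empty_stratum_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            medians, _ = median_tto_comparison(
                {"a": [], "b": [1.0, 2.0], "c": [3.0, 4.0]}
            )
        assert set(medians) == {"b", "c"}

    def test_all_empty_is_error(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                median_tto_comparison({"a": [], "b": [1.0]})
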