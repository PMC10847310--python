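"""PRR, BCPNN information component, signal rule and the pair screen."""

import math
from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, strategies as st

from pvkit import (
    ContingencyTable,
    SimConfig,
    assemble_cases,
    build_contingency,
    deduplicate,
    generate,
    ic,
    is_signal,
    prr,
    screen_signals,
)
from pvkit.signal_detection import UndefinedExposureError, Z_95, prr_corrected
from pvkit.synthetic_data import Association, default_drug_dictionary, default_vocabulary


def prr_oracle(a, b, c, d):
    """Exact rational-arithmetic PRR with the same 0.5 zero-cell handling."""
    if a == 0 or c == 0:
        a, b, c, d = (Fraction(x) + Fraction(1, 2) for x in (a, b, c, d))
    return Fraction(a) * (c + d) / ((a + b) * Fraction(c))


class TestPrr:
    def test_identical_proportions(self):
        value, lo, hi = prr(ContingencyTable(10, 90, 100, 900))
        assert value == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example(self):
        """(4, 96, 96, 9804): reporting proportions 4% vs 96/9900."""
        value, lo, hi = prr(ContingencyTable(4, 96, 96, 9804))
        assert value == 4.125
        assert lo == pytest.approx(1.5472, rel=1e-3)
        assert hi == pytest.approx(11.00, rel=1e-3)

    def test_zero_cell_continuity_correction(self):
        table = ContingencyTable(0, 100, 50, 9850)
        value, lo, hi, corrected = prr_corrected(table)
        assert corrected
        expected = (0.5 * (50.5 + 9850.5)) / ((0.5 + 100.5) * 50.5)
        assert value == pytest.approx(expected)
        se = math.sqrt(1 / 0.5 - 1 / 101.0 + 1 / 50.5 - 1 / 9901.0)
        assert lo == pytest.approx(expected * math.exp(-Z_95 * se))

    def test_empty_margin_is_error(self):
        with pytest.raises(UndefinedExposureError):
            prr(ContingencyTable(0, 0, 5, 5))

    def test_exact_against_rational_oracle(self):
        """All 2x2 tables with cells at most 6 match exact rational arithmetic."""
        for a, b, c, d in product(range(7), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            value, _, _ = prr(ContingencyTable(a, b, c, d))
            assert value == float(prr_oracle(a, b, c, d)), (a, b, c, d)

    @given(st.integers(1, 200), st.integers(0, 200), st.integers(1, 200), st.integers(0, 200))
    def test_point_estimate_within_ci(self, a, b, c, d):
        value, lo, hi = prr(ContingencyTable(a, b, c, d))
        assert lo <= value <= hi

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    def test_scale_invariance_and_ci_narrowing(self, a, b, c, d):
        """Multiplying all cells by k fixes the estimate and narrows the CI."""
        v1, lo1, hi1 = prr(ContingencyTable(a, b, c, d))
        v3, lo3, hi3 = prr(ContingencyTable(3 * a, 3 * b, 3 * c, 3 * d))
        assert v3 == pytest.approx(v1)
        assert hi3 / lo3 < hi1 / lo1

    def test_strictly_increasing_in_a(self):
        values = [prr(ContingencyTable(a, 50, 20, 1000))[0] for a in range(1, 10)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestIc:
    def test_observed_equals_expected(self):
        # margins give E = 10 = a, shrinkage cancels
        table = ContingencyTable(10, 90, 990, 8910)
        assert table.expected == pytest.approx(10.0)
        value, ic025 = ic(table)
        assert value == pytest.approx(0.0)

    def test_worked_example(self):
        table = ContingencyTable(4, 96, 96, 9804)
        assert table.expected == pytest.approx(1.0)
        value, ic025 = ic(table)
        assert value == pytest.approx(math.log2(3), abs=1e-12)
        expected_low = math.log2(3) - 3.3 / math.sqrt(4.5) - 2.0 / 4.5**1.5
        assert ic025 == pytest.approx(expected_low, abs=1e-12)
        assert ic025 == pytest.approx(-0.180, abs=5e-3)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
    def test_lower_bound_below_estimate(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        value, ic025 = ic(ContingencyTable(a, b, c, d))
        assert ic025 < value

    def test_increasing_in_observed_count(self):
        # same margins-derived E by holding (a+b)(a+c)/N ~ constant is fussy;
        # the shrunk log-ratio must rise with a for a fixed expected count
        def ic_at(a, e):
            return math.log2((a + 0.5) / (e + 0.5))

        values = [ic_at(a, 2.0) for a in range(10)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestSignalRule:
    @pytest.mark.parametrize(
        "n,prr_value,lo,expected",
        [
            (4, 2.5, 1.2, True),
            (3, 10.0, 2.0, False),   # count must exceed 3
            (100, 1.99, 1.5, False), # PRR threshold is inclusive at 2
            (4, 2.0, 1.01, True),
            (4, 2.0, 1.0, False),    # lower limit must exceed 1
        ],
    )
    def test_thresholds(self, n, prr_value, lo, expected):
        assert is_signal(n, prr_value, lo) is expected

    def test_min_cases_switch(self):
        assert not is_signal(3, 5.0, 2.0)
        assert is_signal(3, 5.0, 2.0, min_cases=3)


class TestBuildContingency:
    def test_toy_counts(self, toy_cases):
        table = build_contingency(toy_cases, "TDM-1", "Cerebral haemorrhage")
        assert (table.a, table.b, table.c, table.d) == (2, 1, 1, 2)

    def test_case_insensitive_event(self, toy_cases):
        table = build_contingency(toy_cases, "TDM-1", "CEREBRAL HAEMORRHAGE")
        assert table.a == 2

    def test_event_absent(self, toy_cases):
        table = build_contingency(toy_cases, "TDM-1", "Rash")
        assert table.a == 0 and table.c == 0

    def test_empty_collection_is_error(self, toy_cases):
        with pytest.raises(UndefinedExposureError):
            build_contingency(toy_cases.iloc[0:0], "TDM-1", "Rash")


@pytest.fixture(scope="module")
def screened():
    config = SimConfig(
        n_cases=20_000,
        associations=(Association("TDM-1", "Thrombocytopenia", 6.0),),
        seed=11,
    )
    data = generate(config)
    cases = assemble_cases(
        deduplicate(data.demo),
        data.drug,
        data.reac,
        data.outc,
        data.ther,
        default_drug_dictionary(),
    )
    return cases, screen_signals(cases, vocabulary=default_vocabulary())


class TestScreen:
    def test_injected_pair_flagged(self, screened):
        _, table = screened
        hit = table[(table.drug == "TDM-1") & (table.pt == "Thrombocytopenia")]
        assert len(hit) == 1 and bool(hit.iloc[0]["signal"])

    def test_null_pairs_mostly_unflagged(self, screened):
        _, table = screened
        null = table[~((table.drug == "TDM-1") & (table.pt == "Thrombocytopenia"))]
        assert null["signal"].mean() < 0.05

    def test_sorted_by_descending_prr_within_drug(self, screened):
        _, table = screened
        for _, group in table.groupby("drug"):
            assert group["prr"].is_monotonic_decreasing

    def test_soc_filter(self, screened):
        cases, _ = screened
        vocab = default_vocabulary()
        table = screen_signals(cases, vocabulary=vocab, soc="Nervous system disorders")
        assert len(table)
        assert set(table["soc"]) == {"Nervous system disorders"}

    def test_unexposed_drug_absent(self, toy_cases):
        table = screen_signals(toy_cases, drugs=["lapatinib", "TDM-1"])
        assert "lapatinib" not in set(table["drug"])
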