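"""Core 2x2 arithmetic, checked against scipy's independent chi-square oracle."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import casehet as ch
from casehet import AlleleTable, DomainError

from conftest import random_tables


class TestAlleleTable:
    def test_rejects_negative_cells(self):
        with pytest.raises(DomainError):
            AlleleTable(-1, 2, 3, 4)

    def test_rejects_empty_rows(self):
        with pytest.raises(DomainError):
            AlleleTable(0, 0, 1, 1)
        with pytest.raises(DomainError):
            AlleleTable(1, 1, 0, 0)

    def test_fractional_counts_allowed(self):
        t = AlleleTable(0.5, 1.5, 2.25, 3.75)
        assert t.n_cases == 2.0


@pytest.mark.parametrize(
    "table, row, expected",
    [
        ((700, 1300, 650, 1350), "cases", 0.35),
        ((700, 1300, 650, 1350), "controls", 0.325),
        ((7, 7, 650, 1350), "cases", 0.5),
    ],
)
def test_minor_allele_freq(table, row, expected):
    assert ch.minor_allele_freq(AlleleTable(*table), row) == pytest.approx(expected)


@pytest.mark.parametrize(
    "table, expected",
    [
        ((700, 1300, 650, 1350), 1.12),
        ((200, 200, 650, 1350), 2.08),
        ((37, 37, 37, 37), 1.0),
    ],
)
def test_odds_ratio_examples(table, expected):
    assert round(ch.odds_ratio(AlleleTable(*table)), 2) == expected


def test_odds_ratio_zero_cell_errors():
    with pytest.raises(DomainError):
        ch.odds_ratio(AlleleTable(1, 0, 1, 1))


def test_expected_counts_margins_and_values(pooled_table):
    exp = ch.expected_counts(pooled_table)
    assert (exp.a, exp.b) == (675, 1325)
    # margins preserved exactly
    assert exp.n_cases == pooled_table.n_cases
    assert exp.a + exp.c == pooled_table.a + pooled_table.c
    # independent table: expected equals observed
    t = AlleleTable(10, 30, 20, 60)
    e = ch.expected_counts(t)
    assert (e.a, e.b, e.c, e.d) == (10, 30, 20, 60)


class TestChi2:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((700, 1300, 650, 1350), 2.795248),
            ((200, 200, 650, 1350), 44.629981),
        ],
    )
    def test_values(self, table, expected):
        assert ch.chi2_statistic(AlleleTable(*table)) == pytest.approx(expected, rel=1e-6)

    def test_zero_when_independent(self):
        assert ch.chi2_statistic(AlleleTable(10, 30, 20, 60)) == 0.0

    def test_matches_scipy_oracle(self, rng):
        for t in random_tables(rng, 50):
            ref = chi2_contingency(t.as_array(), correction=False).statistic
            assert ch.chi2_statistic(t) == pytest.approx(ref, rel=1e-9)

    def test_matches_obs_exp_sum(self, rng):
        for t in random_tables(rng, 50):
            exp = ch.expected_counts(t)
            brute = sum(
                (o - e) ** 2 / e
                for o, e in zip(
                    (t.a, t.b, t.c, t.d), (exp.a, exp.b, exp.c, exp.d)
                )
            )
            assert ch.chi2_statistic(t) == pytest.approx(brute, rel=1e-9)


class TestPvalue:
    def test_printed_values(self, pooled_table):
        p = ch.chi2_pvalue(ch.chi2_statistic(pooled_table))
        assert f"{p:.2g}" == "0.095"
        p2 = ch.chi2_pvalue(ch.chi2_statistic(AlleleTable(760, 1240, 600, 1400)))
        assert p2 == pytest.approx(9.27e-8, rel=5e-3)

    def test_boundaries(self):
        assert ch.chi2_pvalue(0.0) == 1.0
        with pytest.raises(DomainError):
            ch.chi2_pvalue(-0.1)


class TestScaling:
    def test_cells_scaled(self):
        s = ch.scale_table(AlleleTable(1, 2, 3, 4), 2)
        assert (s.a, s.b, s.c, s.d) == (2, 4, 6, 8)

    def test_chi2_linear_or_invariant(self, rng):
        for t in random_tables(rng, 20):
            g = float(rng.uniform(0.1, 10))
            s = ch.scale_table(t, g)
            assert ch.chi2_statistic(s) == pytest.approx(g * ch.chi2_statistic(t), rel=1e-9)
            assert ch.odds_ratio(s) == pytest.approx(ch.odds_ratio(t), rel=1e-12)

    def test_invalid_factor(self):
        with pytest.raises(DomainError):
            ch.scale_table(AlleleTable(1, 1, 1, 1), 0)


def test_row_swap_inverts_or(rng):
    for t in random_tables(rng, 20):
        swapped = AlleleTable(t.c, t.d, t.a, t.b)
        assert ch.odds_ratio(swapped) == pytest.approx(1 / ch.odds_ratio(t), rel=1e-12)


def test_pvalue_decreasing_in_chi2():
    chis = np.linspace(0, 50, 25)
    ps = [ch.chi2_pvalue(x) for x in chis]
    assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))
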