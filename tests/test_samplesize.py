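"""Sample-size multiplier gamma under heterogeneity (no reclassification)."""

import pytest

import casehet as ch
from casehet import AlleleTable, DomainError, InfeasibleSigmaError, SubclassCounts

from conftest import random_tables


class TestStrip:
    def test_worked_strip(self, pooled_table):
        s = ch.strip_nonsubgroup(pooled_table, 0.8)
        assert (s.a, s.b, s.c, s.d) == pytest.approx((180, 220, 650, 1350))

    def test_sigma_zero_identity(self, pooled_table):
        s = ch.strip_nonsubgroup(pooled_table, 0.0)
        assert (s.a, s.b, s.c, s.d) == (700, 1300, 650, 1350)

    def test_determinant_preserved(self, rng):
        for t in random_tables(rng, 30):
            sigma = float(rng.uniform(0, 1)) * 0.9 * ch.feasible_sigma_max(t)
            s = ch.strip_nonsubgroup(t, sigma)
            det0 = t.a * t.d - t.b * t.c
            det1 = s.a * s.d - s.b * s.c
            assert det1 == pytest.approx(det0, rel=1e-9, abs=1e-6)

    def test_infeasible_sigma(self, pooled_table):
        with pytest.raises(InfeasibleSigmaError):
            ch.strip_nonsubgroup(pooled_table, 0.97)


class TestChi2Subgroup:
    def test_worked_values(self, pooled_table):
        assert ch.chi2_subgroup(pooled_table, 0.8) == pytest.approx(23.022, rel=1e-4)
        assert ch.chi2_subgroup(pooled_table, 0.0) == pytest.approx(
            ch.chi2_statistic(pooled_table)
        )
        t = AlleleTable(1000, 2000, 1200, 1800)
        assert ch.chi2_subgroup(t, 0.4) == pytest.approx(
            ch.chi2_statistic(AlleleTable(520, 1280, 1200, 1800)), rel=1e-12
        )
        assert ch.chi2_subgroup(t, 0.4) == pytest.approx(60.4, rel=1e-2)


class TestGamma:
    @pytest.mark.parametrize(
        "table, sigma, expected, places",
        [
            ((700, 1300, 650, 1350), 0.8, 8.24, 2),
            ((1000, 2000, 1200, 1800), 0.4, 2.1, 1),
        ],
    )
    def test_printed_values(self, table, sigma, expected, places):
        res = ch.gamma(AlleleTable(*table), sigma)
        assert round(res.gamma, places) == expected

    def test_sigma_zero_unity(self, pooled_table):
        assert ch.gamma(pooled_table, 0.0).gamma == 1.0

    def test_defining_identity(self, rng):
        # chi2 of the gamma-scaled original equals the subgroup chi2
        for t in random_tables(rng, 30):
            if t.a * t.d == t.b * t.c:
                continue
            sigma = 0.5 * ch.feasible_sigma_max(t)
            g = ch.gamma(t, sigma).gamma
            lhs = ch.chi2_statistic(ch.scale_table(t, g))
            rhs = ch.chi2_subgroup(t, sigma)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_null_table_rejected(self):
        with pytest.raises(DomainError):
            ch.gamma(AlleleTable(10, 30, 20, 60), 0.2)


class TestGammaEqualN:
    def test_carriage_rate_example(self):
        res = ch.gamma_equal_n(AlleleTable(600, 400, 300, 700), 0.4)
        assert round(res.gamma, 1) == 2.1

    def test_matches_general_on_equal_n(self, rng):
        for _ in range(20):
            a = float(rng.integers(100, 900))
            c = float(rng.integers(100, 900))
            t = AlleleTable(a, 1000 - a, c, 1000 - c)
            if t.a * t.d == t.b * t.c:
                continue
            sigma = 0.5 * ch.feasible_sigma_max(t)
            assert ch.gamma_equal_n(t, sigma).gamma == ch.gamma(t, sigma).gamma

    def test_unequal_rows_rejected(self, pooled_table):
        with pytest.raises(DomainError):
            ch.gamma_equal_n(AlleleTable(700, 1300, 650, 1351), 0.2)


def test_gamma_explicit_subclass(pooled_table):
    # literal subclass counts: gamma = chi2(a1,b1,c,d)/chi2(a,b,c,d)
    res = ch.gamma_explicit_subclass(pooled_table, SubclassCounts(200, 200))
    assert res.gamma == pytest.approx(44.629981 / 2.795248, rel=1e-5)
    assert res.sigma == pytest.approx(0.8)


class TestGammaCurve:
    def test_passes_through_printed_point(self):
        curve = ch.gamma_curve(AlleleTable(1000, 2000, 1200, 1800), 0.05)
        at_04 = next(g for s, g in curve.grid if abs(s - 0.4) < 1e-9)
        assert round(at_04, 1) == 2.1
        assert curve.grid[0] == (0.0, 1.0)

    def test_strictly_increasing(self, rng):
        for t in random_tables(rng, 10):
            if t.a * t.d == t.b * t.c:
                continue
            curve = ch.gamma_curve(t, 0.05)
            vals = [g for _, g in curve.grid]
            assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_grid_stays_feasible(self, pooled_table):
        curve = ch.gamma_curve(pooled_table, 0.1)
        assert max(s for s, _ in curve.grid) < curve.feasible_max_sigma


class TestFeasibleSigmaMax:
    def test_worked_value(self, pooled_table):
        assert ch.feasible_sigma_max(pooled_table) == pytest.approx(0.962963, rel=1e-5)

    def test_proportional_table(self):
        assert ch.feasible_sigma_max(AlleleTable(10, 30, 20, 60)) == 1.0

    def test_binding_cell_near_zero_at_limit(self, pooled_table):
        smax = ch.feasible_sigma_max(pooled_table)
        s = ch.strip_nonsubgroup(pooled_table, smax * (1 - 1e-9))
        assert min(s.a, s.b) == pytest.approx(0.0, abs=1e-4)


def test_strip_and_reclassify_share_case_removals(rng):
    # the two sigma-transforms remove identical amounts from the case row
    for t in random_tables(rng, 20):
        sigma = 0.4 * ch.feasible_sigma_max(t)
        try:
            adj = ch.reclassify_phenocopies(t, sigma)
        except ch.InfeasibleSigmaError:
            continue
        stripped = ch.strip_nonsubgroup(t, sigma)
        assert stripped.a == pytest.approx(adj.a, rel=1e-12, abs=1e-9)
        assert stripped.b == pytest.approx(adj.b, rel=1e-12, abs=1e-9)
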