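"""Statistics kernel: exact tests, odds ratios, EF, Bonferroni.

The Fisher implementation is checked against an independent
hypergeometric enumeration oracle over all tables at the observed
margins.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from hcmcohort import (
    ContingencyTable,
    Sidedness,
    bonferroni,
    etiological_fraction,
    fisher_exact,
    odds_ratio_ci,
)


def _hypergeom_pmf(a, row1, col1, n):
    """P(top-left cell = a) at fixed margins, by binomial coefficients."""
    return (
        math.comb(col1, a)
        * math.comb(n - col1, row1 - a)
        / math.comb(n, row1)
    )


def fisher_oracle(a, b, c, d, sidedness):
    """Enumerate all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = _hypergeom_pmf(a, row1, col1, n)
    total = 0.0
    for x in range(lo, hi + 1):
        p = _hypergeom_pmf(x, row1, col1, n)
        if sidedness == "greater":
            if x >= a:
                total += p
        else:
            # same tie tolerance as the common software convention
            if p <= p_obs * (1 + 1e-7):
                total += p
    return min(total, 1.0)


tables = st.tuples(
    st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
).filter(lambda t: t[0] + t[1] >= 1 and t[2] + t[3] >= 1 and sum(t) <= 60)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(tables)
def test_fisher_matches_enumeration_oracle(t):
    a, b, c, d = t
    table = ContingencyTable(a, b, c, d)
    if table.degenerate:
        assert fisher_exact(table, Sidedness.ONE_SIDED_GREATER) == 1.0
        return
    for sided, key in (
        (Sidedness.ONE_SIDED_GREATER, "greater"),
        (Sidedness.TWO_SIDED, "two-sided"),
    ):
        assert fisher_exact(table, sided) == pytest.approx(
            fisher_oracle(a, b, c, d, "greater" if key == "greater" else "two"),
            rel=1e-9,
        )


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables)
def test_one_sided_not_exceeding_two_sided_for_enrichment(t):
    a, b, c, d = t
    table = ContingencyTable(a, b, c, d)
    if table.degenerate:
        return
    if table.case_freq >= table.control_freq:  # enrichment direction
        assert fisher_exact(table, Sidedness.ONE_SIDED_GREATER) <= fisher_exact(
            table, Sidedness.TWO_SIDED
        ) + 1e-12


@pytest.mark.parametrize(
    "table, sided, expected, rel",
    [
        # homozygous-carrier enrichment, 21/514 cases vs 1/684 comparison patients
        ((21, 493, 1, 683), Sidedness.ONE_SIDED_GREATER, 2e-7, 0.05),
        # consanguinity association 14/99 vs 10/249
        ((14, 85, 10, 239), Sidedness.ONE_SIDED_GREATER, 0.0014, 0.05),
        # symmetric table carries no signal
        ((5, 5, 5, 5), Sidedness.TWO_SIDED, 1.0, 1e-9),
    ],
)
def test_fisher_printed_examples(table, sided, expected, rel):
    assert fisher_exact(ContingencyTable(*table), sided) == pytest.approx(
        expected, rel=rel
    )


def test_degenerate_margin_is_p_one_and_flagged():
    t = ContingencyTable(0, 10, 0, 10)
    assert t.degenerate
    assert fisher_exact(t, Sidedness.TWO_SIDED) == 1.0


class TestOddsRatio:
    def test_sample_or_no_correction(self):
        r = odds_ratio_ci(ContingencyTable(24, 490, 8, 392))
        assert r.odds_ratio == pytest.approx(2.4, abs=1e-12)
        assert not r.corrected

    def test_haldane_corrected_or_and_woolf_ci(self):
        r = odds_ratio_ci(ContingencyTable(6, 508, 0, 400), zero_cell_constant=0.5)
        assert r.corrected
        assert r.odds_ratio == pytest.approx((6.5 * 400.5) / (508.5 * 0.5), rel=1e-12)
        assert r.odds_ratio == pytest.approx(10.2, abs=0.05)
        assert r.ci_low == pytest.approx(0.6, abs=0.05)
        assert r.ci_high == pytest.approx(182.3, abs=0.5)

    def test_identical_arms_or_is_one(self):
        r = odds_ratio_ci(ContingencyTable(3, 7, 3, 7))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ef == pytest.approx(0.0)

    def test_zero_constant_on_positive_table_equals_uncorrected(self):
        r0 = odds_ratio_ci(ContingencyTable(5, 10, 2, 20), zero_cell_constant=0.0)
        r5 = odds_ratio_ci(ContingencyTable(5, 10, 2, 20), zero_cell_constant=0.5)
        assert r0.odds_ratio == r5.odds_ratio
        assert not r0.corrected

    def test_zero_cell_with_zero_constant_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(ContingencyTable(5, 10, 0, 20), zero_cell_constant=0.0)

    def test_ci_brackets_or(self):
        r = odds_ratio_ci(ContingencyTable(12, 88, 5, 95))
        assert r.ci_low <= r.odds_ratio <= r.ci_high


class TestEtiologicalFraction:
    @pytest.mark.parametrize("orr, ef", [(2.0, 0.5), (1.0, 0.0), (0.5, -1.0)])
    def test_formula(self, orr, ef):
        assert etiological_fraction(orr) == pytest.approx(ef)

    def test_region_table_reaches_099(self):
        r = odds_ratio_ci(ContingencyTable(64, 450, 0, 400), zero_cell_constant=0.5)
        assert r.ef == pytest.approx(0.99, abs=0.005)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            etiological_fraction(0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    def test_strictly_increasing_and_bounded(self, x, y):
        assert etiological_fraction(x) < 1.0
        if x < y:
            assert etiological_fraction(x) < etiological_fraction(y)


class TestBonferroni:
    def test_adjustment_and_flags(self):
        out = bonferroni([0.001, 0.03, 1.0], m=16)
        assert out[0].adjusted == pytest.approx(0.016)
        assert out[0].bonferroni_significant and out[0].flag == "**"
        assert out[1].adjusted == pytest.approx(0.48)
        assert not out[1].bonferroni_significant
        assert out[1].nominal_significant and out[1].flag == "*"
        assert out[2].adjusted == 1.0 and out[2].flag == ""

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)
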