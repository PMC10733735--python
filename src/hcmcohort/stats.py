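"""Exact-test statistics kernel.

Case-control enrichment in this package is assessed on 2x2 carrier tables

    ==============  ==========  =============
    arm             carriers    non-carriers
    ==============  ==========  =============
    cases           a           b
    controls        c           d
    ==============  ==========  =============

with Fisher's exact test (one-sided for enrichment scans), a sample odds
ratio OR = ad/bc with Haldane-Anscombe zero-cell correction and a Woolf
(log-normal) confidence interval, the etiological fraction
EF = (OR - 1)/OR (the probability that a case's variant of the tested
class is disease-causing), and Bonferroni multiple-testing adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats as sps

from .types import Sidedness


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b = case carriers/non-carriers, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            x = getattr(self, name)
            if not isinstance(x, (int,)) or x < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {x!r}")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each arm must contain at least one sample")

    @property
    def case_freq(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_freq(self) -> float:
        return self.c / (self.c + self.d)

    @property
    def degenerate(self) -> bool:
        """True when a carrier margin is empty (no carriers or no non-carriers)."""
        return (self.a + self.c == 0) or (self.b + self.d == 0)


@dataclass(frozen=True)
class AssociationResult:
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    ef: float
    corrected: bool
    sidedness: Sidedness
    table: ContingencyTable
    degenerate: bool = False

    @property
    def excess(self) -> float:
        return self.table.case_freq - self.table.control_freq


def fisher_exact(table: ContingencyTable, sidedness: Sidedness) -> float:
    """Exact hypergeometric tail probability for a 2x2 carrier table.

    ``one_sided_greater`` tests enrichment of carriers in cases; the
    two-sided test sums all tables (at fixed margins) whose probability
    does not exceed the observed one.  A degenerate carrier margin gives
    p = 1 by convention.
    """
    sidedness = Sidedness(sidedness)
    if table.degenerate:
        return 1.0
    alt = "greater" if sidedness == Sidedness.ONE_SIDED_GREATER else "two-sided"
    return float(
        sps.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative=alt).pvalue
    )


def odds_ratio_ci(
    table: ContingencyTable,
    zero_cell_constant: float = 0.5,
    confidence: float = 0.95,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
    p_value: Optional[float] = None,
) -> AssociationResult:
    """Sample odds ratio with Woolf CI and Haldane-Anscombe correction.

    OR = ad/bc on the raw cells when all four are positive; if any cell is
    zero, ``zero_cell_constant`` is added to every cell first and the
    result is flagged ``corrected``.  The CI is log-normal (Woolf) on the
    possibly-corrected cells.  EF = (OR - 1)/OR is attached.
    """
    cells = (table.a, table.b, table.c, table.d)
    if all(x == 0 for x in cells):
        raise ValueError("all-zero table has no odds ratio")
    corrected = any(x == 0 for x in cells)
    if corrected and zero_cell_constant == 0:
        raise ValueError(
            "table has a zero cell and zero_cell_constant is 0; odds ratio undefined"
        )
    k = zero_cell_constant if corrected else 0.0
    a, b, c, d = (x + k for x in cells)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + confidence / 2)
    ci_low = math.exp(math.log(orr) - z * se)
    ci_high = math.exp(math.log(orr) + z * se)
    if p_value is None:
        p_value = fisher_exact(table, sidedness)
    return AssociationResult(
        p_value=p_value,
        odds_ratio=orr,
        ci_low=ci_low,
        ci_high=ci_high,
        ef=etiological_fraction(orr),
        corrected=corrected,
        sidedness=Sidedness(sidedness),
        table=table,
        degenerate=table.degenerate,
    )


def etiological_fraction(odds_ratio: float) -> float:
    """EF = (OR - 1)/OR; negative (protective) values are permitted."""
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return (odds_ratio - 1.0) / odds_ratio


@dataclass(frozen=True)
class AdjustedPValue:
    raw: float
    adjusted: float
    bonferroni_significant: bool
    nominal_significant: bool

    @property
    def flag(self) -> str:
        """Table annotation: '**' Bonferroni, '*' nominal, '' otherwise."""
        if self.bonferroni_significant:
            return "**"
        if self.nominal_significant:
            return "*"
        return ""


def bonferroni(
    p_values: Sequence[float], m: int, alpha: float = 0.05
) -> list[AdjustedPValue]:
    """Bonferroni adjustment over m tests with significance flags."""
    if m < len(p_values) or m < 1:
        raise ValueError(f"m must be >= number of tests, got m={m}")
    out = []
    for p in p_values:
        adj = min(1.0, m * p)
        out.append(
            AdjustedPValue(
                raw=p,
                adjusted=adj,
                bonferroni_significant=adj <= alpha,
                nominal_significant=p <= alpha,
            )
        )
    return out
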