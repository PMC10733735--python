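"""Case-control carrier burden per gene/group and variant class.

A *carrier* is a sample with at least one qualifying genotype (het or
hom) in a stratum, counted once however many qualifying variants it
carries.  The *excess burden* of a stratum is the case carrier frequency
minus the control carrier frequency — the fraction of cases whose
variant burden is attributable to disease rather than background
variation.  Two distinct yield notions are exposed:

* ``patient_level_yield`` — unique genotype-positive patients / cohort;
* ``summed_stratum_frequency`` — the sum of per-gene carrier
  frequencies, which can exceed the patient-level yield because a
  patient with variants in two genes contributes to both strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .stats import (
    AdjustedPValue,
    AssociationResult,
    ContingencyTable,
    bonferroni,
    fisher_exact,
    odds_ratio_ci,
)
from .taxonomy import RarityTier, VariantClass, eligible_variant_ids
from .types import AnalysisConfig, Cohort, GenePanel, GeneGroup, Role

BOTH_CLASSES = (VariantClass.TRUNCATING, VariantClass.NONTRUNCATING)
RARE_TIER = (RarityTier.RARE_MONOALLELIC,)


@dataclass(frozen=True)
class CarrierCount:
    case_carriers: int
    control_carriers: int
    case_denominator: int
    control_denominator: int

    @property
    def case_freq(self) -> float:
        return self.case_carriers / self.case_denominator

    @property
    def control_freq(self) -> float:
        return self.control_carriers / self.control_denominator

    def table(self) -> ContingencyTable:
        return ContingencyTable(
            a=self.case_carriers,
            b=self.case_denominator - self.case_carriers,
            c=self.control_carriers,
            d=self.control_denominator - self.control_carriers,
        )


@dataclass(frozen=True)
class BurdenRow:
    stratum: str
    vclass: VariantClass
    counts: CarrierCount
    association: AssociationResult
    adjusted: Optional[AdjustedPValue] = None
    gpos_proportion: Optional[float] = None

    @property
    def case_freq(self) -> float:
        return self.counts.case_freq

    @property
    def control_freq(self) -> float:
        return self.counts.control_freq

    @property
    def excess(self) -> float:
        return self.counts.case_freq - self.counts.control_freq


def scan_strata(panel: GenePanel) -> list[str]:
    """Burden strata in panel declaration order.

    Major and minor genes are scanned individually; the myosin light
    chain and thin-filament genes are pooled into group strata; the
    recessive group is excluded from the dominant-model scan.
    """
    strata: list[str] = []
    for gene, group in panel.genes.items():
        if group == GeneGroup.RECESSIVE:
            continue
        if group in (GeneGroup.MLC, GeneGroup.THIN_FILAMENT):
            if group.value not in strata:
                strata.append(group.value)
        else:
            strata.append(gene)
    return strata


def _carrier_samples(
    cohort: Cohort,
    genes: Sequence[str],
    tiers: Iterable[RarityTier],
    classes: Iterable[VariantClass],
    cfg: AnalysisConfig,
) -> set[str]:
    eligible = eligible_variant_ids(cohort, genes, tiers, classes, cfg)
    return {g.sample_id for g in cohort.genotypes if g.variant_id in eligible}


def carrier_count(
    cohort: Cohort,
    stratum: str,
    tiers: Iterable[RarityTier],
    classes: Iterable[VariantClass] = BOTH_CLASSES,
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> CarrierCount:
    """Unique case/control carriers of a stratum with denominators.

    Denominators use per-gene callable sample counts when any sample
    declares ``callable_genes`` (a sample counts if callable for at
    least one stratum gene), otherwise the full arm sizes.
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    genes = panel.resolve_stratum(stratum)
    carriers = _carrier_samples(cohort, genes, tiers, classes, cfg)

    def denom(role: Role) -> int:
        return sum(
            1
            for s in cohort.samples_by_role(role)
            if any(s.is_callable_for(g) for g in genes)
        )

    case_den, control_den = denom(Role.CASE), denom(Role.CONTROL)
    if case_den == 0 or control_den == 0:
        raise ValueError(f"stratum {stratum!r}: empty callable denominator")
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    return CarrierCount(
        case_carriers=len(carriers & case_ids),
        control_carriers=len(carriers - case_ids),
        case_denominator=case_den,
        control_denominator=control_den,
    )


def excess_burden(
    cohort: Cohort,
    stratum: str,
    tiers: Iterable[RarityTier] = RARE_TIER,
    classes: Iterable[VariantClass] = BOTH_CLASSES,
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> BurdenRow:
    """One stratum's carrier frequencies, excess, and enrichment test."""
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    classes = tuple(classes)
    counts = carrier_count(cohort, stratum, tiers, classes, panel, cfg)
    table = counts.table()
    sided = cfg.sidedness_for("burden_scan")
    p = fisher_exact(table, sided)
    assoc = odds_ratio_ci(
        table, cfg.zero_cell_constant, sidedness=sided, p_value=p
    )
    vclass = classes[0] if len(classes) == 1 else VariantClass.EXCLUDED
    return BurdenRow(stratum=stratum, vclass=vclass, counts=counts, association=assoc)


def genotype_positive_cases(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    tiers: Iterable[RarityTier] = RARE_TIER,
    cfg: Optional[AnalysisConfig] = None,
) -> set[str]:
    """Case samples carrying >= 1 qualifying variant in a dominant panel gene."""
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    carriers = _carrier_samples(cohort, panel.dominant_genes, tiers, BOTH_CLASSES, cfg)
    return carriers & {s.sample_id for s in cohort.samples_by_role(Role.CASE)}


def patient_level_yield(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    tiers: Iterable[RarityTier] = RARE_TIER,
    cfg: Optional[AnalysisConfig] = None,
) -> tuple[int, float]:
    """(count, fraction) of unique genotype-positive patients in the cohort."""
    gpos = genotype_positive_cases(cohort, panel, tiers, cfg)
    n = cohort.n_cases
    if n == 0:
        raise ValueError("cohort has no cases")
    return len(gpos), len(gpos) / n


def summed_stratum_frequency(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    tiers: Iterable[RarityTier] = RARE_TIER,
    cfg: Optional[AnalysisConfig] = None,
) -> float:
    """Sum of per-stratum case carrier frequencies (multi-hit patients
    counted once per stratum, so this can exceed the patient-level yield)."""
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    total = 0.0
    for stratum in scan_strata(panel):
        total += carrier_count(cohort, stratum, tiers, BOTH_CLASSES, panel, cfg).case_freq
    return total


def genotype_positive_proportions(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    tiers: Iterable[RarityTier] = RARE_TIER,
    cfg: Optional[AnalysisConfig] = None,
) -> dict[tuple[str, VariantClass], float]:
    """Per-stratum share of genotype-positive patients.

    For each (stratum, class), carriers-in-stratum / total genotype-
    positive cases.  A multi-gene carrier contributes to several strata,
    so the shares may sum above 1.
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    gpos = genotype_positive_cases(cohort, panel, tiers, cfg)
    if not gpos:
        raise ValueError("no genotype-positive patients")
    out: dict[tuple[str, VariantClass], float] = {}
    for stratum in scan_strata(panel):
        genes = panel.resolve_stratum(stratum)
        for vclass in BOTH_CLASSES:
            carriers = _carrier_samples(cohort, genes, tiers, (vclass,), cfg)
            out[(stratum, vclass)] = len(carriers & gpos) / len(gpos)
    return out


def variant_association(
    cohort: Cohort,
    variant_id: str,
    cfg: Optional[AnalysisConfig] = None,
    analysis: str = "cohort_comparison",
) -> AssociationResult:
    """Single-variant carrier association (het or hom carriers per arm)."""
    cfg = cfg or AnalysisConfig()
    if variant_id not in cohort.catalogue:
        raise KeyError(f"variant {variant_id!r} not in catalogue")
    carriers = {g.sample_id for g in cohort.genotypes if g.variant_id == variant_id}
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    a = len(carriers & case_ids)
    c = len(carriers - case_ids)
    table = ContingencyTable(
        a=a, b=cohort.n_cases - a, c=c, d=cohort.n_controls - c
    )
    sided = cfg.sidedness_for(analysis)
    return odds_ratio_ci(
        table,
        cfg.zero_cell_constant,
        sidedness=sided,
        p_value=fisher_exact(table, sided),
    )


def burden_scan(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    tiers: Iterable[RarityTier] = RARE_TIER,
    cfg: Optional[AnalysisConfig] = None,
) -> list[BurdenRow]:
    """Full scan: one row per (stratum x truncating/nontruncating).

    Bonferroni m defaults to the number of rows scanned (16 for the
    default panel), matching the per-cohort annotation convention.
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    rows: list[BurdenRow] = []
    for stratum in scan_strata(panel):
        for vclass in BOTH_CLASSES:
            rows.append(
                excess_burden(cohort, stratum, tiers, (vclass,), panel, cfg)
            )
    m = cfg.n_tests_bonferroni or len(rows)
    adjusted = bonferroni([r.association.p_value for r in rows], m, cfg.alpha)
    try:
        props = genotype_positive_proportions(cohort, panel, tiers, cfg)
    except ValueError:
        props = {}
    return [
        BurdenRow(
            stratum=r.stratum,
            vclass=r.vclass,
            counts=r.counts,
            association=r.association,
            adjusted=adj,
            gpos_proportion=props.get((r.stratum, r.vclass)),
        )
        for r, adj in zip(rows, adjusted)
    ]
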