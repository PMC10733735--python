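"""Homozygosity profiling and biallelic genotype detection.

In highly consanguineous cohorts a substantial fraction of qualifying
variants occur in homozygosity, and genes whose variants are weakly
penetrant in heterozygosity surface disproportionately through
homozygous genotypes.  This module profiles homozygosity per gene/group
under the two rarity tiers, tests the association between self-reported
consanguinity and carrying a homozygous variant, and detects biallelic
(homozygous or putative compound-heterozygous) genotypes in recessive
genes.  Compound-heterozygous calls are *putative*: phase is unknown, so
a cis configuration cannot be excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

from .burden import scan_strata
from .stats import AssociationResult, ContingencyTable, fisher_exact, odds_ratio_ci
from .taxonomy import RarityTier, VariantClass, eligible_variant_ids, variant_class
from .types import AnalysisConfig, Cohort, Consanguinity, GenePanel, Role


class BiallelicMechanism(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    PUTATIVE_COMPOUND_HET = "putative_compound_het"


@dataclass(frozen=True)
class BiallelicCall:
    sample_id: str
    gene: str
    mechanism: BiallelicMechanism
    variant_ids: tuple[str, ...]


@dataclass(frozen=True)
class ZygosityProfile:
    """Per-stratum homozygosity breakdown under the two rarity tiers.

    ``rare_*`` counts cover carriers of monoallelic-rare variants;
    ``additional_*`` cover carriers of low-frequency (biallelic-rare)
    variants who carry no rare-tier variant in the stratum; totals are
    over the union of the two carrier sets.
    """

    stratum: str
    rare_carriers: int
    rare_hom: int
    additional_carriers: int
    additional_hom: int
    total_carriers: int
    total_hom: int

    @property
    def hom_fraction(self) -> float:
        return 0.0 if self.total_carriers == 0 else self.total_hom / self.total_carriers


def _hom_samples(
    cohort: Cohort, variant_ids: set[str], case_ids: set[str]
) -> set[str]:
    return {
        g.sample_id
        for g in cohort.genotypes
        if g.variant_id in variant_ids
        and g.zygosity.value == "hom"
        and g.sample_id in case_ids
    }


def _carrier_sampleset(
    cohort: Cohort, variant_ids: set[str], case_ids: set[str]
) -> set[str]:
    return {
        g.sample_id
        for g in cohort.genotypes
        if g.variant_id in variant_ids and g.sample_id in case_ids
    }


def homozygosity_profile(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> list[ZygosityProfile]:
    """Homozygosity breakdown for every dominant-model stratum (cases)."""
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    profiles: list[ZygosityProfile] = []
    for stratum in scan_strata(panel):
        genes = panel.resolve_stratum(stratum)
        rare_ids = eligible_variant_ids(
            cohort, genes, (RarityTier.RARE_MONOALLELIC,), cfg=cfg
        )
        lf_ids = eligible_variant_ids(
            cohort, genes, (RarityTier.LOW_FREQUENCY_BIALLELIC,), cfg=cfg
        )
        rare_carriers = _carrier_sampleset(cohort, rare_ids, case_ids)
        lf_carriers = _carrier_sampleset(cohort, lf_ids, case_ids)
        additional = lf_carriers - rare_carriers
        rare_hom = _hom_samples(cohort, rare_ids, case_ids)
        additional_hom = _hom_samples(cohort, lf_ids, case_ids) & additional
        total_carriers = rare_carriers | lf_carriers
        total_hom = rare_hom | _hom_samples(cohort, lf_ids, case_ids)
        profiles.append(
            ZygosityProfile(
                stratum=stratum,
                rare_carriers=len(rare_carriers),
                rare_hom=len(rare_hom),
                additional_carriers=len(additional),
                additional_hom=len(additional_hom),
                total_carriers=len(total_carriers),
                total_hom=len(total_hom),
            )
        )
    return profiles


def homozygous_carrier_rate(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    tier: RarityTier = RarityTier.RARE_MONOALLELIC,
    cfg: Optional[AnalysisConfig] = None,
    role: Role = Role.CASE,
) -> tuple[int, float]:
    """(count, fraction) of samples homozygous for >= 1 tier variant.

    Counts over the dominant panel genes, in the given arm.
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    arm = {s.sample_id for s in cohort.samples_by_role(role)}
    if not arm:
        raise ValueError(f"cohort has no {Role(role).value} samples")
    ids = eligible_variant_ids(cohort, panel.dominant_genes, (tier,), cfg=cfg)
    homs = _hom_samples(cohort, ids, arm)
    return len(homs), len(homs) / len(arm)


def _biallelic_tier_hom_carriers(
    cohort: Cohort, panel: GenePanel, cfg: AnalysisConfig
) -> set[str]:
    """Cases homozygous for any variant rare enough for biallelic disease."""
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    ids = eligible_variant_ids(
        cohort,
        panel.dominant_genes,
        (RarityTier.RARE_MONOALLELIC, RarityTier.LOW_FREQUENCY_BIALLELIC),
        cfg=cfg,
    )
    return _hom_samples(cohort, ids, case_ids)


@dataclass(frozen=True)
class ConsanguinityResult:
    association: AssociationResult
    hom_rate_consanguineous: tuple[int, int]
    hom_rate_nonconsanguineous: tuple[int, int]
    hom_rate_unknown: tuple[int, int]
    hom_carriers_reporting_no: float


def consanguinity_association(
    cohort: Cohort,
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> ConsanguinityResult:
    """Fisher test of homozygous-carrier status against consanguinity.

    Homozygous-carrier status covers both rarity tiers (any variant rare
    enough for biallelic disease).  Patients of unknown consanguinity
    are excluded from the test but their rate is reported, as is the
    fraction of homozygous carriers who reported non-consanguineous
    parents (an underreporting indicator).
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    hom_carriers = _biallelic_tier_hom_carriers(cohort, panel, cfg)
    by_status: dict[Consanguinity, list[str]] = {c: [] for c in Consanguinity}
    for s in cohort.samples_by_role(Role.CASE):
        by_status[s.consanguinity].append(s.sample_id)
    n_yes = len(by_status[Consanguinity.YES])
    n_no = len(by_status[Consanguinity.NO])
    if n_yes == 0 or n_no == 0:
        raise ValueError(
            "consanguinity association requires >= 1 case each with "
            "consanguinity yes and no"
        )
    hom_yes = len(hom_carriers & set(by_status[Consanguinity.YES]))
    hom_no = len(hom_carriers & set(by_status[Consanguinity.NO]))
    n_unk = len(by_status[Consanguinity.UNKNOWN])
    hom_unk = len(hom_carriers & set(by_status[Consanguinity.UNKNOWN]))
    table = ContingencyTable(a=hom_yes, b=n_yes - hom_yes, c=hom_no, d=n_no - hom_no)
    sided = cfg.sidedness_for("consanguinity")
    assoc = odds_ratio_ci(
        table,
        cfg.zero_cell_constant,
        sidedness=sided,
        p_value=fisher_exact(table, sided),
    )
    return ConsanguinityResult(
        association=assoc,
        hom_rate_consanguineous=(hom_yes, n_yes),
        hom_rate_nonconsanguineous=(hom_no, n_no),
        hom_rate_unknown=(hom_unk, n_unk),
        hom_carriers_reporting_no=(
            hom_no / len(hom_carriers) if hom_carriers else 0.0
        ),
    )


def detect_biallelic(
    cohort: Cohort,
    gene: str,
    cfg: Optional[AnalysisConfig] = None,
    role: Role = Role.CASE,
) -> tuple[list[BiallelicCall], float]:
    """Biallelic calls in *gene* and their frequency among callable samples.

    A sample homozygous for an eligible variant (popmax FAF within the
    biallelic bound, protein-altering) is called ``homozygous``; a
    sample with >= 2 distinct eligible heterozygous variants and no
    homozygous one is called ``putative_compound_het``.  Homozygosity
    takes precedence; all eligible variant ids carried are listed on the
    call.  The denominator is the per-gene callable sample count.
    """
    cfg = cfg or AnalysisConfig()
    arm = cohort.samples_by_role(role)
    eligible = {
        v.variant_id
        for v in cohort.catalogue.values()
        if v.gene == gene
        and v.faf_for_filtering <= cfg.faf_biallelic
        and variant_class(v) != VariantClass.EXCLUDED
    }
    index = cohort.genotype_index()
    calls: list[BiallelicCall] = []
    for s in arm:
        if not s.is_callable_for(gene):
            continue
        gts = [g for g in index[s.sample_id] if g.variant_id in eligible]
        if not gts:
            continue
        variant_ids = tuple(sorted(g.variant_id for g in gts))
        homs = [g for g in gts if g.zygosity.value == "hom"]
        if homs:
            calls.append(
                BiallelicCall(
                    sample_id=s.sample_id,
                    gene=gene,
                    mechanism=BiallelicMechanism.HOMOZYGOUS,
                    variant_ids=variant_ids,
                )
            )
        elif len(gts) >= 2:
            calls.append(
                BiallelicCall(
                    sample_id=s.sample_id,
                    gene=gene,
                    mechanism=BiallelicMechanism.PUTATIVE_COMPOUND_HET,
                    variant_ids=variant_ids,
                )
            )
    callable_n = cohort.callable_count(gene, role)
    if callable_n == 0:
        raise ValueError(f"no {Role(role).value} samples callable for {gene!r}")
    return calls, len(calls) / callable_n
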