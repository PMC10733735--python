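"""Consequence taxonomy and two-tier rarity filtering.

Variants are dichotomised into *truncating* (nonsense, frameshift,
canonical splice-site) and *nontruncating* (missense, in-frame indel)
classes; synonymous and unclassified consequences are excluded from all
burden counts.  Rarity is assessed against the popmax filtering allele
frequency (FAF) at two nested thresholds: variants rare enough to cause
monoallelic (dominant) disease, and additional low-frequency variants
still rare enough to cause biallelic (recessive-pattern) disease.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Sequence

from .types import AnalysisConfig, Cohort, Consequence, GenePanel, Variant


class VariantClass(str, enum.Enum):
    TRUNCATING = "truncating"
    NONTRUNCATING = "nontruncating"
    EXCLUDED = "excluded"


class RarityTier(str, enum.Enum):
    RARE_MONOALLELIC = "rare_monoallelic"
    LOW_FREQUENCY_BIALLELIC = "low_frequency_biallelic"
    NONRARE = "nonrare"


_TRUNCATING = {
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.SPLICE_DONOR,
    Consequence.SPLICE_ACCEPTOR,
}
_NONTRUNCATING = {Consequence.MISSENSE, Consequence.INFRAME_INDEL}


def variant_class(v: Variant) -> VariantClass:
    """Truncating/nontruncating dichotomy; total on the consequence enum."""
    if v.consequence in _TRUNCATING:
        return VariantClass.TRUNCATING
    if v.consequence in _NONTRUNCATING:
        return VariantClass.NONTRUNCATING
    return VariantClass.EXCLUDED


def assign_tier(v: Variant, cfg: Optional[AnalysisConfig] = None) -> RarityTier:
    """Rarity tier of a variant by popmax FAF.

    Boundaries are inclusive on the upper edge of each tier; a variant
    absent from the reference population (missing FAF) sits at frequency 0
    and is therefore rare_monoallelic.
    """
    cfg = cfg or AnalysisConfig()
    faf = v.faf_for_filtering
    if faf <= cfg.faf_monoallelic:
        return RarityTier.RARE_MONOALLELIC
    if faf <= cfg.faf_biallelic:
        return RarityTier.LOW_FREQUENCY_BIALLELIC
    return RarityTier.NONRARE


def tier_eligible_biallelic(v: Variant, cfg: Optional[AnalysisConfig] = None) -> bool:
    """True if the variant is rare enough for biallelic disease.

    The monoallelic tier nests inside the biallelic-eligible set.
    """
    cfg = cfg or AnalysisConfig()
    return v.faf_for_filtering <= cfg.faf_biallelic


def select_variants(
    cohort: Cohort,
    panel: GenePanel,
    tiers: Iterable[RarityTier],
    classes: Iterable[VariantClass],
    genes: Iterable[str],
    cfg: Optional[AnalysisConfig] = None,
) -> list[Variant]:
    """Variants of the catalogue matching all selectors.

    Returned in deterministic order (gene, then hgvs_c).  Selector genes
    must belong to the panel.
    """
    cfg = cfg or AnalysisConfig()
    tiers = {RarityTier(t) for t in tiers}
    classes = {VariantClass(c) for c in classes}
    genes = set(genes)
    if not tiers or not classes or not genes:
        raise ValueError("selector sets must be non-empty")
    for g in sorted(genes):
        if g not in panel.genes:
            raise KeyError(f"gene {g!r} is not in the panel")
    hits = [
        v
        for v in cohort.catalogue.values()
        if v.gene in genes
        and assign_tier(v, cfg) in tiers
        and variant_class(v) in classes
    ]
    return sorted(hits, key=lambda v: (v.gene, v.hgvs_c))


def eligible_variant_ids(
    cohort: Cohort,
    genes: Sequence[str],
    tiers: Iterable[RarityTier],
    classes: Iterable[VariantClass] = (
        VariantClass.TRUNCATING,
        VariantClass.NONTRUNCATING,
    ),
    cfg: Optional[AnalysisConfig] = None,
) -> set[str]:
    """Variant ids in *genes* matching the tier/class selectors.

    Convenience used by the burden and zygosity modules; unlike
    :func:`select_variants` it does not require panel membership of the
    gene list (callers pass panel-resolved strata).
    """
    cfg = cfg or AnalysisConfig()
    tiers = {RarityTier(t) for t in tiers}
    classes = {VariantClass(c) for c in classes}
    gene_set = set(genes)
    return {
        v.variant_id
        for v in cohort.catalogue.values()
        if v.gene in gene_set
        and assign_tier(v, cfg) in tiers
        and variant_class(v) in classes
    }
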