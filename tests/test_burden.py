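"""Carrier counting, excess burden, genotype-positive accounting."""

import pytest

from hcmcohort import (
    AnalysisConfig,
    Consequence,
    GenePanel,
    RarityTier,
    VariantClass,
    burden_scan,
    carrier_count,
    excess_burden,
    genotype_positive_proportions,
    patient_level_yield,
    summed_stratum_frequency,
    variant_association,
)
from hcmcohort.burden import scan_strata

from conftest import make_cohort, make_variant

RARE = (RarityTier.RARE_MONOALLELIC,)


def _two_variant_cohort():
    variants = [
        make_variant("MYH7", "c.1A>G", Consequence.MISSENSE),
        make_variant("MYH7", "c.2A>G", Consequence.MISSENSE),
        make_variant("MYBPC3", "c.3A>G", Consequence.MISSENSE),
    ]
    genotypes = [
        ("S1", "MYH7:c.1A>G", "het"),
        ("S1", "MYH7:c.2A>G", "het"),  # same gene twice: one carrier
        ("S2", "MYH7:c.1A>G", "het"),
        ("S2", "MYBPC3:c.3A>G", "het"),  # two genes: counted in each
        ("T1", "MYBPC3:c.3A>G", "hom"),
    ]
    return make_cohort(variants, genotypes)


def test_carrier_counted_once_per_stratum():
    cohort = _two_variant_cohort()
    cc = carrier_count(cohort, "MYH7", RARE)
    assert (cc.case_carriers, cc.control_carriers) == (2, 0)
    cc2 = carrier_count(cohort, "MYBPC3", RARE)
    assert (cc2.case_carriers, cc2.control_carriers) == (1, 1)


def test_multi_gene_carrier_counts_in_each_stratum():
    cohort = _two_variant_cohort()
    n_gpos, _ = patient_level_yield(cohort)
    assert n_gpos == 2  # S1, S2 unique
    summed = summed_stratum_frequency(cohort)
    # S2 contributes to both gene strata: 2/4 + 1/4 = 3/4
    assert summed == pytest.approx(0.75)


def test_excess_equals_frequency_difference_exactly():
    cohort = _two_variant_cohort()
    row = excess_burden(cohort, "MYH7", RARE)
    cc = row.counts
    assert row.excess == cc.case_carriers / cc.case_denominator - (
        cc.control_carriers / cc.control_denominator
    )


def test_carrier_count_idempotent_under_duplicate_variants():
    # the same sample carrying many qualifying variants stays one carrier
    variants = [
        make_variant("MYH7", f"c.{i}A>G", Consequence.MISSENSE) for i in range(1, 6)
    ]
    genotypes = [("S1", f"MYH7:c.{i}A>G", "het") for i in range(1, 6)]
    cohort = make_cohort(variants, genotypes)
    assert carrier_count(cohort, "MYH7", RARE).case_carriers == 1


def test_callable_genes_shrink_denominator(egypt_cohort):
    cc = carrier_count(egypt_cohort, "TRIM63", RARE, panel=GenePanel())
    assert cc.case_denominator == 374
    assert cc.control_denominator == 400
    cc2 = carrier_count(egypt_cohort, "MYH7", RARE)
    assert cc2.case_denominator == 514


def test_scan_strata_order_and_count():
    strata = scan_strata(GenePanel())
    assert strata == [
        "MYH7", "MYBPC3", "MLC", "thin_filament",
        "PLN", "ACTN2", "CSRP3", "JPH2",
    ]


def test_burden_scan_rows_bonferroni_and_mlc_significance(egypt_cohort):
    rows = burden_scan(egypt_cohort)
    assert len(rows) == 16
    mlc = next(
        r for r in rows
        if r.stratum == "MLC" and r.vclass is VariantClass.NONTRUNCATING
    )
    # strong enrichment: 28 case carriers vs 0 controls (rare tier)
    assert mlc.adjusted.bonferroni_significant
    assert mlc.association.p_value < 1e-5
    myh7 = next(
        r for r in rows
        if r.stratum == "MYH7" and r.vclass is VariantClass.NONTRUNCATING
    )
    assert myh7.counts.case_carriers == 82  # 99 carriers minus 17 frameshift-only


def test_empty_catalogue_gives_all_zero_rows():
    cohort = make_cohort([], [])
    rows = burden_scan(cohort)
    assert all(r.counts.case_carriers == 0 for r in rows)
    assert all(r.association.p_value == 1.0 for r in rows)


def test_genotype_positive_proportions_single_carrier():
    variants = [make_variant("PLN", "c.1A>G", Consequence.MISSENSE)]
    cohort = make_cohort(variants, [("S1", "PLN:c.1A>G", "het")])
    props = genotype_positive_proportions(cohort)
    assert props[("PLN", VariantClass.NONTRUNCATING)] == 1.0
    assert props[("MYH7", VariantClass.NONTRUNCATING)] == 0.0


def test_genotype_positive_proportions_error_when_no_carriers():
    cohort = make_cohort([], [])
    with pytest.raises(ValueError, match="genotype-positive"):
        genotype_positive_proportions(cohort)


def test_patient_level_yield_on_fixture(egypt_cohort):
    n, frac = patient_level_yield(egypt_cohort)
    assert n == 240
    assert frac == pytest.approx(0.467, abs=0.0005)
    assert summed_stratum_frequency(egypt_cohort) == pytest.approx(0.527, abs=0.0005)


def test_single_variant_association_on_fixture(egypt_cohort):
    cfg = AnalysisConfig()
    glu441 = variant_association(egypt_cohort, "MYBPC3:c.1321G>A", cfg)
    assert glu441.odds_ratio == pytest.approx(2.4, abs=0.01)
    assert glu441.p_value == pytest.approx(0.03, abs=0.005)
    arg278 = variant_association(egypt_cohort, "TNNT2:c.832C>T", cfg)
    assert arg278.corrected
    assert arg278.odds_ratio == pytest.approx(10.2, abs=0.1)
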