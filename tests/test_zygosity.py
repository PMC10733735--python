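"""Homozygosity profiling, consanguinity association, biallelic calls."""

import numpy as np
import pytest

from hcmcohort import (
    AnalysisConfig,
    BiallelicMechanism,
    Consequence,
    RarityTier,
    consanguinity_association,
    detect_biallelic,
    homozygosity_profile,
    homozygous_carrier_rate,
    sample_genotype,
)

from conftest import make_cohort, make_variant


def test_rare_and_lowfreq_homozygote_rates_on_fixture(egypt_cohort):
    n, frac = homozygous_carrier_rate(egypt_cohort, tier=RarityTier.RARE_MONOALLELIC)
    assert n == 21 and frac == pytest.approx(0.041, abs=0.0005)
    n2, frac2 = homozygous_carrier_rate(
        egypt_cohort, tier=RarityTier.LOW_FREQUENCY_BIALLELIC
    )
    assert n2 == 11 and frac2 == pytest.approx(0.021, abs=0.0005)


def test_gene_profiles_match_published_totals(egypt, cfg):
    cohort, expected = egypt
    profiles = {p.stratum: p for p in homozygosity_profile(cohort, cfg=cfg)}
    for stratum, (n_rare, hom_rare, n_add, hom_add) in expected["table4"].items():
        p = profiles[stratum]
        assert (p.rare_carriers, p.rare_hom) == (n_rare, hom_rare), stratum
        assert (p.additional_carriers, p.additional_hom) == (n_add, hom_add), stratum
    assert profiles["CSRP3"].hom_fraction == pytest.approx(5 / 15)
    assert profiles["MLC"].hom_fraction == pytest.approx(10 / 39)


def test_het_only_cohort_has_zero_hom_fraction():
    variants = [make_variant("MYH7", "c.1A>G")]
    cohort = make_cohort(variants, [("S1", "MYH7:c.1A>G", "het")])
    assert all(p.hom_fraction == 0.0 for p in homozygosity_profile(cohort))


def test_hom_carrier_count_vs_per_variant_row_sum():
    variants = [make_variant("MYH7", "c.1A>G"), make_variant("MYH7", "c.2A>G")]
    # distinct homozygotes: carrier count equals row-sum
    cohort = make_cohort(
        variants, [("S1", "MYH7:c.1A>G", "hom"), ("S2", "MYH7:c.2A>G", "hom")]
    )
    assert homozygous_carrier_rate(cohort)[0] == 2
    # one sample homozygous at two variants: carrier count < row-sum
    multi = make_cohort(
        variants, [("S1", "MYH7:c.1A>G", "hom"), ("S1", "MYH7:c.2A>G", "hom")]
    )
    assert homozygous_carrier_rate(multi)[0] == 1


def test_empty_arm_rejected():
    cohort = make_cohort([make_variant("MYH7", "c.1A>G")], [], n_cases=0, n_controls=2)
    with pytest.raises(ValueError, match="no case"):
        homozygous_carrier_rate(cohort)


class TestConsanguinity:
    def test_fixture_reproduces_stratified_rates(self, egypt_cohort):
        res = consanguinity_association(egypt_cohort)
        assert res.hom_rate_consanguineous == (14, 99)
        assert res.hom_rate_nonconsanguineous == (10, 249)
        assert res.hom_rate_unknown == (8, 166)
        assert res.association.p_value == pytest.approx(0.0014, rel=0.05)
        assert res.hom_carriers_reporting_no == pytest.approx(10 / 32)

    def test_all_unknown_cohort_rejected(self):
        variants = [make_variant("MYH7", "c.1A>G")]
        cohort = make_cohort(variants, [("S1", "MYH7:c.1A>G", "hom")])
        with pytest.raises(ValueError, match="consanguinity"):
            consanguinity_association(cohort)

    def test_direction_emerges_with_inbreeding(self):
        # consanguineous samples homozygous far more often -> OR > 1
        from hcmcohort import SimCohortSpec, SimVariantSpec, simulate_cohort

        spec = SimCohortSpec(
            n_cases=400,
            n_controls=50,
            variants=(
                SimVariantSpec(
                    "MYL2", Consequence.MISSENSE, q=0.03, faf_popmax=1e-5,
                    risk_multiplier_het=1.5, risk_multiplier_hom=80,
                ),
            ),
            consanguinity_rate=0.4,
            inbreeding_F=0.0625,
            baseline_risk=0.01,
            consanguinity_underreport_rate=0.0,
            consanguinity_missing_rate=0.0,
            seed=11,
        )
        cohort = simulate_cohort(spec).cohort
        res = consanguinity_association(cohort)
        assert res.association.odds_ratio > 1.0


class TestBiallelic:
    def test_fixture_trim63_calls(self, egypt_cohort):
        calls, freq = detect_biallelic(egypt_cohort, "TRIM63")
        mechanisms = [c.mechanism for c in calls]
        assert len(calls) == 8
        assert mechanisms.count(BiallelicMechanism.HOMOZYGOUS) == 7
        assert mechanisms.count(BiallelicMechanism.PUTATIVE_COMPOUND_HET) == 1
        assert freq == pytest.approx(8 / 374)
        compound = next(
            c for c in calls if c.mechanism is BiallelicMechanism.PUTATIVE_COMPOUND_HET
        )
        assert len(compound.variant_ids) == 2

    def test_single_het_is_no_call(self):
        variants = [make_variant("TRIM63", "c.1A>G", faf=1e-4)]
        cohort = make_cohort(variants, [("S1", "TRIM63:c.1A>G", "het")])
        calls, freq = detect_biallelic(cohort, "TRIM63")
        assert calls == [] and freq == 0.0

    def test_hom_precedence_over_compound_het(self):
        variants = [
            make_variant("TRIM63", "c.1A>G", faf=1e-4),
            make_variant("TRIM63", "c.2A>G", faf=1e-4),
            make_variant("TRIM63", "c.3A>G", faf=1e-4),
        ]
        cohort = make_cohort(
            variants,
            [
                ("S1", "TRIM63:c.1A>G", "hom"),
                ("S1", "TRIM63:c.2A>G", "het"),
                ("S1", "TRIM63:c.3A>G", "het"),
            ],
        )
        calls, _ = detect_biallelic(cohort, "TRIM63")
        assert len(calls) == 1
        assert calls[0].mechanism is BiallelicMechanism.HOMOZYGOUS
        assert calls[0].variant_ids == (
            "TRIM63:c.1A>G", "TRIM63:c.2A>G", "TRIM63:c.3A>G",
        )

    def test_nonrare_variants_excluded(self):
        variants = [make_variant("TRIM63", "c.1A>G", faf=5e-3)]  # above bound
        cohort = make_cohort(variants, [("S1", "TRIM63:c.1A>G", "hom")])
        calls, _ = detect_biallelic(cohort, "TRIM63")
        assert calls == []


def test_hom_fraction_among_carriers_matches_closed_form():
    """Inbred Hardy-Weinberg: hom share of carriers at F, q."""
    q, F = 0.02, 0.0625
    rng = np.random.default_rng(5)
    g = sample_genotype(q, F, rng, size=400_000)
    hom = np.sum(g == 2)
    het = np.sum(g == 1)
    p_hom = q * q + F * q * (1 - q)
    p_het = 2 * q * (1 - q) * (1 - F)
    expected = p_hom / (p_hom + p_het)
    observed = hom / (hom + het)
    se = np.sqrt(expected * (1 - expected) / (hom + het))
    assert abs(observed - expected) < 4 * se
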