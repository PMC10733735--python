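"""Homozygosity profiling and the consanguinity association.

Shows, per gene/group, how many qualifying carriers are homozygous under
the two rarity tiers, and tests whether self-reported first-cousin
consanguinity predicts carrying a homozygous variant.
"""

from hcmcohort import RarityTier, consanguinity_association, egypt_like_fixture, homozygosity_profile, homozygous_carrier_rate
from hcmcohort.pipeline import fmt_count_frac

cohort, _ = egypt_like_fixture()

n, frac = homozygous_carrier_rate(cohort, tier=RarityTier.RARE_MONOALLELIC)
print(f"rare-tier homozygous carriers:          {fmt_count_frac(n, cohort.n_cases)}")
n, frac = homozygous_carrier_rate(cohort, tier=RarityTier.LOW_FREQUENCY_BIALLELIC)
print(f"low-frequency-tier homozygous carriers: {fmt_count_frac(n, cohort.n_cases)}")

print(f"\n{'stratum':14s} {'rare hom':>14s} {'additional hom':>16s} {'total hom':>14s}")
for p in homozygosity_profile(cohort):
    print(
        f"{p.stratum:14s} {fmt_count_frac(p.rare_hom, p.rare_carriers):>14s} "
        f"{fmt_count_frac(p.additional_hom, p.additional_carriers):>16s} "
        f"{fmt_count_frac(p.total_hom, p.total_carriers):>14s}"
    )

res = consanguinity_association(cohort)
print(
    f"\nhomozygous-carrier rate: consanguineous {fmt_count_frac(*res.hom_rate_consanguineous, 0)}"
    f" vs non-consanguineous {fmt_count_frac(*res.hom_rate_nonconsanguineous, 0)}"
    f" (p = {res.association.p_value:.2g}); unknown family data"
    f" {fmt_count_frac(*res.hom_rate_unknown)}"
)
print(
    "\nMinor genes with high homozygous fractions are candidates for"
    "\nvariants that are weakly penetrant in heterozygosity and surface"
    "\nonly where consanguinity makes homozygosity common."
)
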