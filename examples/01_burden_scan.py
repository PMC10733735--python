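"""Case-control rare-variant burden scan on the bundled cohort fixture.

Builds the count-exact 514-case / 400-control cohort, scans every
gene/group stratum for carrier enrichment, and prints the excess burden
(case carrier frequency minus control carrier frequency), the one-sided
Fisher p with Bonferroni flags, and the two genotype-yield notions.
"""

from hcmcohort import burden_scan, egypt_like_fixture, patient_level_yield, summed_stratum_frequency
from hcmcohort.pipeline import fmt_pct

cohort, _ = egypt_like_fixture()
rows = burden_scan(cohort)

print(f"{'stratum':14s} {'class':14s} {'case':>8s} {'control':>8s} {'excess':>8s}  p")
for r in rows:
    print(
        f"{r.stratum:14s} {r.vclass.value:14s} "
        f"{fmt_pct(r.case_freq):>8s} {fmt_pct(r.control_freq):>8s} "
        f"{fmt_pct(r.excess):>8s}  {r.association.p_value:.2g}{r.adjusted.flag}"
    )

n, frac = patient_level_yield(cohort)
print(f"\ngenotype-positive patients: {n} ({fmt_pct(frac, 1)} of cases)")
print(f"summed stratum frequency:   {fmt_pct(summed_stratum_frequency(cohort), 1)}")
print(
    "\nAn excess of X% means X% of cases carry variants in that stratum"
    "\nbeyond the background rate seen in matched controls; ** marks"
    "\nBonferroni-significant one-sided enrichment over 16 strata."
)
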