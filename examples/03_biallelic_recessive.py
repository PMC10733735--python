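"""Biallelic genotype detection in a recessive gene.

A gene carried on only some panel versions has a reduced callable
denominator; biallelic genotypes are homozygotes or samples with two
distinct eligible heterozygous variants (putative compound
heterozygotes — phase is unknown).
"""

from hcmcohort import detect_biallelic, egypt_like_fixture
from hcmcohort.pipeline import fmt_count_frac

cohort, _ = egypt_like_fixture()
calls, freq = detect_biallelic(cohort, "TRIM63")

callable_n = cohort.callable_count("TRIM63", "case")
print(f"TRIM63 callable cases: {callable_n} of {cohort.n_cases}")
print(f"biallelic genotypes:   {fmt_count_frac(len(calls), callable_n, 2)}")
for c in calls:
    print(f"  {c.sample_id}: {c.mechanism.value:22s} {', '.join(c.variant_ids)}")
print(
    "\nEach call is one patient plausibly biallelic for the recessive"
    "\ngene; compound-het calls are putative because cis configurations"
    "\ncannot be excluded without phase data."
)
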