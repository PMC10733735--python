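"""Simulate a consanguineous case-control cohort and recover a known OR.

The generator draws genotypes under Hardy-Weinberg with inbreeding
(F = 1/16 for offspring of first cousins), applies a multiplicative
disease-risk model, and rejection-samples cases and controls.  Here a
single variant with genotype relative risk 5 is simulated and its odds
ratio re-estimated from the synthetic cohort.
"""

import dataclasses

from hcmcohort import SimCohortSpec, SimVariantSpec, simulate_cohort, variant_association
from hcmcohort.types import Consequence

spec = SimCohortSpec(
    n_cases=2000,
    n_controls=2000,
    variants=(
        SimVariantSpec(
            "MYH7", Consequence.MISSENSE, q=0.005, faf_popmax=1e-5,
            risk_multiplier_het=5.0, risk_multiplier_hom=25.0, hgvs_c="c.demo",
        ),
    ),
    baseline_risk=0.01,
    consanguinity_rate=0.284,
    seed=1,
)
result = simulate_cohort(spec)
assoc = variant_association(result.cohort, "MYH7:c.demo")
print(
    f"true genotype relative risk 5.0 -> estimated OR "
    f"{assoc.odds_ratio:.2f} (95% CI {assoc.ci_low:.2f}-{assoc.ci_high:.2f})"
)

consang = result.sample_truth["true_consanguinity"].mean()
print(f"simulated consanguinity rate: {consang:.3f} (spec {spec.consanguinity_rate})")
print(
    "\nUnder a rare-disease model the carrier odds ratio approximates"
    "\nthe genotype relative risk; the CI should cover 5.0 in ~95% of"
    "\nseeds."
)
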