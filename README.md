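# hcmcohort

Cohort-level rare-variant architecture analysis for consanguineous
case–control studies of hypertrophic cardiomyopathy (HCM) and similar
dominant panel diseases.

Clinical genetics in understudied, highly consanguineous populations
faces two linked problems: reference databases (gnomAD-style) carry too
few matched samples to filter variants reliably, and a large share of
qualifying variants surface in homozygosity — including variants that
are weakly penetrant in heterozygosity and therefore invisible in
outbred cohorts. `hcmcohort` implements the analysis stack such a study
needs, for people running gene-panel case–control comparisons:

* **Two-tier rarity filtering** on the popmax filtering allele
  frequency (FAF): variants rare enough for monoallelic disease
  (FAF ≤ 4×10⁻⁵) and additional low-frequency variants still rare
  enough for biallelic disease (FAF ≤ 1.26×10⁻³), with truncating /
  nontruncating consequence classes.
* **Carrier burden per gene/group**: excess burden
  `excess = a/(a+b) − c/(c+d)` on 2×2 carrier tables, one-sided
  Fisher's exact tests with Bonferroni flags, and genotype-positive
  attribution per gene.
* **Exact-test kernel**: odds ratio `OR = ad/bc` with Haldane–Anscombe
  zero-cell correction (add 0.5 to every cell), Woolf (log-normal)
  confidence intervals, and the etiological fraction
  `EF = (OR − 1)/OR` — the probability that a case's variant of the
  tested class is disease-causing.
* **Homozygosity and biallelic analysis**: per-gene homozygous
  fractions under both tiers, a consanguinity × homozygous-carrier
  association test, and biallelic calls (homozygous or putative
  compound-heterozygous) in recessive genes with per-gene callable
  denominators.
* **ACMG/AMP evidence engine** with cohort-informed extensions: the
  standard combination table; a regional rule that grants PM1 at
  *strong* strength to nontruncating variants inside a protein region
  whose cohort EF ≥ 0.95; evidence deltas from matched-control
  frequencies; and patient-level prioritisation (P > LP > VUS) with
  actionable-yield accounting.
* **A synthetic cohort generator** (Hardy–Weinberg with inbreeding
  F = 1/16 for first-cousin offspring, multiplicative disease risk,
  rejection-sampled case/control arms) and a deterministic,
  count-exact 514-case / 400-control fixture rebuilt from published
  cohort tables, so every stage runs without any external download.

## Worked example

```python
from hcmcohort import (
    RarityTier, egypt_like_fixture, homozygous_carrier_rate,
    detect_biallelic, variant_association, cluster_ef, MYH7_CLUSTER,
)

cohort, expected = egypt_like_fixture()   # 514 cases vs 400 controls

n, frac = homozygous_carrier_rate(cohort, tier=RarityTier.RARE_MONOALLELIC)
print(n, round(100 * frac, 1))            # 21 4.1

calls, freq = detect_biallelic(cohort, "TRIM63")
print(len(calls), round(100 * freq, 2))   # 8 2.14

assoc = variant_association(cohort, "MYBPC3:c.1321G>A")
print(round(assoc.odds_ratio, 1))         # 2.4

print(round(cluster_ef(cohort, MYH7_CLUSTER).ef, 2))  # 0.99
```

4.1% of cases are homozygous for a rare-tier panel variant (21/514);
2.14% of the 374 TRIM63-callable cases carry a biallelic genotype in
the recessive gene; the recurrent low-frequency MYBPC3 variant is
2.4-fold enriched over matched controls; and rare missense variants in
the MYH7 case-enriched region (residues 167–931) reach an etiological
fraction of 0.99, activating the strong regional evidence rule.

The `examples/` directory has one short narrative script per
capability (burden scan, homozygosity, recessive biallelic detection,
reclassification, simulation); each prints the numbers it computes and
a line on what they mean. A thin CLI wraps the same functions:

```bash
hcmcohort simulate --out sim/ --seed 1
hcmcohort run --config config.yaml --out results/
```

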