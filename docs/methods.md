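# Methods

## Scope and data model

The package analyses a gene-panel case–control cohort: a variant
catalogue (gene, HGVS c./p., consequence class, gnomAD-style popmax
filtering allele frequency), a genotype table (sample, variant,
het/hom), and a sample manifest (case/control role, self-reported
consanguinity, optional per-gene callability). All fourteen panel
genes are autosomal; hemizygous genotypes are out of scope and
non-autosomal records are rejected at VCF ingestion. Compound
heterozygosity is never a stored zygosity — it is derived per gene
from unphased het genotypes, and therefore always reported as
*putative*.

A missing popmax FAF means the variant is absent from the reference
population. It is treated as frequency 0 for tier filtering (the most
conservative reading) but stored as a distinct absent-from-reference
flag so reports can distinguish "never observed" from "observed at 0".

## Rarity tiers and consequence classes

Two nested tiers, boundaries inclusive on the upper edge:

| tier | bound | disease model |
|---|---|---|
| rare_monoallelic | FAF ≤ 4×10⁻⁵ | dominant (monoallelic) |
| low_frequency_biallelic | 4×10⁻⁵ < FAF ≤ 1.26×10⁻³ | recessive-pattern (biallelic) |

Nonsense, frameshift and canonical splice-site changes are
*truncating*; missense and in-frame indels are *nontruncating*;
synonymous and unclassified consequences are excluded from every
burden count. A frameshift predicted to escape nonsense-mediated decay
remains truncating — escape predictions do not change the class.
The separate "nonrare" recurrence analysis uses the window
4×10⁻⁵ < FAF < 0.01, strict on the upper edge.

## Statistics

Carrier tables are 2×2 (case carriers a, case non-carriers b, control
carriers c, d). Enrichment scans use one-sided (greater) Fisher exact
tests; cross-cohort comparisons are two-sided ("sum of tables with
probability ≤ observed" convention, with the usual 1+10⁻⁷ tie
tolerance). A degenerate carrier margin returns p = 1 and is flagged.
The consanguinity association is one-sided by default — homozygosity
under consanguinity is a directional hypothesis — and the sidedness of
every analysis is configurable.

The odds ratio is the sample OR = ad/bc. If any cell is zero, the
Haldane–Anscombe constant (default 0.5) is added to *all four* cells
before estimation and the result is flagged as corrected; this
convention reproduces standard zero-cell ORs such as 6/514 vs 0/400 →
OR 10.2 (95% CI 0.6–182.3). Confidence intervals are Woolf
(log-normal) on the possibly-corrected cells. Published CIs for some
single-variant tests are wider than the Woolf interval for the same
table (different CI methods were likely mixed at source); this package
reports Woolf CIs throughout and does not force agreement.

The etiological fraction EF = (OR − 1)/OR estimates the probability
that a case's variant of the tested class is disease-causing; values
below 0 (protective) are permitted. Multiple testing uses Bonferroni
with m = the number of strata scanned in one cohort pair (16 for the
default panel: MYH7, MYBPC3, the MLC and thin-filament groups, and
four minor genes, each × truncating/nontruncating), with two-level
flags (Bonferroni / nominal).

## Carrier counting and yields

A sample counts at most once per stratum however many qualifying
variants it carries; group strata (MLC, thin filament) are unions of
their genes. Denominators use per-gene callable sample counts when the
manifest declares callability (a sample counts for a group stratum if
callable for at least one member gene), else full arm sizes. Two yield
notions are deliberately kept separate: *patient-level yield* (unique
genotype-positive patients / cohort) and the *summed stratum
frequency* (sum of per-gene carrier frequencies), which exceeds the
former whenever patients carry variants in several genes.

## Homozygosity and biallelic detection

Per-gene profiles partition carriers into the rare tier and the
*additional* low-frequency tier (carriers with no rare-tier variant in
that gene), mirroring the two-block layout of published homozygosity
tables; homozygous fractions are computed over the union. The
consanguinity association tests homozygous-carrier status (either
tier, dominant genes) against self-reported first-cousin
consanguinity; unknowns are excluded from the test but their rate is
reported, as is the share of homozygous carriers reporting
non-consanguineous parents (an underreporting indicator, reported over
the combined 32-carrier denominator).

Biallelic detection in recessive genes takes all protein-altering
variants within the biallelic FAF bound: a homozygote is called
`homozygous`; otherwise two or more distinct het variants yield one
`putative_compound_het` call. A sample with a homozygous call plus
extra hets yields exactly one call with mechanism homozygous
(dominant-mechanism precedence), listing every eligible variant
carried.

## Classification engine

Baseline ACMG/AMP evidence per variant is an *input* (a TSV of code,
polarity, strength): baseline annotation depends on external knowledge
bases and is not recomputed here. The engine owns combination and the
cohort-informed deltas:

* Standard 2015 combination rules on strength counts, so items applied
  at modified strengths count at the modified strength — PM1 upgraded
  to strong is a strong item, hence PM1_strong + PM2 → LP. One
  extension: a single strong benign item alone yields likely benign,
  the reading required for control-frequency reclassification to work
  with one evidence delta. Conflicting (both sides satisfied) → VUS.
* Regional EF rule: nontruncating variants whose residue falls in a
  cluster with EF ≥ 0.95 (computed from the cohort pair with the
  configured zero-cell correction) earn PM1 at strong. Variants
  without a protein residue cannot be placed and get nothing.
* Cohort-informed deltas: ≥ 2 matched-control carriers → strong benign
  evidence; ≥ 2 case carriers with 0 controls → moderate pathogenic
  evidence. Both thresholds are configurable; the defaults are the
  smallest counts consistent with the worked reclassifications they
  generalise.
* Patient level: each patient takes the maximum class among carried
  rare-tier variants (P > LP > VUS); carrying nothing is
  genotype-negative, a separate state, not a class. Actionable yield =
  fraction with a top class in {LP, P}, reported over the whole cohort
  and over the genotype-positive subset, under the baseline and
  extended regimes.

## Synthetic cohorts

`simulate_cohort` draws genotypes per individual under Hardy–Weinberg
with inbreeding — P(hom) = q² + Fq(1−q), P(het) = 2q(1−q)(1−F) — with
F = 1/16 (first-cousin offspring, pedigree theory) for consanguineous
individuals and 0 otherwise. Disease probability is the baseline risk
times a per-variant genotype relative-risk multiplier (hom defaulting
to het², capped at probability 1); cases and controls are
rejection-sampled to the requested sizes, so the control arm is an
essentially unbiased population sample under a rare-disease model.
Reported consanguinity is flipped to "no" at the underreporting rate
and blanked at a missing-data rate. Everything is reproducible from
the single spec seed.

Defaults are the study conditions the package targets: 514 cases / 400
controls, consanguinity 28.4%, baseline risk 0.002 (the canonical
1:500 HCM prevalence), underreporting 0.3 (motivated by the ~31% of
homozygous carriers reporting no consanguinity), missing family data
0.323. The default catalogue sketches the assumed structure — a
founder truncating variant at a few percent of cases, penetrant
major-gene missense inside the case-enriched region, minor-gene
variants weak in het and strong in hom, a recessive locus neutral in
het, and benign background. The generator does **not** emulate linkage
or phase, pedigree structure, sequencing error, population
stratification, or per-variant FAF mismatch beyond a fixed emitted
value — so passing calibration tests demonstrate statistical
correctness of the machinery under the stated model, not robustness to
those real-data features.

The deterministic Egypt-like fixture is *count-exact*, not
individual-exact: every published per-variant hom/het count, per-gene
tier total, the founder carriers (17/514), the TRIM63 biallelic calls
(8/374 callable), the consanguinity margins (99/249/166 with 14/10/8
homozygous carriers) and both yield notions (240 unique
genotype-positive = 46.7%; summed stratum frequency 52.7% via 31
two-gene carriers among 271 gene-slots) are realised exactly, while
filler carriers (`c.f<k>` variants) that pad per-gene totals are
synthetic. The fixture self-checks against its expected table on
construction.

## Numerical and design choices

* Fisher tests delegate to the standard scipy implementation; tests
  cross-check it against an independent hypergeometric enumeration.
* Deterministic ordering everywhere: variants sort by (gene, hgvs_c),
  scan rows follow panel declaration order, reruns with the same
  config and seed are byte-identical.
* Rounding happens only at render time (2 decimals for burden tables,
  1–2 for homozygosity tables); stored results keep full precision.
* Degenerate inputs fail loudly: empty arms, empty callable
  denominators, all-zero tables, zero-cell ORs with a zero correction
  constant, and cohorts with no genotype-positive patients all raise.
* Simulation sizes used by the test suite: 10⁶ draws for
  genotype-frequency recovery (4 Monte-Carlo SE tolerance), 200
  replicates of 2000/2000 for OR CI coverage (≥ 93%), 63 replicates ×
  16 strata (≥ 1000 p-values) for null calibration, checked for
  super-uniformity with a one-sided Kolmogorov–Smirnov test at
  α = 0.01 — exact one-sided p-values on discrete tables are
  conservative, so a two-sided uniformity test would reject by design.

## Known limitations

* Phase is never inferred; compound-het calls can be cis pairs.
* Baseline evidence quality is the caller's responsibility; the engine
  combines what it is given.
* The published per-variant evidence tables behind the source study's
  VUS-proportion and actionable-yield shifts are not redistributable,
  so those two end-to-end numbers are exercised structurally (the
  yield accounting and its monotonicity) rather than reproduced
  numerically.
* FAF values are taken as given; the package does not recompute
  filtering allele frequencies from allele counts, perform liftover,
  or query reference databases.
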