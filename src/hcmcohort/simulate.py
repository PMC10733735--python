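"""Synthetic consanguineous case-control cohort generator.

Individuals are drawn from a population in which each catalogue variant
segregates at allele frequency ``q`` under Hardy-Weinberg with
inbreeding:

    P(hom) = q^2 + F q (1 - q)
    P(het) = 2 q (1 - q) (1 - F)

where F is the inbreeding coefficient — 1/16 for offspring of
first-cousin marriages, the self-reported definition of consanguinity
used here.  Disease risk is multiplicative: an individual's disease
probability is the baseline risk times a genotype relative-risk
multiplier per variant (het or hom), capped at 1.  Cases and controls
are rejection-sampled to the requested sizes, and the self-reported
consanguinity label is flipped to "no" with a fixed underreporting rate
(and blanked to "unknown" with a missing-data rate), emulating
incomplete family histories.

Defaults mirror the study conditions this package analyses: 514 cases
vs 400 matched controls, 28.4% consanguinity among reporters, baseline
risk 0.002 (the canonical 1:500 disease prevalence), and a variant
catalogue with a founder truncating variant, weakly-penetrant minor-gene
variants that surface through homozygosity, a recessive locus, and
benign background variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    Consanguinity,
    Consequence,
    GenotypeRecord,
    Role,
    Sample,
    Variant,
    Zygosity,
)

REF, HET, HOM = 0, 1, 2


@dataclass(frozen=True)
class SimVariantSpec:
    """Generative counterpart of a catalogue variant.

    ``q`` is the true population allele frequency; ``faf_popmax`` is the
    reference-database frequency to *emit* on the variant record (kept
    separate because understudied populations are systematically
    underrepresented in reference databases).  Risk multipliers are
    genotype relative risks on the baseline disease probability.
    """

    gene: str
    consequence: Consequence
    q: float
    faf_popmax: Optional[float] = None
    risk_multiplier_het: float = 1.0
    risk_multiplier_hom: Optional[float] = None
    hgvs_c: Optional[str] = None
    cluster_residue: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 0.5:
            raise ValueError(f"allele frequency q must lie in (0, 0.5], got {self.q}")
        hom = self.hom_multiplier
        if not (hom >= self.risk_multiplier_het >= 0):
            raise ValueError("risk multipliers must satisfy hom >= het >= 0")

    @property
    def hom_multiplier(self) -> float:
        """Hom multiplier; defaults to het^2 (per-allele multiplicativity)."""
        if self.risk_multiplier_hom is not None:
            return self.risk_multiplier_hom
        return self.risk_multiplier_het**2


@dataclass(frozen=True)
class SimCohortSpec:
    n_cases: int = 514
    n_controls: int = 400
    variants: tuple[SimVariantSpec, ...] = ()
    consanguinity_rate: float = 0.284
    inbreeding_F: float = 1.0 / 16.0
    F_background: float = 0.0
    baseline_risk: float = 0.002
    consanguinity_underreport_rate: float = 0.3
    consanguinity_missing_rate: float = 0.323
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "consanguinity_rate",
            "inbreeding_F",
            "F_background",
            "baseline_risk",
            "consanguinity_underreport_rate",
            "consanguinity_missing_rate",
        ):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {x}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")


def sample_genotype(
    q: float, F: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw genotypes (0=ref, 1=het, 2=hom) under inbred Hardy-Weinberg."""
    p_hom = q * q + F * q * (1 - q)
    p_het = 2 * q * (1 - q) * (1 - F)
    u = rng.random(size)
    return np.where(u < p_hom, HOM, np.where(u < p_hom + p_het, HET, REF))


def _genotype_matrix(
    qs: np.ndarray, F: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n individuals x n variants) genotype draws with per-individual F."""
    q = qs[None, :]
    Fi = F[:, None]
    p_hom = q * q + Fi * q * (1 - q)
    p_het = 2 * q * (1 - q) * (1 - Fi)
    u = rng.random((F.shape[0], qs.shape[0]))
    return np.where(u < p_hom, HOM, np.where(u < p_hom + p_het, HET, REF))


@dataclass
class SimResult:
    cohort: Cohort
    variant_truth: pd.DataFrame
    sample_truth: pd.DataFrame
    spec: SimCohortSpec


def _make_variants(spec: SimCohortSpec) -> list[Variant]:
    variants: list[Variant] = []
    for i, vs in enumerate(spec.variants, start=1):
        hgvs_c = vs.hgvs_c or f"c.sim{i}"
        variants.append(
            Variant(
                variant_id=f"{vs.gene}:{hgvs_c}",
                gene=vs.gene,
                hgvs_c=hgvs_c,
                consequence=vs.consequence,
                protein_residue=vs.cluster_residue,
                faf_popmax=vs.faf_popmax,
            )
        )
    return variants


def simulate_cohort(spec: SimCohortSpec, max_draws: int = 20_000_000) -> SimResult:
    """Simulate a case-control cohort; fully reproducible from the seed.

    Raises if the spec cannot produce cases (zero disease probability)
    or if rejection sampling exhausts ``max_draws`` individuals.
    """
    if not spec.variants:
        raise ValueError("spec has no variants")
    max_mult = max(
        (max(vs.risk_multiplier_het, vs.hom_multiplier) for vs in spec.variants),
        default=1.0,
    )
    if spec.baseline_risk * max(max_mult, 1.0) == 0 and spec.n_cases > 0:
        raise ValueError("disease probability is identically 0; cannot draw cases")
    rng = np.random.default_rng(spec.seed)
    qs = np.array([vs.q for vs in spec.variants])
    log_het = np.log([max(vs.risk_multiplier_het, 1e-300) for vs in spec.variants])
    log_hom = np.log([max(vs.hom_multiplier, 1e-300) for vs in spec.variants])
    zero_het = np.array([vs.risk_multiplier_het == 0 for vs in spec.variants])
    zero_hom = np.array([vs.hom_multiplier == 0 for vs in spec.variants])

    case_G: list[np.ndarray] = []
    case_consang: list[np.ndarray] = []
    ctrl_G: list[np.ndarray] = []
    ctrl_consang: list[np.ndarray] = []
    n_case = n_ctrl = 0
    drawn = 0
    batch = 8192
    while n_case < spec.n_cases or n_ctrl < spec.n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"rejection sampling exhausted {max_draws} draws "
                f"({n_case}/{spec.n_cases} cases so far); spec infeasible?"
            )
        consang = rng.random(batch) < spec.consanguinity_rate
        F = np.where(consang, spec.inbreeding_F, spec.F_background)
        G = _genotype_matrix(qs, F, rng)
        log_risk = (G == HET) @ log_het + (G == HOM) @ log_hom
        risk = np.minimum(spec.baseline_risk * np.exp(log_risk), 1.0)
        risk[((G == HET) & zero_het[None, :]).any(axis=1)] = 0.0
        risk[((G == HOM) & zero_hom[None, :]).any(axis=1)] = 0.0
        diseased = rng.random(batch) < risk
        drawn += batch
        take_case = np.nonzero(diseased)[0][: spec.n_cases - n_case]
        take_ctrl = np.nonzero(~diseased)[0][: spec.n_controls - n_ctrl]
        case_G.append(G[take_case])
        case_consang.append(consang[take_case])
        ctrl_G.append(G[take_ctrl])
        ctrl_consang.append(consang[take_ctrl])
        n_case += len(take_case)
        n_ctrl += len(take_ctrl)

    variants = _make_variants(spec)
    samples: list[Sample] = []
    genotypes: list[GenotypeRecord] = []
    truth_rows: list[dict] = []
    for role, G_arr, consang_arr, prefix in (
        (Role.CASE, np.concatenate(case_G), np.concatenate(case_consang), "SIM-CASE"),
        (Role.CONTROL, np.concatenate(ctrl_G), np.concatenate(ctrl_consang), "SIM-CTRL"),
    ):
        n = G_arr.shape[0]
        underreport = rng.random(n) < spec.consanguinity_underreport_rate
        missing = rng.random(n) < spec.consanguinity_missing_rate
        for i in range(n):
            sid = f"{prefix}-{i + 1:05d}"
            if consang_arr[i] and not underreport[i]:
                reported = Consanguinity.YES
            else:
                reported = Consanguinity.NO
            if missing[i]:
                reported = Consanguinity.UNKNOWN
            samples.append(Sample(sample_id=sid, role=role, consanguinity=reported))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "role": role.value,
                    "true_consanguinity": bool(consang_arr[i]),
                    "true_F": spec.inbreeding_F
                    if consang_arr[i]
                    else spec.F_background,
                    "reported_consanguinity": reported.value,
                }
            )
        for i, j in np.argwhere(G_arr != REF):
            genotypes.append(
                GenotypeRecord(
                    sample_id=f"{prefix}-{i + 1:05d}",
                    variant_id=variants[j].variant_id,
                    zygosity=Zygosity.HOM if G_arr[i, j] == HOM else Zygosity.HET,
                )
            )
    variant_truth = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "q": qs,
            "risk_multiplier_het": [vs.risk_multiplier_het for vs in spec.variants],
            "risk_multiplier_hom": [vs.hom_multiplier for vs in spec.variants],
        }
    )
    cohort = Cohort.build(samples, genotypes, variants, name=f"sim-seed{spec.seed}")
    return SimResult(
        cohort=cohort,
        variant_truth=variant_truth,
        sample_truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def default_spec(seed: int = 0) -> SimCohortSpec:
    """Study-condition default spec.

    The catalogue sketches the structure the analyses assume: a founder
    truncating variant carried by a few percent of cases, penetrant
    major-gene missense variation, minor-gene variants that are weakly
    penetrant in heterozygosity but strongly penetrant in homozygosity,
    a recessive locus, and benign background variation that appears in
    controls.
    """
    mk = SimVariantSpec
    variants = (
        # founder frameshift, absent from reference populations
        mk("MYH7", Consequence.FRAMESHIFT, q=6e-4, faf_popmax=None,
           risk_multiplier_het=40, risk_multiplier_hom=400, hgvs_c="c.founder1del"),
        # penetrant major-gene missense, inside the case-enriched region
        mk("MYH7", Consequence.MISSENSE, q=5e-4, faf_popmax=3e-6,
           risk_multiplier_het=30, cluster_residue=500, hgvs_c="c.1500G>A"),
        mk("MYH7", Consequence.MISSENSE, q=4e-4, faf_popmax=1e-5,
           risk_multiplier_het=25, cluster_residue=700, hgvs_c="c.2100C>T"),
        mk("MYBPC3", Consequence.NONSENSE, q=6e-4, faf_popmax=None,
           risk_multiplier_het=30, hgvs_c="c.1558G>T"),
        mk("MYBPC3", Consequence.MISSENSE, q=6e-4, faf_popmax=2e-5,
           risk_multiplier_het=12, hgvs_c="c.2908C>T"),
        # minor-gene variants: weak in het, strong in hom
        mk("MYL2", Consequence.MISSENSE, q=1.2e-3, faf_popmax=1e-5,
           risk_multiplier_het=3, risk_multiplier_hom=300, hgvs_c="c.278C>T"),
        mk("MYL3", Consequence.MISSENSE, q=1.5e-3, faf_popmax=4.4e-5,
           risk_multiplier_het=3, risk_multiplier_hom=300, hgvs_c="c.530A>G"),
        mk("CSRP3", Consequence.SPLICE_DONOR, q=8e-4, faf_popmax=None,
           risk_multiplier_het=4, risk_multiplier_hom=250, hgvs_c="c.414+1G>T"),
        mk("TNNT2", Consequence.MISSENSE, q=5e-4, faf_popmax=1e-5,
           risk_multiplier_het=15, hgvs_c="c.832C>T"),
        # recessive locus: neutral in het, causal in hom
        mk("TRIM63", Consequence.MISSENSE, q=4e-3, faf_popmax=2e-4,
           risk_multiplier_het=1, risk_multiplier_hom=120, hgvs_c="c.224G>A"),
        # benign background variation (appears equally in both arms)
        mk("MYBPC3", Consequence.MISSENSE, q=2e-3, faf_popmax=2e-4,
           risk_multiplier_het=1, hgvs_c="c.1321G>A"),
        mk("JPH2", Consequence.MISSENSE, q=1.5e-3, faf_popmax=2e-4,
           risk_multiplier_het=1, hgvs_c="c.572C>G"),
        mk("ACTN2", Consequence.MISSENSE, q=1e-3, faf_popmax=1e-5,
           risk_multiplier_het=1, hgvs_c="c.100A>G"),
    )
    return SimCohortSpec(variants=variants, seed=seed)


def null_spec(
    n_cases: int = 250,
    n_controls: int = 250,
    seed: int = 0,
    q: float = 4e-3,
) -> SimCohortSpec:
    """All-multipliers-1 spec: no enrichment anywhere (null calibration)."""
    genes = [
        "MYH7", "MYBPC3", "MYL2", "MYL3", "ACTC1", "TNNC1", "TNNI3",
        "TNNT2", "TPM1", "PLN", "ACTN2", "CSRP3", "JPH2",
    ]
    variants = []
    for i, gene in enumerate(genes):
        variants.append(
            SimVariantSpec(
                gene=gene, consequence=Consequence.MISSENSE, q=q,
                faf_popmax=1e-5, hgvs_c=f"c.null{i}m",
            )
        )
        variants.append(
            SimVariantSpec(
                gene=gene, consequence=Consequence.NONSENSE, q=q,
                faf_popmax=1e-5, hgvs_c=f"c.null{i}t",
            )
        )
    return SimCohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        variants=tuple(variants),
        baseline_risk=0.01,
        seed=seed,
    )
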