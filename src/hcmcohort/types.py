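"""Domain types for cohort-level rare-variant analysis.

The objects here model a sequenced case-control cohort the way a clinical
genetics panel study sees it: a catalogue of distinct variants (gene, HGVS
description, consequence class, gnomAD-style popmax filtering allele
frequency), a genotype table linking samples to variants with zygosity, and
a sample manifest carrying case/control role, self-reported consanguinity
and optional per-gene callability.  All downstream modules (burden,
zygosity, classification) operate on these containers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional


class Consequence(str, enum.Enum):
    """Protein-level consequence class of a variant (closed vocabulary)."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class Role(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Consanguinity(str, enum.Enum):
    """Self-reported first-cousin parental consanguinity."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class GeneGroup(str, enum.Enum):
    """Functional gene groups used as burden strata.

    ``major`` genes (MYH7, MYBPC3) account for the large majority of
    pathogenic variants and are scanned individually; the myosin light
    chain and thin-filament genes are pooled because individual variant
    counts are small; ``recessive`` genes (TRIM63) are analysed only for
    biallelic genotypes and excluded from dominant-model scans.
    """

    MAJOR = "major"
    MLC = "MLC"
    THIN_FILAMENT = "thin_filament"
    MINOR_NONSARCOMERIC = "minor_nonsarcomeric"
    RECESSIVE = "recessive"


class IntegrityError(ValueError):
    """A table or cohort violated a structural invariant."""


@dataclass(frozen=True)
class Variant:
    """One catalogued alternate allele.

    ``faf_popmax`` is the highest filtering allele frequency across the
    main gnomAD subpopulations; ``None`` means the variant is absent from
    the reference population.  For rarity-tier filtering an absent variant
    is treated as frequency 0, but the distinction is preserved here for
    reporting (see :func:`hcmcohort.taxonomy.assign_tier`).
    """

    variant_id: str
    gene: str
    hgvs_c: str
    consequence: Consequence
    hgvs_p: Optional[str] = None
    protein_residue: Optional[int] = None
    faf_popmax: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise IntegrityError("variant_id must be non-empty")
        if not self.gene:
            raise IntegrityError("gene must be non-empty")
        self.__dict__["consequence"] = Consequence(self.consequence)
        if self.protein_residue is not None and self.protein_residue < 1:
            raise IntegrityError(
                f"protein_residue must be >= 1, got {self.protein_residue}"
            )
        if self.faf_popmax is not None:
            if math.isnan(self.faf_popmax) or not 0.0 <= self.faf_popmax <= 1.0:
                raise IntegrityError(
                    f"faf_popmax must lie in [0, 1], got {self.faf_popmax}"
                )

    @property
    def faf_for_filtering(self) -> float:
        """FAF used in tier filtering: absent-from-reference counts as 0."""
        return 0.0 if self.faf_popmax is None else self.faf_popmax

    @property
    def absent_from_reference(self) -> bool:
        return self.faf_popmax is None


@dataclass(frozen=True)
class GenotypeRecord:
    sample_id: str
    variant_id: str
    zygosity: Zygosity

    def __post_init__(self) -> None:
        self.__dict__["zygosity"] = Zygosity(self.zygosity)


@dataclass(frozen=True)
class Sample:
    """One study participant.

    ``callable_genes``, when given, restricts the genes this sample was
    sequenced/callable for; per-gene denominators then count only callable
    samples (e.g. a recessive gene present on only a subset of panel
    versions).  ``None`` means callable for every panel gene.
    """

    sample_id: str
    role: Role
    consanguinity: Consanguinity = Consanguinity.UNKNOWN
    callable_genes: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        self.__dict__["role"] = Role(self.role)
        self.__dict__["consanguinity"] = Consanguinity(self.consanguinity)
        if self.callable_genes is not None:
            if len(self.callable_genes) == 0:
                raise IntegrityError(
                    f"sample {self.sample_id}: callable_genes present but empty"
                )
            self.__dict__["callable_genes"] = frozenset(self.callable_genes)

    def is_callable_for(self, gene: str) -> bool:
        return self.callable_genes is None or gene in self.callable_genes


@dataclass
class Cohort:
    """Sample manifest + genotype records + variant catalogue.

    Referential integrity (every genotype points at an existing sample and
    variant; no duplicate genotype per (sample, variant); unique
    (gene, hgvs_c) in the catalogue) is enforced by :meth:`validate`,
    which is called on construction.
    """

    samples: dict[str, Sample]
    genotypes: list[GenotypeRecord]
    catalogue: dict[str, Variant]
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def build(
        cls,
        samples: Iterable[Sample],
        genotypes: Iterable[GenotypeRecord],
        catalogue: Iterable[Variant],
        name: str = "cohort",
    ) -> "Cohort":
        sample_map: dict[str, Sample] = {}
        for s in samples:
            if s.sample_id in sample_map:
                raise IntegrityError(f"duplicate sample_id {s.sample_id!r}")
            sample_map[s.sample_id] = s
        var_map: dict[str, Variant] = {}
        for v in catalogue:
            if v.variant_id in var_map:
                raise IntegrityError(f"duplicate variant_id {v.variant_id!r}")
            var_map[v.variant_id] = v
        return cls(sample_map, list(genotypes), var_map, name=name)

    def validate(self) -> None:
        seen_cdna: dict[tuple[str, str], str] = {}
        for v in self.catalogue.values():
            key = (v.gene, v.hgvs_c)
            if key in seen_cdna:
                raise IntegrityError(
                    f"duplicate (gene, hgvs_c) {key} in catalogue "
                    f"(variant ids {seen_cdna[key]!r}, {v.variant_id!r})"
                )
            seen_cdna[key] = v.variant_id
        missing_samples = sorted(
            {g.sample_id for g in self.genotypes} - set(self.samples)
        )
        if missing_samples:
            raise IntegrityError(
                f"genotypes reference unknown samples: {missing_samples}"
            )
        missing_variants = sorted(
            {g.variant_id for g in self.genotypes} - set(self.catalogue)
        )
        if missing_variants:
            raise IntegrityError(
                f"genotypes reference unknown variants: {missing_variants}"
            )
        seen_pairs: set[tuple[str, str]] = set()
        for g in self.genotypes:
            pair = (g.sample_id, g.variant_id)
            if pair in seen_pairs:
                raise IntegrityError(
                    f"duplicate genotype record for sample {g.sample_id!r} "
                    f"variant {g.variant_id!r}"
                )
            seen_pairs.add(pair)

    # -- convenience views -------------------------------------------------

    def samples_by_role(self, role: Role) -> list[Sample]:
        role = Role(role)
        return [s for s in self.samples.values() if s.role == role]

    @property
    def n_cases(self) -> int:
        return len(self.samples_by_role(Role.CASE))

    @property
    def n_controls(self) -> int:
        return len(self.samples_by_role(Role.CONTROL))

    def genotypes_of(self, sample_id: str) -> list[GenotypeRecord]:
        return [g for g in self.genotypes if g.sample_id == sample_id]

    def genotype_index(self) -> dict[str, list[GenotypeRecord]]:
        """Genotypes grouped by sample id (one pass; use for hot loops)."""
        index: dict[str, list[GenotypeRecord]] = {s: [] for s in self.samples}
        for g in self.genotypes:
            index[g.sample_id].append(g)
        return index

    def callable_count(self, gene: str, role: Role) -> int:
        return sum(
            1 for s in self.samples_by_role(role) if s.is_callable_for(gene)
        )


# -- panel and configuration ----------------------------------------------

#: The validated autosomal-dominant HCM panel plus the recessive gene.
DEFAULT_PANEL_GENES: dict[str, GeneGroup] = {
    "MYH7": GeneGroup.MAJOR,
    "MYBPC3": GeneGroup.MAJOR,
    "MYL2": GeneGroup.MLC,
    "MYL3": GeneGroup.MLC,
    "ACTC1": GeneGroup.THIN_FILAMENT,
    "TNNC1": GeneGroup.THIN_FILAMENT,
    "TNNI3": GeneGroup.THIN_FILAMENT,
    "TNNT2": GeneGroup.THIN_FILAMENT,
    "TPM1": GeneGroup.THIN_FILAMENT,
    "PLN": GeneGroup.MINOR_NONSARCOMERIC,
    "ACTN2": GeneGroup.MINOR_NONSARCOMERIC,
    "CSRP3": GeneGroup.MINOR_NONSARCOMERIC,
    "JPH2": GeneGroup.MINOR_NONSARCOMERIC,
    "TRIM63": GeneGroup.RECESSIVE,
}


@dataclass(frozen=True)
class RegionCluster:
    """A protein region with an attached etiological fraction.

    Nontruncating variants falling inside a region whose EF reaches the
    configured threshold earn region-based pathogenic evidence (PM1) at
    strong strength.  ``ef`` may be unset until computed from a cohort
    pair by :func:`hcmcohort.classify.cluster_ef`.
    """

    gene: str
    residue_start: int
    residue_end: int
    ef: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residue_start < 1 or self.residue_end < self.residue_start:
            raise IntegrityError(
                f"invalid residue bounds [{self.residue_start}, {self.residue_end}]"
            )
        if self.ef is not None and not 0.0 <= self.ef < 1.0:
            raise IntegrityError(f"cluster ef must lie in [0, 1), got {self.ef}")

    def contains(self, residue: int) -> bool:
        return self.residue_start <= residue <= self.residue_end

    def with_ef(self, ef: float) -> "RegionCluster":
        return replace(self, ef=ef)


#: Patient-enriched MYH7 missense region (head/neck + proximal rod).
MYH7_CLUSTER = RegionCluster(gene="MYH7", residue_start=167, residue_end=931)


@dataclass(frozen=True)
class GenePanel:
    genes: Mapping[str, GeneGroup] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_GENES)
    )
    clusters: tuple[RegionCluster, ...] = (MYH7_CLUSTER,)

    def __post_init__(self) -> None:
        self.__dict__["genes"] = {
            g: GeneGroup(grp) for g, grp in self.genes.items()
        }

    def group_of(self, gene: str) -> GeneGroup:
        try:
            return self.genes[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not in the panel") from None

    def genes_in_group(self, group: GeneGroup) -> list[str]:
        group = GeneGroup(group)
        return sorted(g for g, grp in self.genes.items() if grp == group)

    @property
    def dominant_genes(self) -> list[str]:
        """Panel genes analysed under the dominant (monoallelic) model."""
        return sorted(
            g for g, grp in self.genes.items() if grp != GeneGroup.RECESSIVE
        )

    def resolve_stratum(self, label: str) -> list[str]:
        """Map a stratum label (gene symbol or group name) to gene symbols."""
        if label in self.genes:
            return [label]
        try:
            group = GeneGroup(label)
        except ValueError:
            raise KeyError(
                f"stratum {label!r} is neither a panel gene nor a gene group"
            ) from None
        members = self.genes_in_group(group)
        if not members:
            raise KeyError(f"gene group {label!r} has no panel genes")
        return members


class Sidedness(str, enum.Enum):
    ONE_SIDED_GREATER = "one_sided_greater"
    TWO_SIDED = "two_sided"


@dataclass
class AnalysisConfig:
    """Thresholds and statistical conventions for a full analysis run.

    faf_monoallelic
        Rarity bound for variants compatible with dominant (monoallelic)
        disease; default 4e-5.
    faf_biallelic
        Looser bound for variants still rare enough to cause biallelic
        disease; default 1.26e-3.
    ef_strong_threshold
        Minimum regional etiological fraction to emit region evidence at
        strong strength; default 0.95.
    zero_cell_constant
        Haldane-Anscombe constant added to every cell of a 2x2 table with
        a zero cell before odds-ratio estimation; default 0.5.
    sidedness
        Per-analysis Fisher-test sidedness.  Burden scans and the
        consanguinity association are one-sided for case enrichment;
        cross-cohort comparisons are two-sided.
    """

    faf_monoallelic: float = 4e-5
    faf_biallelic: float = 1.26e-3
    ef_strong_threshold: float = 0.95
    zero_cell_constant: float = 0.5
    alpha: float = 0.05
    n_tests_bonferroni: Optional[int] = None
    sidedness: dict[str, Sidedness] = field(
        default_factory=lambda: {
            "burden_scan": Sidedness.ONE_SIDED_GREATER,
            "consanguinity": Sidedness.ONE_SIDED_GREATER,
            "cohort_comparison": Sidedness.TWO_SIDED,
        }
    )
    control_benign_threshold: int = 2
    case_recurrence_threshold: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.faf_monoallelic < self.faf_biallelic:
            raise IntegrityError(
                "faf thresholds must satisfy 0 < monoallelic < biallelic"
            )
        if not 0.0 < self.ef_strong_threshold < 1.0:
            raise IntegrityError("ef_strong_threshold must lie in (0, 1)")
        if self.zero_cell_constant < 0:
            raise IntegrityError("zero_cell_constant must be >= 0")
        self.sidedness = {
            k: Sidedness(v) for k, v in self.sidedness.items()
        }

    def sidedness_for(self, analysis: str) -> Sidedness:
        return self.sidedness.get(analysis, Sidedness.TWO_SIDED)
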