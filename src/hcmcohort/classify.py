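"""ACMG/AMP evidence combination with cohort-informed extensions.

Variants enter with a baseline set of ACMG/AMP evidence items (code,
polarity, strength) produced by external annotation; this module owns
the *combination* step and three quantitative extensions that exploit an
ancestry-matched case-control cohort:

* a regional etiological-fraction rule — nontruncating variants inside a
  protein region whose case-control EF reaches 0.95 earn region-based
  pathogenic evidence (PM1) at **strong** strength;
* cohort-informed evidence deltas — recurrence in cases with absence
  from matched controls adds pathogenic evidence at moderate strength,
  while presence in multiple matched controls adds benign evidence at
  strong strength;
* patient-level prioritisation — each patient takes the most pathogenic
  class among their carried variants, and the *actionable yield* is the
  fraction of patients whose top class is likely-pathogenic or
  pathogenic.

A PM1 item upgraded to strong counts as a strong item in the
combination table, so PM1_strong + PM2 combine to likely pathogenic.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .stats import ContingencyTable, fisher_exact, odds_ratio_ci
from .taxonomy import RarityTier, VariantClass, eligible_variant_ids, variant_class
from .types import (
    AnalysisConfig,
    Cohort,
    GenePanel,
    RegionCluster,
    Role,
    Sidedness,
    Variant,
)


class Polarity(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"


class AcmgClass(enum.IntEnum):
    """Five-tier classification, ordered by pathogenicity."""

    BENIGN = 0
    LIKELY_BENIGN = 1
    VUS = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    @property
    def label(self) -> str:
        return {
            AcmgClass.BENIGN: "B",
            AcmgClass.LIKELY_BENIGN: "LB",
            AcmgClass.VUS: "VUS",
            AcmgClass.LIKELY_PATHOGENIC: "LP",
            AcmgClass.PATHOGENIC: "P",
        }[self]

    @property
    def actionable(self) -> bool:
        return self >= AcmgClass.LIKELY_PATHOGENIC


@dataclass(frozen=True)
class EvidenceItem:
    code: str
    polarity: Polarity
    strength: Strength

    def __post_init__(self) -> None:
        self.__dict__["polarity"] = Polarity(self.polarity)
        self.__dict__["strength"] = Strength(self.strength)
        if (
            self.strength == Strength.STAND_ALONE
            and self.polarity != Polarity.BENIGN
        ):
            raise ValueError("stand_alone strength is benign-only (BA1-style)")


class EvidenceSet:
    """A multiset of evidence items with unique codes."""

    def __init__(self, items: Iterable[EvidenceItem] = ()) -> None:
        self._items: dict[str, EvidenceItem] = {}
        for item in items:
            self.add(item)

    def add(self, item: EvidenceItem) -> None:
        if item.code in self._items:
            raise ValueError(f"duplicate evidence code {item.code!r}")
        self._items[item.code] = item

    def with_items(self, items: Iterable[EvidenceItem]) -> "EvidenceSet":
        new = EvidenceSet(self._items.values())
        for item in items:
            if item.code not in new._items:
                new.add(item)
        return new

    def __iter__(self):
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, code: str) -> bool:
        return code in self._items

    def codes(self) -> list[str]:
        return sorted(self._items)


@dataclass(frozen=True)
class Classification:
    klass: AcmgClass
    evidence: EvidenceSet
    provenance: tuple[str, ...] = ()


def _strength_counts(evidence: Iterable[EvidenceItem]) -> tuple[Counter, Counter]:
    path: Counter = Counter()
    ben: Counter = Counter()
    for item in evidence:
        (path if item.polarity == Polarity.PATHOGENIC else ben)[item.strength] += 1
    return path, ben


def _pathogenic_tier(path: Counter) -> Optional[AcmgClass]:
    pvs = path[Strength.VERY_STRONG]
    ps = path[Strength.STRONG]
    pm = path[Strength.MODERATE]
    pp = path[Strength.SUPPORTING]
    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    if pathogenic:
        return AcmgClass.PATHOGENIC
    likely = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    if likely:
        return AcmgClass.LIKELY_PATHOGENIC
    return None


def _benign_tier(ben: Counter) -> Optional[AcmgClass]:
    if ben[Strength.STAND_ALONE] >= 1 or ben[Strength.STRONG] >= 2:
        return AcmgClass.BENIGN
    # A single strong benign item suffices for likely benign (the
    # practice followed by cohort-frequency reclassification workflows).
    if ben[Strength.STRONG] == 1 or ben[Strength.SUPPORTING] >= 2:
        return AcmgClass.LIKELY_BENIGN
    return None


def combine_evidence(evidence: EvidenceSet | Iterable[EvidenceItem]) -> Classification:
    """Combine evidence items into a five-tier class.

    The standard combining rules are applied on strength counts (so
    items applied at modified strengths count at their modified
    strength).  If both a pathogenic-side and a benign-side combination
    are satisfied the evidence is conflicting and the result is VUS;
    insufficient evidence is likewise VUS.
    """
    ev = evidence if isinstance(evidence, EvidenceSet) else EvidenceSet(evidence)
    path, ben = _strength_counts(ev)
    p_tier = _pathogenic_tier(path)
    b_tier = _benign_tier(ben)
    provenance: list[str] = []
    if p_tier is not None and b_tier is not None:
        klass = AcmgClass.VUS
        provenance.append("conflicting_evidence")
    elif p_tier is not None:
        klass = p_tier
    elif b_tier is not None:
        klass = b_tier
    else:
        klass = AcmgClass.VUS
    return Classification(klass=klass, evidence=ev, provenance=tuple(provenance))


# -- regional EF rule ------------------------------------------------------


def cluster_ef(
    cohort: Cohort,
    cluster: RegionCluster,
    cfg: Optional[AnalysisConfig] = None,
) -> RegionCluster:
    """Fill a region cluster's etiological fraction from the cohort.

    Carriers are counted among rare (monoallelic-tier) nontruncating
    variants of the cluster gene whose affected residue falls inside the
    cluster bounds; the odds ratio uses the matched control arm as the
    reference population, with zero-cell correction as configured.
    """
    cfg = cfg or AnalysisConfig()
    in_cluster = {
        v.variant_id
        for v in cohort.catalogue.values()
        if v.gene == cluster.gene
        and variant_class(v) == VariantClass.NONTRUNCATING
        and v.protein_residue is not None
        and cluster.contains(v.protein_residue)
        and v.faf_for_filtering <= cfg.faf_monoallelic
    }
    carriers = {g.sample_id for g in cohort.genotypes if g.variant_id in in_cluster}
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    a = len(carriers & case_ids)
    c = len(carriers - case_ids)
    if a == 0 and c == 0:
        raise ValueError(
            f"no carriers of cluster {cluster.gene}:"
            f"{cluster.residue_start}-{cluster.residue_end} in either arm"
        )
    table = ContingencyTable(
        a=a, b=cohort.n_cases - a, c=c, d=cohort.n_controls - c
    )
    assoc = odds_ratio_ci(
        table,
        cfg.zero_cell_constant,
        sidedness=Sidedness.ONE_SIDED_GREATER,
        p_value=fisher_exact(table, Sidedness.ONE_SIDED_GREATER),
    )
    return cluster.with_ef(assoc.ef)


def apply_ef_rule(
    v: Variant,
    clusters: Sequence[RegionCluster],
    cfg: Optional[AnalysisConfig] = None,
) -> Optional[EvidenceItem]:
    """Region-based pathogenic evidence at strong strength, or None.

    Emitted only for nontruncating variants whose residue lies inside a
    cluster of the same gene with EF at or above the configured
    threshold.  Nontruncating variants lacking a protein residue cannot
    be placed and yield nothing.
    """
    cfg = cfg or AnalysisConfig()
    if variant_class(v) != VariantClass.NONTRUNCATING:
        return None
    if v.protein_residue is None:
        return None
    for cluster in clusters:
        if cluster.gene != v.gene or cluster.ef is None:
            continue
        if cluster.ef >= cfg.ef_strong_threshold and cluster.contains(v.protein_residue):
            return EvidenceItem("PM1", Polarity.PATHOGENIC, Strength.STRONG)
    return None


def cohort_informed_update(
    v: Variant,
    case_carriers: int,
    control_carriers: int,
    cfg: Optional[AnalysisConfig] = None,
) -> list[EvidenceItem]:
    """Evidence deltas from ancestry-matched carrier counts.

    Presence in multiple matched controls adds benign evidence at strong
    strength (BS-class); recurrence in cases with absence from controls
    adds pathogenic evidence at moderate strength (PS4-class applied at
    moderate).  Thresholds are configurable.
    """
    cfg = cfg or AnalysisConfig()
    deltas: list[EvidenceItem] = []
    if control_carriers >= cfg.control_benign_threshold:
        deltas.append(EvidenceItem("BS_cohort", Polarity.BENIGN, Strength.STRONG))
    if case_carriers >= cfg.case_recurrence_threshold and control_carriers == 0:
        deltas.append(EvidenceItem("PS4_moderate", Polarity.PATHOGENIC, Strength.MODERATE))
    return deltas


# -- patient-level prioritisation -----------------------------------------


def classify_patient(
    classifications: Iterable[Classification | AcmgClass],
) -> Optional[AcmgClass]:
    """Most pathogenic class among a patient's variants; None if none."""
    classes = [
        c.klass if isinstance(c, Classification) else AcmgClass(c)
        for c in classifications
    ]
    return max(classes) if classes else None


@dataclass(frozen=True)
class YieldReport:
    """Actionable-yield accounting under two evidence regimes."""

    n_cases: int
    n_genotype_positive: int
    actionable_before: int
    actionable_after: int

    @property
    def yield_before(self) -> float:
        return self.actionable_before / self.n_cases

    @property
    def yield_after(self) -> float:
        return self.actionable_after / self.n_cases

    @property
    def yield_before_gpos(self) -> float:
        return self.actionable_before / self.n_genotype_positive

    @property
    def yield_after_gpos(self) -> float:
        return self.actionable_after / self.n_genotype_positive


def patient_classes(
    cohort: Cohort,
    variant_classes: Mapping[str, AcmgClass],
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> dict[str, Optional[AcmgClass]]:
    """Patient-level class per case, from per-variant classifications.

    Only rare (monoallelic-tier) variants in dominant panel genes count
    toward a patient's genotype; unclassified carried variants default
    to VUS.
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    eligible = eligible_variant_ids(
        cohort, panel.dominant_genes, (RarityTier.RARE_MONOALLELIC,), cfg=cfg
    )
    index = cohort.genotype_index()
    out: dict[str, Optional[AcmgClass]] = {}
    for s in cohort.samples_by_role(Role.CASE):
        carried = [g.variant_id for g in index[s.sample_id] if g.variant_id in eligible]
        out[s.sample_id] = classify_patient(
            variant_classes.get(vid, AcmgClass.VUS) for vid in carried
        )
    return out


def actionable_yield(
    cohort: Cohort,
    classes_before: Mapping[str, AcmgClass],
    classes_after: Mapping[str, AcmgClass],
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> YieldReport:
    """Fraction of patients with an actionable (LP/P) top variant,
    before and after reclassification."""
    before = patient_classes(cohort, classes_before, panel, cfg)
    after = patient_classes(cohort, classes_after, panel, cfg)
    gpos = [sid for sid, k in before.items() if k is not None]
    if not gpos:
        raise ValueError("no genotype-positive patients to account")
    return YieldReport(
        n_cases=cohort.n_cases,
        n_genotype_positive=len(gpos),
        actionable_before=sum(
            1 for k in before.values() if k is not None and k.actionable
        ),
        actionable_after=sum(
            1 for k in after.values() if k is not None and k.actionable
        ),
    )


# -- evidence table I/O ----------------------------------------------------


def load_evidence_table(path) -> dict[str, EvidenceSet]:
    """Read a baseline-evidence TSV (variant_id, code, polarity, strength)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, EvidenceSet] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.variant_id, EvidenceSet()).add(
            EvidenceItem(row.code, Polarity(row.polarity), Strength(row.strength))
        )
    return out


def reclassify_catalogue(
    cohort: Cohort,
    baseline_evidence: Mapping[str, EvidenceSet],
    panel: Optional[GenePanel] = None,
    cfg: Optional[AnalysisConfig] = None,
    clusters: Optional[Sequence[RegionCluster]] = None,
) -> dict[str, tuple[Classification, Classification]]:
    """(before, after) classifications for every catalogued variant.

    *after* adds the regional-EF evidence and the cohort-informed deltas
    to the baseline evidence before recombination.  Clusters without an
    EF are computed from the cohort first.
    """
    panel = panel or GenePanel()
    cfg = cfg or AnalysisConfig()
    if clusters is None:
        clusters = panel.clusters
    filled: list[RegionCluster] = []
    for cl in clusters:
        filled.append(cl if cl.ef is not None else cluster_ef(cohort, cl, cfg))
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    carriers_by_variant: dict[str, set[str]] = {}
    for g in cohort.genotypes:
        carriers_by_variant.setdefault(g.variant_id, set()).add(g.sample_id)
    out: dict[str, tuple[Classification, Classification]] = {}
    for vid, v in cohort.catalogue.items():
        base = baseline_evidence.get(vid, EvidenceSet())
        before = combine_evidence(base)
        deltas: list[EvidenceItem] = []
        prov: list[str] = []
        ef_item = apply_ef_rule(v, filled, cfg)
        if ef_item is not None and ef_item.code not in base:
            deltas.append(ef_item)
            prov.append("ef_region_rule")
        carriers = carriers_by_variant.get(vid, set())
        n_case = len(carriers & case_ids)
        n_ctrl = len(carriers - case_ids)
        for item in cohort_informed_update(v, n_case, n_ctrl, cfg):
            if item.code not in base:
                deltas.append(item)
                prov.append(f"cohort_informed:{item.code}")
        after = combine_evidence(base.with_items(deltas))
        after = Classification(
            klass=after.klass,
            evidence=after.evidence,
            provenance=after.provenance + tuple(prov),
        )
        out[vid] = (before, after)
    return out
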