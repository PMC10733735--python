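"""Deterministic Egypt-like cohort fixture and published reference tables.

``egypt_like_fixture`` materialises a 514-case / 400-control cohort that
is *count-exact* with respect to the published cohort summaries this
package is designed to reproduce: every per-variant case/control
hom/het count of the homozygosity table, the per-gene carrier totals
under both rarity tiers, the founder-variant carriers, the recessive
TRIM63 biallelic genotypes (with its reduced callable denominator), the
consanguinity margins, and both genotype-yield notions.  Individual
patient assignments beyond those counts are unknowable from published
summaries, so filler carriers are synthetic: they are labelled
``c.f<k>`` and exist purely to pad per-gene carrier totals.

``load_published_excess`` ships the published per-stratum excess-burden
columns for the two cohorts (printed summary values, used for
cross-table consistency checks), since no per-variant table exists for
the comparison cohort.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

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

_MS = Consequence.MISSENSE
_NS = Consequence.NONSENSE
_FS = Consequence.FRAMESHIFT
_SD = Consequence.SPLICE_DONOR
_SA = Consequence.SPLICE_ACCEPTOR
_IF = Consequence.INFRAME_INDEL

# Named variants: (gene, hgvs_c, hgvs_p, consequence, residue, faf,
#                  case_hom, case_het, ctrl_hom, ctrl_het)
# FAF None = absent from the reference population (printed as 0).
_RARE_VARIANTS = [
    ("MYH7", "c.5122G>A", "p.Glu1708Lys", _MS, 1708, None, 1, 0, 0, 0),
    ("MYH7", "c.4258C>T", "p.Arg1420Trp", _MS, 1420, 3.0e-6, 1, 2, 0, 0),
    ("MYH7", "c.3622G>C", "p.Asp1208His", _MS, 1208, None, 1, 3, 0, 0),
    ("MYH7", "c.1064C>T", "p.Ala355Val", _MS, 355, None, 1, 0, 0, 0),
    ("MYH7", "c.925G>A", "p.Asp309Asn", _MS, 309, 1.1e-5, 1, 4, 0, 0),
    ("MYH7", "c.5769delG", "p.Ser1924AlafsTer9", _FS, 1924, None, 1, 16, 0, 0),
    ("MYBPC3", "c.2908C>T", "p.Arg970Trp", _MS, 970, None, 1, 2, 0, 1),
    ("MYBPC3", "c.2458C>G", "p.Arg820Gly", _MS, 820, None, 1, 0, 0, 0),
    ("MYBPC3", "c.2441_2443delAGA", "p.Lys814del", _IF, 814, None, 1, 0, 0, 0),
    ("MYBPC3", "c.1558G>T", "p.Glu520Ter", _NS, 520, None, 1, 0, 0, 0),
    ("MYBPC3", "c.1227-2A>G", None, _SA, None, None, 1, 1, 0, 0),
    ("MYL2", "c.278C>T", "p.Ala93Val", _MS, 93, None, 1, 4, 0, 0),
    ("MYL3", "c.508G>C", "p.Glu170Gln", _MS, 170, None, 3, 3, 0, 0),
    ("TNNI3", "c.485G>T", "p.Arg162Leu", _MS, 162, None, 1, 0, 0, 0),
    ("CSRP3", "c.415-1G>C", None, _SA, None, None, 1, 0, 0, 0),
    ("CSRP3", "c.414+1G>T", None, _SD, None, None, 3, 1, 0, 1),
    ("CSRP3", "c.365G>A", "p.Arg122Gln", _MS, 122, 2.9e-6, 1, 3, 0, 0),
]

_LOWFREQ_VARIANTS = [
    ("MYBPC3", "c.3676C>T", "p.Arg1226Cys", _MS, 1226, 6.4e-5, 1, 0, 0, 0),
    ("MYBPC3", "c.2618C>A", "p.Pro873His", _MS, 873, 9.3e-5, 1, 0, 0, 0),
    ("MYBPC3", "c.1321G>A", "p.Glu441Lys", _MS, 441, 2.0e-4, 2, 22, 0, 8),
    ("MYL3", "c.530A>G", "p.Glu177Gly", _MS, 177, 4.4e-5, 4, 1, 0, 3),
    ("MYL3", "c.170C>A", "p.Ala57Asp", _MS, 57, 4.0e-4, 2, 1, 0, 0),
    ("JPH2", "c.572C>G", "p.Pro191Arg", _MS, 191, 2.0e-4, 1, 1, 0, 1),
]

# Nonrare (low-frequency window) variant carried recurrently in cases only.
_NONRARE_VARIANTS = [
    ("TNNT2", "c.832C>T", "p.Arg278Cys", _MS, 278, 2.0e-3, 0, 6, 0, 0),
]

# TRIM63 biallelic genotypes among the callable subset of cases.
_TRIM63_VARIANTS = [
    ("TRIM63", "c.224G>A", "p.Cys75Tyr", _MS, 75, 2.0e-4, 5, 0, 0, 2),
    ("TRIM63", "c.739C>T", "p.Gln247Ter", _NS, 247, None, 2, 0, 0, 0),
    # the two alleles of the single putative compound heterozygote
    ("TRIM63", "c.110T>C", "p.Leu37Pro", _MS, 37, None, 0, 1, 0, 0),
    ("TRIM63", "c.478G>A", "p.Ala160Thr", _MS, 160, None, 0, 1, 0, 0),
]

# Filler carrier totals padding each gene to its published per-tier
# patient totals (rare tier / additional low-frequency tier).  The MYH7
# rare fillers are split so that, together with the named in-region
# variants, exactly 64 case carriers of rare missense variants fall in
# the case-enriched region (residues 167-931).
_RARE_FILLER = {
    # gene: list of (n_carriers, consequence, residue)
    "MYH7": [(58, _MS, 400), (10, _MS, 1500)],
    "MYBPC3": [(40, _NS, None), (37, _MS, 600)],
    "CSRP3": [(6, _MS, 100)],
    "MYL2": [(8, _MS, 80), (1, _SD, None)],
    "MYL3": [(8, _MS, 120)],
    "TNNT2": [(6, _MS, 150)],
    "ACTC1": [(4, _MS, 200)],
    "TNNI3": [(3, _MS, 140)],
    "TPM1": [(2, _MS, 100)],
    "TNNC1": [(2, _MS, 90)],
    "ACTN2": [(12, _MS, 300)],
    "JPH2": [(14, _MS, 250)],
}
_LOWFREQ_FILLER = {
    "MYH7": [(5, _MS, 1500)],
    "MYBPC3": [(19, _MS, 700)],
    "MYL3": [(3, _MS, 60)],
    "TNNT2": [(8, _MS, 180)],
    "ACTN2": [(8, _MS, 320)],
    "JPH2": [(2, _MS, 260)],
}
_FILLER_CHUNK = 6  # carriers per synthetic filler variant
_LOWFREQ_FILLER_FAF = 1.0e-4

# One published reclassification anchor: a case VUS observed in two
# matched controls (counted inside the MYBPC3 rare filler total).
_CONTROL_SEEN_VUS = ("MYBPC3", "c.305C>T", "p.Pro102Leu", _MS, 102, None)

_N_CASES, _N_CONTROLS = 514, 400
_TRIM63_CALLABLE = 374
_CONSANG_YES, _CONSANG_NO, _CONSANG_UNKNOWN = 99, 249, 166
_HOM_YES, _HOM_NO, _HOM_UNKNOWN = 14, 10, 8
_N_GENOTYPE_POSITIVE = 240  # unique rare-tier carriers (271 gene-slots)

#: Expected summary statistics the fixture realises exactly.
EGYPT_EXPECTED: dict = {
    "n_cases": _N_CASES,
    "n_controls": _N_CONTROLS,
    "rare_hom_carriers": 21,
    "lowfreq_hom_carriers": 11,
    "csrp3_hom": (5, 15),
    "mlc_hom": (10, 39),
    "founder_carriers": 17,
    "trim63_biallelic": (8, _TRIM63_CALLABLE),
    "genotype_positive": _N_GENOTYPE_POSITIVE,
    "rare_gene_slots": 271,
    "consanguinity_hom": {"yes": (14, 99), "no": (10, 249), "unknown": (8, 166)},
    "table4": {
        # stratum: (rare patients, rare hom, additional patients, additional hom)
        "MYH7": (99, 6, 5, 0),
        "MYBPC3": (85, 5, 45, 4),
        "CSRP3": (15, 5, 0, 0),
        "MLC": (28, 4, 11, 6),
        "thin_filament": (18, 1, 8, 0),
        "ACTN2": (12, 0, 8, 0),
        "JPH2": (14, 0, 4, 1),
        "PLN": (0, 0, 0, 0),
    },
    "glu441lys_carriers": (24, 8),
    "arg278cys_carriers": (6, 0),
    "myh7_cluster_carriers": (64, 0),
}

_GROUPS = {
    "MLC": {"MYL2", "MYL3"},
    "thin_filament": {"ACTC1", "TNNC1", "TNNI3", "TNNT2", "TPM1"},
}


def _case_id(i: int) -> str:
    return f"E{i:03d}"


def _ctrl_id(i: int) -> str:
    return f"C{i:03d}"


class _Builder:
    def __init__(self) -> None:
        self.variants: list[Variant] = []
        self.genotypes: list[GenotypeRecord] = []
        self.case_genes: dict[str, set[str]] = {}  # sample -> genes carried
        self.hits: dict[str, int] = {}  # sample -> number of gene slots
        self.next_case = 1
        self.next_ctrl = 1
        self.hom_samples_rare: list[str] = []
        self.hom_samples_lowfreq: list[str] = []

    def add_variant(self, gene, hgvs_c, hgvs_p, consequence, residue, faf) -> str:
        vid = f"{gene}:{hgvs_c}"
        self.variants.append(
            Variant(
                variant_id=vid,
                gene=gene,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                consequence=consequence,
                protein_residue=residue,
                faf_popmax=faf,
            )
        )
        return vid

    def new_case(self, gene: str) -> str:
        sid = _case_id(self.next_case)
        self.next_case += 1
        self.case_genes[sid] = {gene}
        self.hits[sid] = 1
        return sid

    def attach_second_hit(self, gene: str) -> Optional[str]:
        """Earliest single-hit case not already carrying *gene*."""
        for i in range(1, self.next_case):
            sid = _case_id(i)
            if self.hits.get(sid, 0) == 1 and gene not in self.case_genes[sid]:
                self.case_genes[sid].add(gene)
                self.hits[sid] += 1
                return sid
        return None

    def genotype(self, sid: str, vid: str, zyg: Zygosity) -> None:
        self.genotypes.append(GenotypeRecord(sid, vid, zyg))


def egypt_like_fixture() -> tuple[Cohort, dict]:
    """Build the count-exact cohort; returns (cohort, expected table).

    Deterministic: repeated calls produce identical cohorts.  Raises if
    the constructed data fail the internal consistency check against
    :data:`EGYPT_EXPECTED`.
    """
    b = _Builder()

    # Named rare variants: hom carriers first (new samples), then hets.
    het_queue: list[tuple[str, str]] = []  # (variant_id, gene)
    ctrl_queue: list[tuple[str, Zygosity]] = []
    for gene, c, p, csq, res, faf, chom, chet, khom, khet in _RARE_VARIANTS:
        vid = b.add_variant(gene, c, p, csq, res, faf)
        for _ in range(chom):
            sid = b.new_case(gene)
            b.genotype(sid, vid, Zygosity.HOM)
            b.hom_samples_rare.append(sid)
        het_queue.extend([(vid, gene)] * chet)
        ctrl_queue.extend([(vid, Zygosity.HOM)] * khom + [(vid, Zygosity.HET)] * khet)
    for vid, gene in het_queue:
        sid = b.new_case(gene)
        b.genotype(sid, vid, Zygosity.HET)

    # Rare-tier filler carriers: pad per-gene totals; the first second-hit
    # slots are attached to existing carriers of other genes so that the
    # 271 gene-carrier slots collapse onto 240 unique patients.
    second_hits_left = 271 - _N_GENOTYPE_POSITIVE
    vus_gene, vus_c, vus_p, vus_csq, vus_res, vus_faf = _CONTROL_SEEN_VUS
    vus_vid = b.add_variant(vus_gene, vus_c, vus_p, vus_csq, vus_res, vus_faf)
    ctrl_queue.extend([(vus_vid, Zygosity.HET)] * 2)
    filler_slots: list[tuple[str, Consequence, Optional[int], Optional[float], str]] = []
    for gene, blocks in _RARE_FILLER.items():
        for n, csq, res in blocks:
            if gene == vus_gene and csq == _MS:
                n -= 1  # the control-seen VUS occupies one filler slot
                filler_slots.append((gene, csq, vus_res, vus_faf, vus_vid))
            filler_slots.extend([(gene, csq, res, None, "")] * n)
    k = 0
    chunk_left = 0
    chunk_key: tuple = ()
    current_vid = ""
    for gene, csq, res, faf, fixed_vid in filler_slots:
        if fixed_vid:
            vid = fixed_vid
        else:
            if chunk_left == 0 or chunk_key != (gene, csq, res):
                k += 1
                current_vid = b.add_variant(gene, f"c.f{k}", None, csq, res, faf)
                chunk_left = _FILLER_CHUNK
                chunk_key = (gene, csq, res)
            vid = current_vid
            chunk_left -= 1
        sid = None
        if second_hits_left > 0:
            sid = b.attach_second_hit(gene)
            if sid is not None:
                second_hits_left -= 1
        if sid is None:
            sid = b.new_case(gene)
        b.genotype(sid, vid, Zygosity.HET)
    if second_hits_left != 0:
        raise AssertionError("could not place all multi-gene carrier slots")

    # Low-frequency (additional) tier: fresh patients throughout.
    for gene, c, p, csq, res, faf, chom, chet, khom, khet in _LOWFREQ_VARIANTS:
        vid = b.add_variant(gene, c, p, csq, res, faf)
        for _ in range(chom):
            sid = b.new_case(gene)
            b.genotype(sid, vid, Zygosity.HOM)
            b.hom_samples_lowfreq.append(sid)
        for _ in range(chet):
            b.genotype(b.new_case(gene), vid, Zygosity.HET)
        ctrl_queue.extend([(vid, Zygosity.HOM)] * khom + [(vid, Zygosity.HET)] * khet)
    for gene, blocks in _LOWFREQ_FILLER.items():
        for n, csq, res in blocks:
            for j in range(n):
                if j % _FILLER_CHUNK == 0:
                    k += 1
                    vid = b.add_variant(
                        gene, f"c.f{k}", None, csq, res, _LOWFREQ_FILLER_FAF
                    )
                b.genotype(b.new_case(gene), vid, Zygosity.HET)

    # Nonrare recurrent variants (outside both tiers, case-enriched).
    for gene, c, p, csq, res, faf, chom, chet, khom, khet in _NONRARE_VARIANTS:
        vid = b.add_variant(gene, c, p, csq, res, faf)
        for _ in range(chom):
            b.genotype(b.new_case(gene), vid, Zygosity.HOM)
        for _ in range(chet):
            b.genotype(b.new_case(gene), vid, Zygosity.HET)
        ctrl_queue.extend([(vid, Zygosity.HOM)] * khom + [(vid, Zygosity.HET)] * khet)

    # TRIM63 biallelic genotypes: 7 homozygotes + 1 compound het.
    trim_vids = []
    for gene, c, p, csq, res, faf, chom, chet, khom, khet in _TRIM63_VARIANTS:
        vid = b.add_variant(gene, c, p, csq, res, faf)
        trim_vids.append((vid, chom, chet))
        ctrl_queue.extend([(vid, Zygosity.HOM)] * khom + [(vid, Zygosity.HET)] * khet)
    for vid, chom, _ in trim_vids:
        for _ in range(chom):
            b.genotype(b.new_case("TRIM63"), vid, Zygosity.HOM)
    compound = b.new_case("TRIM63")
    for vid, _, chet in trim_vids:
        if chet:
            b.genotype(compound, vid, Zygosity.HET)

    # Remaining genotype-negative cases.
    while b.next_case <= _N_CASES:
        b.new_case("")  # placeholder; gene set unused for negatives
    used_cases = [_case_id(i) for i in range(1, _N_CASES + 1)]

    # Consanguinity labels: homozygous carriers realise the published
    # stratified rates exactly; the remainder fill the cohort margins.
    hom_carriers = b.hom_samples_rare + b.hom_samples_lowfreq
    consang: dict[str, Consanguinity] = {}
    for idx, sid in enumerate(hom_carriers):
        if idx < _HOM_YES:
            consang[sid] = Consanguinity.YES
        elif idx < _HOM_YES + _HOM_NO:
            consang[sid] = Consanguinity.NO
        else:
            consang[sid] = Consanguinity.UNKNOWN
    rest = [s for s in used_cases if s not in consang]
    yes_left = _CONSANG_YES - _HOM_YES
    no_left = _CONSANG_NO - _HOM_NO
    for i, sid in enumerate(rest):
        if i < yes_left:
            consang[sid] = Consanguinity.YES
        elif i < yes_left + no_left:
            consang[sid] = Consanguinity.NO
        else:
            consang[sid] = Consanguinity.UNKNOWN

    # Per-gene callability: TRIM63 was callable in only 374 cases; the
    # non-callable 140 are drawn from genotype-negative patients.
    all_genes = sorted(
        {
            "MYH7", "MYBPC3", "MYL2", "MYL3", "ACTC1", "TNNC1", "TNNI3",
            "TNNT2", "TPM1", "PLN", "ACTN2", "CSRP3", "JPH2", "TRIM63",
        }
    )
    no_trim = frozenset(g for g in all_genes if g != "TRIM63")
    n_uncallable = _N_CASES - _TRIM63_CALLABLE
    uncallable = set(used_cases[-n_uncallable:])
    trim_carriers = {
        g.sample_id
        for g in b.genotypes
        if g.variant_id.startswith("TRIM63:")
    }
    if uncallable & trim_carriers:
        raise AssertionError("TRIM63 carriers must stay in the callable subset")

    samples = [
        Sample(
            sample_id=sid,
            role=Role.CASE,
            consanguinity=consang[sid],
            callable_genes=no_trim if sid in uncallable else None,
        )
        for sid in used_cases
    ]
    # Controls: assign queued control genotypes to fresh control samples.
    ctrl_genotypes: list[GenotypeRecord] = []
    for vid, zyg in ctrl_queue:
        sid = _ctrl_id(b.next_ctrl)
        b.next_ctrl += 1
        ctrl_genotypes.append(GenotypeRecord(sid, vid, zyg))
    samples.extend(
        Sample(sample_id=_ctrl_id(i), role=Role.CONTROL)
        for i in range(1, _N_CONTROLS + 1)
    )

    cohort = Cohort.build(
        samples, b.genotypes + ctrl_genotypes, b.variants, name="egypt_like"
    )
    _check_fixture(cohort, b)
    return cohort, dict(EGYPT_EXPECTED)


def _check_fixture(cohort: Cohort, b: _Builder) -> None:
    """Raw-count consistency check against the expected table."""
    exp = EGYPT_EXPECTED
    if cohort.n_cases != exp["n_cases"] or cohort.n_controls != exp["n_controls"]:
        raise AssertionError("fixture cohort sizes wrong")
    if len(b.hom_samples_rare) != exp["rare_hom_carriers"]:
        raise AssertionError("rare-tier homozygote count wrong")
    if len(b.hom_samples_lowfreq) != exp["lowfreq_hom_carriers"]:
        raise AssertionError("low-frequency-tier homozygote count wrong")
    founder = sum(
        1 for g in cohort.genotypes if g.variant_id == "MYH7:c.5769delG"
        and g.sample_id.startswith("E")
    )
    if founder != exp["founder_carriers"]:
        raise AssertionError("founder carrier count wrong")
    # per-gene tier totals (case side)
    case_ids = {s.sample_id for s in cohort.samples_by_role(Role.CASE)}
    for stratum, (n_rare, _, n_add, _) in exp["table4"].items():
        genes = _GROUPS.get(stratum, {stratum})
        rare_ids = {
            v.variant_id
            for v in cohort.catalogue.values()
            if v.gene in genes and v.faf_for_filtering <= 4e-5
        }
        lf_ids = {
            v.variant_id
            for v in cohort.catalogue.values()
            if v.gene in genes and 4e-5 < v.faf_for_filtering <= 1.26e-3
        }
        rare_carriers = {
            g.sample_id for g in cohort.genotypes
            if g.variant_id in rare_ids and g.sample_id in case_ids
        }
        lf_carriers = {
            g.sample_id for g in cohort.genotypes
            if g.variant_id in lf_ids and g.sample_id in case_ids
        }
        if len(rare_carriers) != n_rare or len(lf_carriers - rare_carriers) != n_add:
            raise AssertionError(
                f"{stratum}: carrier totals "
                f"({len(rare_carriers)}, {len(lf_carriers - rare_carriers)}) "
                f"!= expected ({n_rare}, {n_add})"
            )


def load_published_excess() -> pd.DataFrame:
    """Published per-stratum excess-burden columns for both cohorts.

    Columns: stratum, vclass, egypt_excess_pct, uk_excess_pct,
    egypt_gpos_prop_pct, uk_gpos_prop_pct.  Values are percentages as
    printed in the source summary table.
    """
    with resources.files("hcmcohort.data").joinpath("published_excess.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def excess_ratio(published: Optional[pd.DataFrame] = None) -> float:
    """Ratio of summed excess-burden columns (cohort A over cohort B)."""
    df = load_published_excess() if published is None else published
    return float(df["egypt_excess_pct"].sum() / df["uk_excess_pct"].sum())
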