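"""Readers and writers for cohort tables, panel/config YAML, and VCF.

Text tables are UTF-8, tab-separated, with a mandatory header row; column
order is free but column names are fixed:

* variant catalogue: ``variant_id gene hgvs_c hgvs_p consequence
  protein_residue faf_popmax`` (``variant_id`` may be omitted, in which
  case ``gene:hgvs_c`` is used);
* genotype table: ``sample_id variant_id zygosity``;
* sample manifest: ``sample_id role consanguinity callable_genes``
  (callable_genes semicolon-joined, optional).

A missing FAF field denotes a variant absent from the reference
population and is stored as missing, never as zero.  Genotypes can also
be ingested from a multi-sample VCF; gene and consequence annotations
come from INFO keys (``GENE``, ``CONSEQUENCE``, optional ``FAF_POPMAX``)
or a sidecar table keyed by (chrom, pos, ref, alt).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    Cohort,
    Consanguinity,
    Consequence,
    GenePanel,
    GeneGroup,
    GenotypeRecord,
    IntegrityError,
    RegionCluster,
    Role,
    Sample,
    Variant,
    Zygosity,
)

_CATALOGUE_COLUMNS = [
    "variant_id",
    "gene",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "protein_residue",
    "faf_popmax",
]
_GENOTYPE_COLUMNS = ["sample_id", "variant_id", "zygosity"]
_MANIFEST_COLUMNS = ["sample_id", "role", "consanguinity", "callable_genes"]

#: Autosomal chromosome labels accepted from VCF input.
_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def _is_blank(x: object) -> bool:
    return x is None or (isinstance(x, float) and pd.isna(x)) or str(x).strip() == ""


def format_faf(faf: Optional[float]) -> str:
    """Render a FAF for the TSV; exact for values printed to <=3 sig digits."""
    if faf is None:
        return ""
    return f"{faf:.6g}"


def parse_faf(token: object) -> Optional[float]:
    if _is_blank(token):
        return None
    return float(str(token))


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing required columns {missing}")
    return df


def load_variant_catalogue(
    path: str | os.PathLike, dialect: str = "tsv"
) -> list[Variant]:
    """Read and validate a variant catalogue table.

    Rows are numbered from 1 (excluding the header) in error messages.
    Unknown consequence tokens and duplicate (gene, hgvs_c) pairs are
    rejected.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported table dialect {dialect!r}")
    df = _read_tsv(path, required=["gene", "hgvs_c", "consequence", "faf_popmax"])
    variants: list[Variant] = []
    seen: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        token = str(row["consequence"]).strip()
        try:
            consequence = Consequence(token)
        except ValueError:
            raise IntegrityError(
                f"{path} row {i}: unknown consequence {token!r}"
            ) from None
        key = (row["gene"].strip(), row["hgvs_c"].strip())
        if key in seen:
            raise IntegrityError(
                f"{path} row {i}: duplicate (gene, hgvs_c) {key} "
                f"(first seen at row {seen[key]})"
            )
        seen[key] = i
        vid = row.get("variant_id")
        residue = row.get("protein_residue")
        hgvs_p = row.get("hgvs_p")
        variants.append(
            Variant(
                variant_id=f"{key[0]}:{key[1]}" if _is_blank(vid) else str(vid).strip(),
                gene=key[0],
                hgvs_c=key[1],
                hgvs_p=None if _is_blank(hgvs_p) else str(hgvs_p).strip(),
                consequence=consequence,
                protein_residue=None if _is_blank(residue) else int(float(residue)),
                faf_popmax=parse_faf(row["faf_popmax"]),
            )
        )
    return variants


def load_cohort(
    manifest: str | os.PathLike,
    genotypes: str | os.PathLike,
    catalogue: Iterable[Variant],
    name: str = "cohort",
) -> Cohort:
    """Assemble a cohort from manifest + genotype tables and a catalogue.

    Referential integrity is enforced: genotypes referencing unknown
    samples or variants are rejected with the offending ids listed.
    Blank consanguinity fields become ``unknown``.
    """
    mdf = _read_tsv(manifest, required=["sample_id", "role"])
    samples: list[Sample] = []
    for i, row in enumerate(mdf.itertuples(index=False), start=1):
        row = row._asdict()
        consang = row.get("consanguinity")
        callable_raw = row.get("callable_genes")
        callable_genes = (
            None
            if _is_blank(callable_raw)
            else frozenset(g for g in str(callable_raw).split(";") if g)
        )
        try:
            samples.append(
                Sample(
                    sample_id=str(row["sample_id"]).strip(),
                    role=Role(str(row["role"]).strip()),
                    consanguinity=(
                        Consanguinity.UNKNOWN
                        if _is_blank(consang)
                        else Consanguinity(str(consang).strip())
                    ),
                    callable_genes=callable_genes,
                )
            )
        except ValueError as exc:
            raise IntegrityError(f"{manifest} row {i}: {exc}") from None
    gdf = _read_tsv(genotypes, required=_GENOTYPE_COLUMNS)
    records: list[GenotypeRecord] = []
    for i, row in enumerate(gdf.itertuples(index=False), start=1):
        row = row._asdict()
        token = str(row["zygosity"]).strip()
        try:
            zyg = Zygosity(token)
        except ValueError:
            raise IntegrityError(
                f"{genotypes} row {i}: unknown zygosity token {token!r}"
            ) from None
        records.append(
            GenotypeRecord(
                sample_id=str(row["sample_id"]).strip(),
                variant_id=str(row["variant_id"]).strip(),
                zygosity=zyg,
            )
        )
    return Cohort.build(samples, records, catalogue, name=name)


# -- writers ---------------------------------------------------------------


def write_variant_catalogue(variants: Iterable[Variant], path: str | os.PathLike) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "hgvs_c": v.hgvs_c,
            "hgvs_p": v.hgvs_p or "",
            "consequence": v.consequence.value,
            "protein_residue": "" if v.protein_residue is None else v.protein_residue,
            "faf_popmax": format_faf(v.faf_popmax),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_CATALOGUE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_manifest(samples: Iterable[Sample], path: str | os.PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "role": s.role.value,
            "consanguinity": s.consanguinity.value,
            "callable_genes": (
                "" if s.callable_genes is None else ";".join(sorted(s.callable_genes))
            ),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_genotypes(records: Iterable[GenotypeRecord], path: str | os.PathLike) -> None:
    rows = [
        {"sample_id": g.sample_id, "variant_id": g.variant_id, "zygosity": g.zygosity.value}
        for g in records
    ]
    pd.DataFrame(rows, columns=_GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> dict[str, str]:
    """Write a cohort as three TSVs in *directory*; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "catalogue": os.path.join(directory, "catalogue.tsv"),
        "manifest": os.path.join(directory, "manifest.tsv"),
        "genotypes": os.path.join(directory, "genotypes.tsv"),
    }
    write_variant_catalogue(cohort.catalogue.values(), paths["catalogue"])
    write_manifest(cohort.samples.values(), paths["manifest"])
    write_genotypes(cohort.genotypes, paths["genotypes"])
    return paths


def read_cohort(directory: str | os.PathLike, name: str = "cohort") -> Cohort:
    """Inverse of :func:`write_cohort`."""
    catalogue = load_variant_catalogue(os.path.join(directory, "catalogue.tsv"))
    return load_cohort(
        os.path.join(directory, "manifest.tsv"),
        os.path.join(directory, "genotypes.tsv"),
        catalogue,
        name=name,
    )


# -- panel / config YAML ---------------------------------------------------


def load_panel(path: str | os.PathLike) -> GenePanel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return panel_from_dict(doc)


def panel_from_dict(doc: Mapping) -> GenePanel:
    genes = {g: GeneGroup(grp) for g, grp in doc.get("genes", {}).items()}
    clusters = tuple(
        RegionCluster(
            gene=c["gene"],
            residue_start=int(c["residue_start"]),
            residue_end=int(c["residue_end"]),
            ef=c.get("ef"),
        )
        for c in doc.get("clusters", [])
    )
    return GenePanel(genes=genes, clusters=clusters)


def load_analysis_config(path: str | os.PathLike) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return AnalysisConfig(**doc)


# -- VCF ingestion ---------------------------------------------------------


def ingest_vcf(
    path: str | os.PathLike,
    panel: GenePanel,
    annotations: Optional[Mapping[tuple[str, int, str, str], Mapping]] = None,
) -> tuple[list[Variant], list[GenotypeRecord]]:
    """Read a multi-sample VCF into catalogue + genotype fragments.

    Diploid genotypes map 0/1 -> het, 1/1 -> hom; 0/0 and ./. are
    dropped.  Multiallelic sites are decomposed into one variant per ALT
    allele, with each sample's genotype resolved against the allele
    index.  Gene/consequence come from INFO keys ``GENE``/``CONSEQUENCE``
    or from the *annotations* sidecar keyed by (chrom, pos, ref, alt).
    Non-autosomal records are rejected (the panel is autosomal).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    records: list[GenotypeRecord] = []
    for site in vcf:
        chrom = str(site.CHROM)
        if chrom not in _AUTOSOMES:
            raise IntegrityError(
                f"non-autosomal record {chrom}:{site.POS}; panel genes are autosomal"
            )
        gts = site.genotypes
        if gts is None:
            raise IntegrityError(f"missing GT format at {chrom}:{site.POS}")
        for alt_index, alt in enumerate(site.ALT, start=1):
            key = (chrom, int(site.POS), site.REF, alt)
            ann = dict(annotations.get(key, {})) if annotations else {}
            gene = ann.get("gene") or site.INFO.get("GENE")
            consequence = ann.get("consequence") or site.INFO.get("CONSEQUENCE")
            if gene is None or consequence is None:
                raise IntegrityError(
                    f"{chrom}:{site.POS} ALT {alt}: gene/consequence annotation required"
                )
            faf = ann.get("faf_popmax", site.INFO.get("FAF_POPMAX"))
            residue = ann.get("protein_residue")
            vid = f"{chrom}-{site.POS}-{site.REF}-{alt}"
            variants.append(
                Variant(
                    variant_id=vid,
                    gene=str(gene),
                    hgvs_c=ann.get("hgvs_c", vid),
                    hgvs_p=ann.get("hgvs_p"),
                    consequence=Consequence(str(consequence)),
                    protein_residue=None if residue is None else int(residue),
                    faf_popmax=None if faf is None else float(faf),
                )
            )
            for sample_id, gt in zip(sample_ids, gts):
                alleles = gt[:-1]  # last element is the phasing flag
                if len(alleles) != 2:
                    raise IntegrityError(
                        f"non-diploid call for {sample_id} at {chrom}:{site.POS}"
                    )
                if any(a is None or a < 0 for a in alleles):
                    continue  # ./. or half-missing: dropped
                dose = sum(1 for a in alleles if a == alt_index)
                if dose == 0:
                    continue
                records.append(
                    GenotypeRecord(
                        sample_id=sample_id,
                        variant_id=vid,
                        zygosity=Zygosity.HOM if dose == 2 else Zygosity.HET,
                    )
                )
    return variants, records
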