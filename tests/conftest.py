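import pytest

from hcmcohort import (
    AnalysisConfig,
    Cohort,
    Consequence,
    GenePanel,
    GenotypeRecord,
    Role,
    Sample,
    Variant,
    Zygosity,
    egypt_like_fixture,
)


@pytest.fixture(scope="session")
def egypt():
    """Count-exact cohort fixture plus its expected summary table."""
    cohort, expected = egypt_like_fixture()
    return cohort, expected


@pytest.fixture(scope="session")
def egypt_cohort(egypt):
    return egypt[0]


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def panel():
    return GenePanel()


def make_variant(
    gene="MYH7",
    hgvs_c="c.1A>G",
    consequence=Consequence.MISSENSE,
    faf=None,
    residue=None,
    hgvs_p=None,
    vid=None,
):
    return Variant(
        variant_id=vid or f"{gene}:{hgvs_c}",
        gene=gene,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        consequence=consequence,
        protein_residue=residue,
        faf_popmax=faf,
    )


def make_cohort(variants, genotypes, n_cases=4, n_controls=4, consanguinity=None):
    """Tiny cohort builder: genotypes as (sample_id, variant_id, zygosity).

    Case ids S1..Sn, control ids T1..Tm; *consanguinity* maps sample ids
    to 'yes'/'no'/'unknown'.
    """
    consanguinity = consanguinity or {}
    samples = [
        Sample(f"S{i}", Role.CASE, consanguinity.get(f"S{i}", "unknown"))
        for i in range(1, n_cases + 1)
    ] + [
        Sample(f"T{i}", Role.CONTROL, consanguinity.get(f"T{i}", "unknown"))
        for i in range(1, n_controls + 1)
    ]
    records = [GenotypeRecord(s, v, Zygosity(z)) for s, v, z in genotypes]
    return Cohort.build(samples, records, variants, name="tiny")
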