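"""Evidence combination, regional EF rule, reclassification, yields.

``oracle_combine`` is an independent transcription of the combination
table used to cross-check the engine exhaustively.
"""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hcmcohort import (
    AcmgClass,
    AnalysisConfig,
    Consequence,
    EvidenceItem,
    EvidenceSet,
    Polarity,
    RegionCluster,
    Strength,
    actionable_yield,
    apply_ef_rule,
    classify_patient,
    cluster_ef,
    cohort_informed_update,
    combine_evidence,
    reclassify_catalogue,
)

from conftest import make_cohort, make_variant

# evidence "categories" for enumeration: (polarity, strength)
CATEGORIES = [
    (Polarity.PATHOGENIC, Strength.VERY_STRONG),
    (Polarity.PATHOGENIC, Strength.STRONG),
    (Polarity.PATHOGENIC, Strength.MODERATE),
    (Polarity.PATHOGENIC, Strength.SUPPORTING),
    (Polarity.BENIGN, Strength.STAND_ALONE),
    (Polarity.BENIGN, Strength.STRONG),
    (Polarity.BENIGN, Strength.SUPPORTING),
]


def oracle_combine(counts):
    """Brute-force combination table on category counts.

    counts: tuple aligned with CATEGORIES
    (pvs, ps, pm, pp, ba, bs, bp).
    """
    pvs, ps, pm, pp, ba, bs, bp = counts
    pathogenic = False
    if pvs >= 2:
        pathogenic = True
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        pathogenic = True
    if ps >= 2:
        pathogenic = True
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        pathogenic = True
    likely_pathogenic = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and pm in (1, 2))
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = bs == 1 or bp >= 2
    path_side = AcmgClass.PATHOGENIC if pathogenic else (
        AcmgClass.LIKELY_PATHOGENIC if likely_pathogenic else None
    )
    benign_side = AcmgClass.BENIGN if benign else (
        AcmgClass.LIKELY_BENIGN if likely_benign else None
    )
    if path_side is not None and benign_side is not None:
        return AcmgClass.VUS
    if path_side is not None:
        return path_side
    if benign_side is not None:
        return benign_side
    return AcmgClass.VUS


def _evidence_from_counts(counts):
    items = []
    k = 0
    for (pol, strength), n in zip(CATEGORIES, counts):
        for _ in range(n):
            k += 1
            items.append(EvidenceItem(f"X{k}", pol, strength))
    return items


def _all_count_vectors(max_total):
    for counts in itertools.product(range(max_total + 1), repeat=len(CATEGORIES)):
        if sum(counts) <= max_total:
            yield counts


def test_combine_matches_oracle_for_all_multisets_up_to_six():
    for counts in _all_count_vectors(6):
        got = combine_evidence(_evidence_from_counts(counts)).klass
        assert got is oracle_combine(counts), counts


@pytest.mark.parametrize(
    "items, expected",
    [
        ([("PVS1", "pathogenic", "very_strong"), ("PS3", "pathogenic", "strong")],
         AcmgClass.PATHOGENIC),
        ([("PM1", "pathogenic", "strong"), ("PM2", "pathogenic", "moderate")],
         AcmgClass.LIKELY_PATHOGENIC),  # region evidence upgraded to strong
        ([], AcmgClass.VUS),
        ([("BA1", "benign", "stand_alone")], AcmgClass.BENIGN),
        ([("BS_cohort", "benign", "strong")], AcmgClass.LIKELY_BENIGN),
    ],
)
def test_combine_known_profiles(items, expected):
    ev = [EvidenceItem(c, p, s) for c, p, s in items]
    assert combine_evidence(ev).klass is expected


evidence_sets = st.lists(
    st.sampled_from(CATEGORIES), min_size=0, max_size=7
).map(
    lambda cats: [
        EvidenceItem(f"E{i}", pol, strength)
        for i, (pol, strength) in enumerate(cats)
    ]
)


@settings(max_examples=300, derandomize=True)
@given(evidence_sets, st.sampled_from(CATEGORIES))
def test_monotonicity_under_evidence_addition(items, extra):
    """Pathogenic evidence never lowers the class; benign never raises."""
    base = combine_evidence(items).klass
    pol, strength = extra
    try:
        added = combine_evidence(items + [EvidenceItem("ZZZ", pol, strength)]).klass
    except ValueError:
        return
    if pol is Polarity.PATHOGENIC:
        assert added >= base
    else:
        assert added <= base


def test_stand_alone_pathogenic_rejected():
    with pytest.raises(ValueError):
        EvidenceItem("XX", Polarity.PATHOGENIC, Strength.STAND_ALONE)


def test_duplicate_codes_rejected():
    ev = EvidenceSet([EvidenceItem("PM2", Polarity.PATHOGENIC, Strength.MODERATE)])
    with pytest.raises(ValueError, match="duplicate"):
        ev.add(EvidenceItem("PM2", Polarity.PATHOGENIC, Strength.SUPPORTING))


class TestEfRule:
    CLUSTER = RegionCluster("MYH7", 167, 931, ef=0.99)

    def test_inside_cluster_missense_gets_strong_region_evidence(self):
        v = make_variant("MYH7", "c.1500G>A", Consequence.MISSENSE, residue=500)
        item = apply_ef_rule(v, [self.CLUSTER])
        assert item is not None
        assert item.code == "PM1" and item.strength is Strength.STRONG

    def test_outside_cluster_and_truncating_get_nothing(self):
        outside = make_variant("MYH7", "c.3000G>A", Consequence.MISSENSE, residue=1000)
        assert apply_ef_rule(outside, [self.CLUSTER]) is None
        truncating = make_variant("MYH7", "c.4fs", Consequence.FRAMESHIFT, residue=500)
        assert apply_ef_rule(truncating, [self.CLUSTER]) is None

    def test_missing_residue_gives_nothing(self):
        v = make_variant("MYH7", "c.5G>A", Consequence.MISSENSE, residue=None)
        assert apply_ef_rule(v, [self.CLUSTER]) is None

    def test_below_threshold_cluster_inactive(self):
        weak = RegionCluster("MYH7", 167, 931, ef=0.90)
        v = make_variant("MYH7", "c.1500G>A", Consequence.MISSENSE, residue=500)
        assert apply_ef_rule(v, [weak]) is None

    def test_idempotent(self):
        v = make_variant("MYH7", "c.1500G>A", Consequence.MISSENSE, residue=500)
        first = apply_ef_rule(v, [self.CLUSTER])
        again = apply_ef_rule(v, [self.CLUSTER])
        assert first == again


class TestClusterEf:
    def test_fixture_region_reaches_099(self, egypt_cohort):
        from hcmcohort import MYH7_CLUSTER

        filled = cluster_ef(egypt_cohort, MYH7_CLUSTER)
        assert filled.ef == pytest.approx(0.99, abs=0.005)

    def test_twofold_enrichment_gives_ef_half(self):
        # 40/1000 cases vs 20/1000 controls: OR ~ 2, EF ~ 0.5
        variants = [
            make_variant("MYH7", "c.10A>G", Consequence.MISSENSE, residue=500)
        ]
        genotypes = [(f"S{i}", "MYH7:c.10A>G", "het") for i in range(1, 41)]
        genotypes += [(f"T{i}", "MYH7:c.10A>G", "het") for i in range(1, 21)]
        cohort = make_cohort(variants, genotypes, n_cases=1000, n_controls=1000)
        filled = cluster_ef(cohort, RegionCluster("MYH7", 167, 931))
        assert filled.ef == pytest.approx(0.5, abs=0.03)

    def test_no_carriers_rejected(self):
        cohort = make_cohort([], [])
        with pytest.raises(ValueError, match="no carriers"):
            cluster_ef(cohort, RegionCluster("MYH7", 167, 931))


class TestCohortInformed:
    def test_control_presence_adds_strong_benign(self):
        v = make_variant("MYBPC3", "c.305C>T", Consequence.MISSENSE, residue=102)
        deltas = cohort_informed_update(v, case_carriers=1, control_carriers=2)
        assert [d.polarity for d in deltas] == [Polarity.BENIGN]
        base = EvidenceSet(
            [EvidenceItem("PM2", Polarity.PATHOGENIC, Strength.MODERATE)]
        )
        after = combine_evidence(base.with_items(deltas))
        assert combine_evidence(base).klass is AcmgClass.VUS
        assert after.klass is AcmgClass.LIKELY_BENIGN

    def test_case_recurrence_upgrades_lp_to_p(self):
        v = make_variant("MYH7", "c.1500G>A", Consequence.MISSENSE, residue=500)
        deltas = cohort_informed_update(v, case_carriers=3, control_carriers=0)
        assert [d.strength for d in deltas] == [Strength.MODERATE]
        base = EvidenceSet(
            [
                EvidenceItem("PVS1", Polarity.PATHOGENIC, Strength.VERY_STRONG),
                EvidenceItem("PM2", Polarity.PATHOGENIC, Strength.MODERATE),
            ]
        )
        assert combine_evidence(base).klass is AcmgClass.LIKELY_PATHOGENIC
        assert combine_evidence(base.with_items(deltas)).klass is AcmgClass.PATHOGENIC

    def test_no_carriers_no_delta(self):
        v = make_variant("MYH7", "c.1A>G")
        assert cohort_informed_update(v, 0, 0) == []


class TestPatientLevel:
    @pytest.mark.parametrize(
        "classes, expected",
        [
            ([AcmgClass.VUS, AcmgClass.PATHOGENIC], AcmgClass.PATHOGENIC),
            ([AcmgClass.LIKELY_PATHOGENIC, AcmgClass.VUS], AcmgClass.LIKELY_PATHOGENIC),
            ([], None),
        ],
    )
    def test_highest_class_prioritised(self, classes, expected):
        assert classify_patient(classes) is expected

    def _vus_cohort(self):
        variants = [
            make_variant("MYH7", "c.10A>G", Consequence.MISSENSE, residue=500),
            make_variant("MYH7", "c.20A>G", Consequence.MISSENSE, residue=1500),
        ]
        genotypes = [
            ("S1", "MYH7:c.10A>G", "het"),
            ("S2", "MYH7:c.20A>G", "het"),
        ]
        return make_cohort(variants, genotypes)

    def test_yield_increases_when_rule_upgrades_half(self):
        cohort = self._vus_cohort()
        before = {"MYH7:c.10A>G": AcmgClass.VUS, "MYH7:c.20A>G": AcmgClass.VUS}
        after = dict(before, **{"MYH7:c.10A>G": AcmgClass.LIKELY_PATHOGENIC})
        report = actionable_yield(cohort, before, after)
        assert report.actionable_before == 0 and report.actionable_after == 1
        assert report.yield_after > report.yield_before
        assert report.yield_after_gpos == pytest.approx(0.5)

    def test_identical_regimes_identical_yield(self):
        cohort = self._vus_cohort()
        classes = {"MYH7:c.10A>G": AcmgClass.VUS, "MYH7:c.20A>G": AcmgClass.VUS}
        report = actionable_yield(cohort, classes, classes)
        assert report.yield_before == report.yield_after == 0.0

    def test_all_pathogenic_full_yield(self):
        cohort = self._vus_cohort()
        classes = {
            "MYH7:c.10A>G": AcmgClass.PATHOGENIC,
            "MYH7:c.20A>G": AcmgClass.PATHOGENIC,
        }
        report = actionable_yield(cohort, classes, classes)
        assert report.yield_before_gpos == report.yield_after_gpos == 1.0


def test_reclassification_is_deterministic_fixed_point(egypt_cohort):
    baseline = {
        "MYBPC3:c.305C>T": EvidenceSet(
            [EvidenceItem("PM2", Polarity.PATHOGENIC, Strength.MODERATE)]
        )
    }
    first = reclassify_catalogue(egypt_cohort, baseline)
    second = reclassify_catalogue(egypt_cohort, baseline)
    assert {k: (b.klass, a.klass) for k, (b, a) in first.items()} == {
        k: (b.klass, a.klass) for k, (b, a) in second.items()
    }
    # the control-seen case VUS moves to likely benign
    before, after = first["MYBPC3:c.305C>T"]
    assert before.klass is AcmgClass.VUS
    assert after.klass is AcmgClass.LIKELY_BENIGN
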