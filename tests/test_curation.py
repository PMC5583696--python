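import math

import pytest
from hypothesis import given, settings, strategies as st

from ligandlink import (
    ActivityRecord,
    CurationCriteria,
    MeasureType,
    PotencyAnnotation,
    Relation,
    TargetInfo,
    aggregate_potency,
    canonical_key,
    curate,
    exclude_antitargets,
    flag_compounds,
    select_records,
)
from ligandlink.curation import CONFLICT, StructureError
from ligandlink.datamodel import CompoundInfo


def _rec(cid="C1", target="T1", *, rel_type="D", conf=9, organism="human",
         measure=MeasureType.KI, relation=Relation.EXACT, value=100.0,
         smiles="CCO"):
    return ActivityRecord(
        compound_id=cid, structure=smiles, target_id=target,
        organism=organism, relationship_type=rel_type, confidence_score=conf,
        measure_type=measure, relation=relation, value_nM=value,
    )


class TestSelectRecords:
    def test_fully_compliant_record_is_kept(self):
        kept, report = select_records([_rec()], CurationCriteria())
        assert len(kept) == 1 and not report.records

    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            ({"rel_type": "H"}, "wrong_relationship_type"),
            ({"conf": 8}, "low_confidence"),
            ({"organism": "rat"}, "wrong_organism"),
            ({"measure": MeasureType.OTHER}, "wrong_measure_type"),
            ({"relation": Relation.GREATER}, "non_exact_relation"),
            ({"relation": Relation.APPROX}, "non_exact_relation"),
        ],
    )
    def test_each_violated_criterion_counts_under_its_reason(self, kwargs, reason):
        kept, report = select_records([_rec(**kwargs)], CurationCriteria())
        assert kept == [] and report.records == {reason: 1}

    def test_empty_input_gives_empty_output_and_zero_counters(self):
        kept, report = select_records([], CurationCriteria())
        assert kept == [] and sum(report.records.values()) == 0

    def test_selection_is_idempotent(self):
        records = [_rec(), _rec(conf=3), _rec(cid="C2"), _rec(organism="rat")]
        once, _ = select_records(records, CurationCriteria())
        twice, report = select_records(once, CurationCriteria())
        assert twice == once and not report.records


class TestCanonicalKey:
    @pytest.mark.parametrize(
        "a, b",
        [
            ("CCO", "OCC"),                                # atom ordering
            ("CCO.Cl", "CCO"),                             # salt stripping
            ("CCO.O", "CCO"),                              # solvent stripping
            ("C[C@H](N)C(=O)O", "CC(N)C(=O)O"),            # stereo removal
            ("[13CH3]CO", "CCO"),                          # isotope clearing
            ("CC(=O)[O-]", "CC(=O)O"),                     # acid neutralization
            ("CC[NH3+].[Cl-]", "CCN"),                     # base neutralization
        ],
    )
    def test_equivalent_inputs_share_one_key(self, a, b):
        assert canonical_key(a) == canonical_key(b)

    def test_distinct_parents_have_distinct_keys(self):
        assert canonical_key("CCO") != canonical_key("CCCO")

    def test_unparseable_structure_raises(self):
        with pytest.raises(StructureError):
            canonical_key("not_a_smiles(((")


class TestAggregatePotency:
    def test_singleton_is_identity(self):
        assert aggregate_potency([100.0]) == pytest.approx(100.0)

    def test_geometric_mean_within_one_order(self):
        # sqrt(20 * 50) = sqrt(1000); ratio 2.5 < 10 so the value is kept
        assert aggregate_potency([20.0, 50.0]) == pytest.approx(31.6228, abs=1e-2)
        assert aggregate_potency([10.0, 20.0, 40.0]) == pytest.approx(20.0)

    def test_order_of_magnitude_boundary_is_a_conflict(self):
        # ratio exactly 10 is NOT "within the same order of magnitude"
        assert aggregate_potency([10.0, 100.0]) is CONFLICT
        assert aggregate_potency([10.0, 99.0]) is not CONFLICT

    def test_non_positive_value_is_a_hard_error(self):
        with pytest.raises(ValueError):
            aggregate_potency([10.0, -1.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 9.0), min_size=1, max_size=6),
        scale=st.floats(0.01, 1e6),
    )
    def test_scale_equivariance_and_permutation_invariance(self, values, scale):
        base = aggregate_potency(values)
        assert base is not CONFLICT
        assert aggregate_potency(sorted(values, reverse=True)) == pytest.approx(base)
        assert aggregate_potency([v * scale for v in values]) == pytest.approx(
            base * scale, rel=1e-9
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(0.1, 1e6), n=st.integers(1, 8))
    def test_mean_of_n_copies_is_x(self, x, n):
        assert aggregate_potency([x] * n) == pytest.approx(x)

    def test_result_bounded_by_input_range(self):
        v = aggregate_potency([5.0, 7.0, 30.0])
        assert 5.0 <= v <= 30.0


def _info(cid, key, members=None):
    return CompoundInfo(compound_id=cid, canonical_key=key,
                        member_ids=frozenset(members or {cid}))


class TestFlagCompounds:
    QUINONE = "O=C1C=CC(=O)C=C1"

    def test_empty_pattern_list_flags_nothing(self):
        out = flag_compounds({"C1": _info("C1", "CCO")}, [], [])
        assert out["C1"].flags == frozenset()

    def test_aggregator_membership_by_id(self):
        out = flag_compounds({"C1": _info("C1", "CCO")}, [], ["C1"])
        assert out["C1"].flags == {"aggregator"}

    def test_exactly_the_quinone_bearing_compound_is_flagged(self):
        compounds = {
            f"C{i}": _info(f"C{i}", smi)
            for i, smi in enumerate(
                ["CCO", "CCN", "CC1=CC(=O)C=CC1=O", "c1ccccc1", "CCCC"]
            )
        }
        out = flag_compounds(compounds, [self.QUINONE], [])
        flagged = [c for c, info in out.items() if "interference" in info.flags]
        assert flagged == ["C2"]


class TestExcludeAntitargets:
    INFO = {
        "T1": TargetInfo(target_id="T1", family="GPCR"),
        "HERG": TargetInfo(target_id="HERG", family="hERG", is_antitarget=True),
        "CYP": TargetInfo(target_id="CYP", family="CYP450", is_antitarget=True),
    }

    def _ann(self, cid, target):
        return PotencyAnnotation(compound_id=cid, target_id=target,
                                 measure_type=MeasureType.KI, potency_nM=10.0)

    def test_compound_active_on_antitarget_is_fully_removed(self):
        anns = [self._ann("C1", "HERG"), self._ann("C1", "T1")]
        kept, removed = exclude_antitargets(anns, self.INFO)
        assert kept == [] and removed == {"C1"}

    def test_no_antitargets_is_identity(self):
        anns = [self._ann("C1", "T1"), self._ann("C2", "T1")]
        kept, removed = exclude_antitargets(anns, self.INFO)
        assert kept == anns and not removed

    def test_only_the_cyp_active_compound_is_dropped(self):
        anns = [self._ann("C1", "T1"), self._ann("C2", "T1"),
                self._ann("C3", "T1"), self._ann("C3", "CYP")]
        kept, removed = exclude_antitargets(anns, self.INFO)
        assert {a.compound_id for a in kept} == {"C1", "C2"}
        assert removed == {"C3"}


class TestFullCuration:
    TARGETS = {
        "T1": TargetInfo(target_id="T1", family="GPCR"),
        "T2": TargetInfo(target_id="T2", family="Kinase"),
    }

    def test_no_potency_cutoff_keeps_millimolar_actives(self):
        # a 1 mM-only compound survives curation and can still form pairs
        anns, _, _ = curate([_rec(value=1e6)], self.TARGETS)
        assert len(anns) == 1 and anns[0].potency_nM == pytest.approx(1e6)

    def test_salt_and_parent_records_merge_into_one_entity(self):
        records = [_rec(cid="C_salt", smiles="CCO.Cl", value=100.0),
                   _rec(cid="C_base", smiles="OCC", value=200.0)]
        anns, compounds, _ = curate(records, self.TARGETS)
        assert len(anns) == 1
        assert anns[0].compound_id == "C_base"  # lexicographically smallest
        assert anns[0].n_measurements == 2
        assert compounds["C_base"].member_ids == {"C_salt", "C_base"}

    def test_ki_and_ic50_are_never_pooled(self):
        records = [_rec(value=10.0, measure=MeasureType.KI),
                   _rec(value=1000.0, measure=MeasureType.IC50)]
        anns, _, report = curate(records, self.TARGETS)
        # pooling would be an order-of-magnitude conflict; separately both live
        assert len(anns) == 2
        assert report.records["order_of_magnitude_conflict"] == 0

    def test_conflicting_measurements_are_disregarded_and_counted(self):
        records = [_rec(value=10.0), _rec(value=500.0)]
        anns, _, report = curate(records, self.TARGETS)
        assert anns == []
        assert report.records["order_of_magnitude_conflict"] == 2

    def test_unparseable_structures_counted_per_record(self):
        records = [_rec(), _rec(cid="C2", smiles="))bad((")]
        anns, _, report = curate(records, self.TARGETS)
        assert len(anns) == 1
        assert report.records["unparseable_structure"] == 1

    def test_every_rejected_record_increments_exactly_one_counter(self):
        records = [_rec(), _rec(cid="C2", conf=2), _rec(cid="C3", rel_type="H"),
                   _rec(cid="C4", relation=Relation.LESS)]
        _, _, report = curate(records, self.TARGETS)
        assert sum(report.records.values()) == 3
        assert report.compounds_out <= report.compounds_in
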