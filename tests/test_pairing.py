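import random

import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from ligandlink import (
    CurationCriteria,
    IdentityResult,
    MeasureType,
    PotencyAnnotation,
    TargetInfo,
    annotate_drugs,
    compute_identity,
    enumerate_family_pairs,
    enumerate_sequence_diverse_pairs,
    form_pairs,
    intersect_and_finalize,
    is_sequence_diverse,
    new_pairs,
)
from ligandlink.datamodel import FAMILY_BASED, SEQUENCE_BASED, TargetPair, pair_key
from ligandlink.pairing import align_score

from oracles import all_pairs, brute_force_pairs, gotoh_tuple_dp

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


class TestComputeIdentity:
    def test_self_identity_is_total(self):
        rng = random.Random(1)
        seq = _random_seq(rng, 50)
        res = compute_identity(seq, seq)
        assert res.pct_identity == 100.0
        assert res.n_identical == 50
        assert res.alignment_length == 50

    def test_disjoint_alphabets_share_nothing(self):
        res = compute_identity("AAAA", "WWWW")
        assert res.n_identical == 0 and res.pct_identity == 0.0

    def test_empty_sequence_is_hard_error(self):
        with pytest.raises(ValueError):
            compute_identity("", "MKV")

    def test_symmetry_on_random_pairs(self):
        rng = random.Random(2)
        for _ in range(20):
            a = _random_seq(rng, rng.randint(10, 80))
            b = _random_seq(rng, rng.randint(10, 80))
            assert compute_identity(a, b) == compute_identity(b, a)

    def test_matches_tuple_dp_oracle_on_random_pairs(self):
        """Score and max-identity agree with an independent exhaustive DP."""
        rng = random.Random(3)
        for _ in range(50):
            a = _random_seq(rng, rng.randint(5, 60))
            b = _random_seq(rng, rng.randint(5, 60))
            score, ident = gotoh_tuple_dp(a, b)
            res = compute_identity(a, b)
            assert align_score(a, b) == pytest.approx(score)
            assert res.n_identical == ident

    def test_score_matches_biopython_global_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.5  # first gap residue: open 10 + extend 0.5
        aligner.extend_gap_score = -0.5
        rng = random.Random(4)
        for _ in range(20):
            a = _random_seq(rng, rng.randint(20, 120))
            b = _random_seq(rng, rng.randint(20, 120))
            assert align_score(a, b) == pytest.approx(aligner.score(a, b))


class TestSequenceDiverseRule:
    @pytest.mark.parametrize(
        "pct, n_ident, kept",
        [
            (25.0, 10, False),  # identity above 20% -> removed
            (15.0, 35, False),  # 30+ identical residues -> removed
            (15.0, 30, False),  # boundary: "at least 30" removes
            (15.0, 20, True),   # diverse
            (20.0, 29, True),   # boundary: exactly 20% is not "> 20%"
        ],
    )
    def test_removal_rule(self, pct, n_ident, kept):
        res = IdentityResult(pct_identity=pct, n_identical=n_ident,
                             alignment_length=200)
        assert is_sequence_diverse(res, CurationCriteria()) is kept


def _target(tid, family="GPCR", seq=""):
    return TargetInfo(target_id=tid, family=family, sequence=seq)


class TestEnumerateFamilyPairs:
    def test_same_family_pairs_are_excluded(self):
        targets = [_target("A", "GPCR"), _target("B", "GPCR"),
                   _target("C", "Kinase")]
        assert enumerate_family_pairs(targets) == {("A", "C"), ("B", "C")}

    def test_single_family_yields_nothing(self):
        targets = [_target(t, "GPCR") for t in "ABCD"]
        assert enumerate_family_pairs(targets) == set()

    def test_distinct_families_give_complete_graph(self):
        targets = [_target(f"T{i}", f"F{i}") for i in range(6)]
        assert len(enumerate_family_pairs(targets)) == 15

    def test_unassigned_targets_are_excluded_from_this_protocol(self):
        targets = [_target("A", "GPCR"), _target("B")]  # B unassigned
        assert enumerate_family_pairs(targets) == set()


class TestEnumerateSequenceDiversePairs:
    def test_duplicate_sequence_under_new_id_is_removed(self):
        rng = random.Random(5)
        seq = _random_seq(rng, 100)
        targets = [_target("A", seq=seq), _target("B", seq=seq)]
        assert enumerate_sequence_diverse_pairs(targets) == set()

    def test_unrelated_random_sequences_are_kept(self):
        rng = random.Random(6)
        targets = [_target("A", seq=_random_seq(rng, 80)),
                   _target("B", seq=_random_seq(rng, 80))]
        assert enumerate_sequence_diverse_pairs(targets) == {("A", "B")}

    def test_one_similar_pair_among_five_targets_removes_one_of_ten(self):
        # disjoint residue alphabets make cross-pairs 0% identical for sure
        seqs = ["ACDE" * 20, "FGHI" * 20, "KLMN" * 20, "PQRS" * 20]
        seqs.append(seqs[0])  # the fifth duplicates the first
        targets = [_target(f"T{i}", seq=s) for i, s in enumerate(seqs)]
        kept = enumerate_sequence_diverse_pairs(targets)
        assert len(kept) == 9 and ("T0", "T4") not in kept


def _ann(cid, target):
    return PotencyAnnotation(compound_id=cid, target_id=target,
                             measure_type=MeasureType.KI, potency_nM=50.0)


def _random_instance(rng, n_targets=15, n_compounds=60, p=0.08):
    targets = [f"T{i:02d}" for i in range(n_targets)]
    anns = [
        _ann(f"C{c:02d}", t)
        for c in range(n_compounds)
        for t in targets
        if rng.random() < p
    ]
    return targets, anns


class TestFormPairs:
    def test_two_shared_compounds_never_emit_three_always(self):
        candidates = {("T1", "T2")}
        anns2 = [_ann(c, t) for c in ("C1", "C2") for t in ("T1", "T2")]
        assert form_pairs(anns2, candidates) == []
        anns3 = anns2 + [_ann("C3", "T1"), _ann("C3", "T2")]
        pairs = form_pairs(anns3, candidates)
        assert len(pairs) == 1 and pairs[0].n_shared == 3

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = random.Random(8)
        for _ in range(30):
            targets, anns = _random_instance(rng)
            candidates = all_pairs(targets)
            got = {p.key: p.shared_compounds for p in form_pairs(anns, candidates)}
            assert got == brute_force_pairs(anns, candidates, 3)

    def test_result_is_independent_of_annotation_order(self):
        rng = random.Random(9)
        targets, anns = _random_instance(rng)
        candidates = all_pairs(targets)
        shuffled = anns[:]
        rng.shuffle(shuffled)
        assert form_pairs(anns, candidates) == form_pairs(shuffled, candidates)

    def test_monotonicity_in_min_shared_and_annotations(self):
        rng = random.Random(10)
        targets, anns = _random_instance(rng)
        candidates = all_pairs(targets)
        for k in (5, 4, 3, 2, 1):
            crit = CurationCriteria(min_shared_compounds=k)
            n_k = len(form_pairs(anns, candidates, crit))
            crit_up = CurationCriteria(min_shared_compounds=k + 1)
            assert n_k >= len(form_pairs(anns, candidates, crit_up))
        keys = {p.key for p in form_pairs(anns, candidates)}
        more = anns + [_ann("C99", "T00")]
        assert keys <= {p.key for p in form_pairs(more, candidates)}


def _pair(a, b, compounds, origin=FAMILY_BASED):
    return TargetPair(*pair_key(a, b), shared_compounds=frozenset(compounds),
                      origin=frozenset({origin}))


class TestIntersectAndFinalize:
    def test_disjoint_sets_intersect_to_nothing(self):
        fam = [_pair("A", "B", {"C1", "C2", "C3"})]
        seq = [_pair("C", "D", {"C1", "C2", "C3"}, SEQUENCE_BASED)]
        assert intersect_and_finalize(fam, seq) == []

    def test_identical_sets_keep_everything_with_both_origins(self):
        fam = [_pair("A", "B", {"C1", "C2", "C3"}),
               _pair("A", "C", {"C4", "C5", "C6"})]
        seq = [_pair(p.target_a, p.target_b, p.shared_compounds, SEQUENCE_BASED)
               for p in fam]
        final = intersect_and_finalize(fam, seq)
        assert len(final) == 2
        assert all(p.origin == {FAMILY_BASED, SEQUENCE_BASED} for p in final)

    def test_reported_pairs_are_excluded_from_the_new_set(self):
        # 6 family pairs, 5 sequence pairs, overlap 4, 1 reported -> 3 new
        fam = [_pair("A", f"B{i}", {"C1", "C2", "C3"}) for i in range(6)]
        seq = [_pair(p.target_a, p.target_b, p.shared_compounds, SEQUENCE_BASED)
               for p in fam[:4]] + [_pair("X", "Y", {"C7", "C8", "C9"},
                                          SEQUENCE_BASED)]
        final = intersect_and_finalize(fam, seq, reported_pairs={("A", "B0")})
        assert len(final) == 4
        novel = new_pairs(final)
        assert len(novel) == 3 and ("A", "B0") not in [p.key for p in novel]

    def test_final_is_subset_of_both_protocols(self):
        rng = random.Random(11)
        targets, anns = _random_instance(rng)
        half1 = {p for p in all_pairs(targets) if rng.random() < 0.7}
        half2 = {p for p in all_pairs(targets) if rng.random() < 0.7}
        fam = form_pairs(anns, half1, origin=FAMILY_BASED)
        seq = form_pairs(anns, half2, origin=SEQUENCE_BASED)
        final = {p.key for p in intersect_and_finalize(fam, seq)}
        assert final <= {p.key for p in fam} and final <= {p.key for p in seq}


class TestAnnotateDrugs:
    def test_no_drugs_gives_zero_counts(self):
        pairs, tally = annotate_drugs([_pair("A", "B", {"C1", "C2", "C3"})], [])
        assert pairs[0].n_drugs == 0 and tally == 0

    def test_one_drug_shared_by_two_pairs_tallies_once(self):
        pairs = [_pair("A", "B", {"C1", "C2", "C3"}),
                 _pair("A", "C", {"C1", "C4", "C5"})]
        out, tally = annotate_drugs(pairs, {"C1"})
        assert [p.n_drugs for p in out] == [1, 1] and tally == 1

    def test_per_pair_count_is_intersection_size(self):
        shared = {f"C{i}" for i in range(10)}
        out, tally = annotate_drugs([_pair("A", "B", shared)],
                                    {"C0", "C1", "C2", "C77"})
        assert out[0].n_drugs == 3 and tally == 3
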