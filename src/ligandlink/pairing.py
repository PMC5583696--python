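"""Target selection protocols and compound-based pair formation.

Two protocols run in parallel. Family-based selection keeps all pairs of
targets from *different* families (same-family pairs are never considered).
Sequence-based selection enumerates all target pairs and removes
sequence-similar ones: identity > 20% or at least 30 identical residues in a
global alignment. Pairs sharing at least three curated active compounds are
formed under each protocol, and the intersection of the two pair sets —
targets that are both cross-family and sequence-diverse, i.e. distantly
related or unrelated — is the final relationship set.

Identity is computed with an affine-gap global alignment (Gotoh algorithm,
BLOSUM62, gap open 10 / extend 0.5) that, among all score-optimal
alignments, maximises the number of identical aligned residues. That makes
the identity count a well-defined function of the two sequences (no
dependence on traceback tie-breaking) and is the conservative choice for a
removal filter. The percent denominator is the shorter sequence's length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .datamodel import (
    FAMILY_BASED,
    SEQUENCE_BASED,
    UNASSIGNED,
    CurationCriteria,
    IdentityResult,
    PotencyAnnotation,
    TargetInfo,
    TargetPair,
    pair_key,
)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for the pairwise identity alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@lru_cache(maxsize=4)
def _doubled_matrix(name: str) -> np.ndarray:
    """Substitution scores doubled to integers, indexed by ord(aa) - 65."""
    mat = substitution_matrices.load(name)
    out = np.full((26, 26), -2 * 8, dtype=np.int64)  # unseen letters: harsh
    for a in mat.alphabet:
        for b in mat.alphabet:
            if a.isalpha() and b.isalpha():
                out[ord(a) - 65, ord(b) - 65] = int(round(2 * mat[a, b]))
    return out


_NEG = -(1 << 40)


@njit(cache=True)
def _gotoh(a, b, sub2, open2, ext2):  # pragma: no cover - compiled
    """Affine-gap global alignment maximising (score, n_identical) lexically.

    Scores are doubled integers so half-point gap extensions stay exact.
    Returns (doubled score, identical residues, alignment length).
    """
    n, m = a.shape[0], b.shape[0]
    # state 0: a_i ~ b_j, state 1: a_i ~ gap, state 2: gap ~ b_j
    sc = np.full((3, n + 1, m + 1), _NEG, dtype=np.int64)
    ident = np.zeros((3, n + 1, m + 1), dtype=np.int64)
    length = np.zeros((3, n + 1, m + 1), dtype=np.int64)
    sc[0, 0, 0] = 0
    for i in range(1, n + 1):
        sc[1, i, 0] = -open2 - i * ext2
        length[1, i, 0] = i
    for j in range(1, m + 1):
        sc[2, 0, j] = -open2 - j * ext2
        length[2, 0, j] = j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            # diagonal: best predecessor state at (i-1, j-1)
            best = 0
            for s in (1, 2):
                if sc[s, i - 1, j - 1] > sc[best, i - 1, j - 1] or (
                    sc[s, i - 1, j - 1] == sc[best, i - 1, j - 1]
                    and ident[s, i - 1, j - 1] > ident[best, i - 1, j - 1]
                ):
                    best = s
            sc[0, i, j] = sc[best, i - 1, j - 1] + sub2[ai, bj]
            ident[0, i, j] = ident[best, i - 1, j - 1] + (1 if ai == bj else 0)
            length[0, i, j] = length[best, i - 1, j - 1] + 1
            # gap in b (consume a_i): open from states 0/2, extend state 1
            s0 = sc[0, i - 1, j] - open2 - ext2
            s1 = sc[1, i - 1, j] - ext2
            s2 = sc[2, i - 1, j] - open2 - ext2
            best, bs = 0, s0
            if s1 > bs or (s1 == bs and ident[1, i - 1, j] > ident[best, i - 1, j]):
                best, bs = 1, s1
            if s2 > bs or (s2 == bs and ident[2, i - 1, j] > ident[best, i - 1, j]):
                best, bs = 2, s2
            sc[1, i, j] = bs
            ident[1, i, j] = ident[best, i - 1, j]
            length[1, i, j] = length[best, i - 1, j] + 1
            # gap in a (consume b_j)
            s0 = sc[0, i, j - 1] - open2 - ext2
            s1 = sc[2, i, j - 1] - ext2
            s2 = sc[1, i, j - 1] - open2 - ext2
            best, bs = 0, s0
            if s1 > bs or (s1 == bs and ident[2, i, j - 1] > ident[best, i, j - 1]):
                best, bs = 2, s1
            if s2 > bs or (s2 == bs and ident[1, i, j - 1] > ident[best, i, j - 1]):
                best, bs = 1, s2
            sc[2, i, j] = bs
            ident[2, i, j] = ident[best, i, j - 1]
            length[2, i, j] = length[best, i, j - 1] + 1
    best = 0
    for s in (1, 2):
        if sc[s, n, m] > sc[best, n, m] or (
            sc[s, n, m] == sc[best, n, m] and ident[s, n, m] > ident[best, n, m]
        ):
            best = s
    return sc[best, n, m], ident[best, n, m], length[best, n, m]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65


def align_score(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score under the identity scoring scheme."""
    params = params or AlignmentParams()
    sc2, _, _ = _gotoh(
        _encode(seq_a),
        _encode(seq_b),
        _doubled_matrix(params.matrix),
        int(round(2 * params.gap_open)),
        int(round(2 * params.gap_extend)),
    )
    return sc2 / 2.0


def compute_identity(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> IdentityResult:
    """Pairwise sequence identity from a global alignment.

    Symmetric in its arguments and deterministic under fixed parameters.
    ``n_identical`` counts aligned positions with equal residues, maximised
    over score-optimal alignments; ``pct_identity`` divides by the shorter
    sequence length.
    """
    if not seq_a or not seq_b:
        raise ValueError("compute_identity requires two non-empty sequences")
    params = params or AlignmentParams()
    if seq_b < seq_a:  # canonical argument order => exact symmetry
        seq_a, seq_b = seq_b, seq_a
    _, n_ident, aln_len = _gotoh(
        _encode(seq_a),
        _encode(seq_b),
        _doubled_matrix(params.matrix),
        int(round(2 * params.gap_open)),
        int(round(2 * params.gap_extend)),
    )
    denom = min(len(seq_a), len(seq_b))
    return IdentityResult(
        pct_identity=100.0 * n_ident / denom,
        n_identical=int(n_ident),
        alignment_length=int(aln_len),
    )


def is_sequence_diverse(res: IdentityResult, criteria: CurationCriteria) -> bool:
    """False (pair removed as similar) iff identity > 20% or >= 30 identical."""
    return not (
        res.pct_identity > criteria.max_identity_pct
        or res.n_identical >= criteria.max_identical_residues
    )


def enumerate_family_pairs(targets: Sequence[TargetInfo]) -> set[tuple[str, str]]:
    """All unordered pairs of targets from two *different* assigned families."""
    assigned = [t for t in targets if t.family != UNASSIGNED]
    return {
        pair_key(a.target_id, b.target_id)
        for a, b in itertools.combinations(assigned, 2)
        if a.family != b.family
    }


def enumerate_sequence_diverse_pairs(
    targets: Sequence[TargetInfo],
    criteria: CurationCriteria | None = None,
    params: AlignmentParams | None = None,
) -> set[tuple[str, str]]:
    """All unordered pairs minus the sequence-similar ones.

    Targets without a sequence are excluded from this protocol (the caller
    counts them).
    """
    criteria = criteria or CurationCriteria()
    with_seq = [t for t in targets if t.sequence]
    return {
        pair_key(a.target_id, b.target_id)
        for a, b in itertools.combinations(with_seq, 2)
        if is_sequence_diverse(
            compute_identity(a.sequence, b.sequence, params), criteria
        )
    }


def form_pairs(
    annotations: Iterable[PotencyAnnotation],
    candidate_pairs: Iterable[tuple[str, str]],
    criteria: CurationCriteria | None = None,
    *,
    origin: str = "",
) -> list[TargetPair]:
    """Form compound-based pairs from the candidates.

    For each candidate pair the shared compounds are those annotated against
    *both* targets (any measure type); the pair is emitted iff it shares at
    least ``criteria.min_shared_compounds`` (default three) compounds.
    Independent of annotation order.
    """
    criteria = criteria or CurationCriteria()
    actives: dict[str, set[str]] = {}
    for a in annotations:
        actives.setdefault(a.target_id, set()).add(a.compound_id)
    pairs: list[TargetPair] = []
    for a, b in sorted(pair_key(x, y) for x, y in candidate_pairs):
        shared = actives.get(a, set()) & actives.get(b, set())
        if len(shared) >= criteria.min_shared_compounds:
            pairs.append(
                TargetPair(
                    a,
                    b,
                    shared_compounds=frozenset(shared),
                    origin=frozenset({origin} if origin else ()),
                )
            )
    return pairs


def intersect_and_finalize(
    family_pairs: Sequence[TargetPair],
    sequence_pairs: Sequence[TargetPair],
    reported_pairs: Iterable[tuple[str, str]] = (),
) -> list[TargetPair]:
    """Intersect the two protocols' pair sets into the final relationships.

    A pair survives iff present in both sets (its origin becomes
    {family_based, sequence_based}); pairs found in ``reported_pairs`` are
    marked ``previously_reported`` so the novel set can exclude them.
    """
    reported = {pair_key(a, b) for a, b in reported_pairs}
    seq_by_key = {p.key: p for p in sequence_pairs}
    final: list[TargetPair] = []
    for fam in sorted(family_pairs, key=lambda p: p.key):
        seq = seq_by_key.get(fam.key)
        if seq is None:
            continue
        final.append(
            TargetPair(
                fam.target_a,
                fam.target_b,
                shared_compounds=fam.shared_compounds,
                origin=frozenset({FAMILY_BASED, SEQUENCE_BASED}),
                previously_reported=fam.key in reported,
            )
        )
    return final


def new_pairs(final: Iterable[TargetPair]) -> list[TargetPair]:
    """The previously unreported subset of the final pair set."""
    return [p for p in final if not p.previously_reported]


def annotate_drugs(
    pairs: Sequence[TargetPair], drug_ids: Iterable[str]
) -> tuple[list[TargetPair], int]:
    """Count approved drugs among each pair's shared compounds.

    Returns the pairs with ``n_drugs`` set, plus the global tally: the number
    of distinct drugs involved in any pair (union semantics).
    """
    drugs = set(drug_ids)
    out: list[TargetPair] = []
    involved: set[str] = set()
    for p in pairs:
        hit = p.shared_compounds & drugs
        involved |= hit
        out.append(
            TargetPair(
                p.target_a,
                p.target_b,
                shared_compounds=p.shared_compounds,
                origin=p.origin,
                n_drugs=len(hit),
                previously_reported=p.previously_reported,
            )
        )
    return out, len(involved)


def pair_summary(pairs: Sequence[TargetPair]) -> dict[str, int]:
    """Unique-compound and unique-target tallies over a pair set."""
    compounds: set[str] = set()
    targets: set[str] = set()
    for p in pairs:
        compounds |= p.shared_compounds
        targets |= {p.target_a, p.target_b}
    return {
        "n_pairs": len(pairs),
        "n_unique_compounds": len(compounds),
        "n_unique_targets": len(targets),
    }
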