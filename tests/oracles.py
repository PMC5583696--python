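"""Independent reference implementations used only by the tests.

Deliberately naive: a tuple-valued dynamic program for alignment identity,
a brute-force scan for pair formation, and a hand-rolled union-find for
connected components. None of these share code with the package.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_tuple_dp(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5):
    """Affine-gap global alignment maximizing (score, identical) lexically.

    Plain three-state DP over (score, n_identical) tuples; Python's tuple
    comparison gives the lexicographic maximum directly. Quadratic and slow,
    fine for sequences up to ~60 residues.
    """
    n, m = len(a), len(b)
    NEG = (float("-inf"), 0)
    first = gap_open + gap_extend  # cost of a gap's first residue
    # states: M (residue~residue), X (gap in b), Y (gap in a)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (-gap_open - i * gap_extend, 0)
    for j in range(1, m + 1):
        Y[0][j] = (-gap_open - j * gap_extend, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            ident = 1 if a[i - 1] == b[j - 1] else 0
            ps, pi = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (ps + s, pi + ident)
            X[i][j] = max(
                (M[i - 1][j][0] - first, M[i - 1][j][1]),
                (X[i - 1][j][0] - gap_extend, X[i - 1][j][1]),
                (Y[i - 1][j][0] - first, Y[i - 1][j][1]),
            )
            Y[i][j] = max(
                (M[i][j - 1][0] - first, M[i][j - 1][1]),
                (Y[i][j - 1][0] - gap_extend, Y[i][j - 1][1]),
                (X[i][j - 1][0] - first, X[i][j - 1][1]),
            )
    score, ident = max(M[n][m], X[n][m], Y[n][m])
    return score, ident


def brute_force_pairs(annotations, candidate_pairs, min_shared):
    """Scan every candidate pair and intersect compound sets naively."""
    result = {}
    for a, b in candidate_pairs:
        a, b = min(a, b), max(a, b)
        shared = {
            x.compound_id for x in annotations if x.target_id == a
        } & {x.compound_id for x in annotations if x.target_id == b}
        if len(shared) >= min_shared:
            result[(a, b)] = frozenset(shared)
    return result


def union_find_components(nodes, edges):
    """Connected components by naive union-find with path compression."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def all_pairs(ids):
    return {tuple(sorted(p)) for p in itertools.combinations(ids, 2)}
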