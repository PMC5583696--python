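"""Compound-based target network and descriptive statistics.

Targets are nodes, connected by an edge when they share active compounds.
The statistics mirror the standard read-outs of a pair-mining study: how
many compounds establish each link (frequency bins), which families the
paired targets come from, which family combinations occur, and what
therapeutic / disease / pathway information is already on record for the
paired targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .datamodel import UNASSIGNED, TargetPair

log = logging.getLogger(__name__)

#: Shared-compound frequency bins: [3, 9], [10, 19], [20, 49], [50, inf).
BIN_LABELS = ("3-9", "10-19", "20-49", ">=50")
BIN_EDGES = ((3, 9), (10, 19), (20, 49), (50, None))

#: Enzyme sub-families merged into one family for the coarse network view.
ENZYME_FAMILIES = frozenset(
    {"Hydrolase", "Oxidoreductase", "Transferase", "Lyase", "Isomerase",
     "Ligase", "Protease", "Phosphatase", "Kinase"}
)


@dataclass
class TargetNetwork:
    """Targets as nodes, compound-sharing relationships as edges."""

    graph: nx.Graph
    degree: dict[str, int] = field(default_factory=dict)
    components: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class FrequencyBins:
    """Pair counts per shared-compound bin, with integer percentages."""

    counts: dict[str, int]
    percentages: dict[str, int]
    total: int


@dataclass
class AnnotationCoverage:
    """Percentage of pairs with prior functional/therapeutic information.

    A pair is therapeutic iff *both* targets are designated therapeutic
    targets; disease- (pathway-) related iff the two targets' disease
    (pathway) sets intersect, i.e. both are implicated in the same disease
    or pathway. Percentages carry one decimal place.
    """

    pct_therapeutic: float
    pct_disease: float
    pct_pathway: float
    pct_disease_and_pathway: float


def build_network(
    pairs: Sequence[TargetPair], families: Mapping[str, str] | None = None
) -> TargetNetwork:
    """One node per distinct paired target, one edge per pair."""
    families = families or {}
    g = nx.Graph()
    for p in pairs:
        for t in (p.target_a, p.target_b):
            if t not in g:
                g.add_node(t, family=families.get(t, UNASSIGNED))
        g.add_edge(p.target_a, p.target_b, n_shared=p.n_shared, n_drugs=p.n_drugs)
    return TargetNetwork(
        graph=g,
        degree=dict(g.degree()),
        components=[frozenset(c) for c in nx.connected_components(g)],
    )


def shared_count_bin(n_shared: int) -> str:
    for label, (lo, hi) in zip(BIN_LABELS, BIN_EDGES):
        if n_shared >= lo and (hi is None or n_shared <= hi):
            return label
    raise ValueError(f"n_shared = {n_shared} below the minimum bin")


def frequency_bins(pairs: Sequence[TargetPair]) -> FrequencyBins:
    """Distribution of pairs over shared-compound frequency bins."""
    counts = {label: 0 for label in BIN_LABELS}
    for p in pairs:
        counts[shared_count_bin(p.n_shared)] += 1
    total = len(pairs)
    if total == 0:
        log.warning("frequency_bins: empty pair list, percentages reported as 0")
        pct = {label: 0 for label in BIN_LABELS}
    else:
        pct = {label: round(100 * c / total) for label, c in counts.items()}
    return FrequencyBins(counts=counts, percentages=pct, total=total)


def family_matrix(
    pairs: Sequence[TargetPair], families: Mapping[str, str]
) -> dict[tuple[str, str], int]:
    """Pair counts per unordered family combination; values sum to |pairs|."""
    counts: dict[tuple[str, str], int] = {}
    for p in pairs:
        fa = families.get(p.target_a, UNASSIGNED)
        fb = families.get(p.target_b, UNASSIGNED)
        cell = (fa, fb) if fa <= fb else (fb, fa)
        counts[cell] = counts.get(cell, 0) + 1
    return counts


def family_matrix_frame(
    pairs: Sequence[TargetPair], families: Mapping[str, str]
) -> pd.DataFrame:
    """Symmetric family-combination matrix as a DataFrame."""
    counts = family_matrix(pairs, families)
    labels = sorted({f for cell in counts for f in cell})
    df = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for (fa, fb), n in counts.items():
        df.loc[fa, fb] += n
        if fa != fb:
            df.loc[fb, fa] += n
    return df


def target_family_distribution(
    pairs: Sequence[TargetPair],
    families: Mapping[str, str],
    *,
    merge_enzymes: bool = False,
) -> dict[str, int]:
    """Distinct paired targets per family (each target counted once).

    With ``merge_enzymes`` the enzyme sub-families are combined into one
    'Enzyme' family, the coarse grouping used for network colouring.
    """
    targets: set[str] = set()
    for p in pairs:
        targets |= {p.target_a, p.target_b}
    dist: dict[str, int] = {}
    for t in sorted(targets):
        fam = families.get(t, UNASSIGNED)
        if merge_enzymes and fam in ENZYME_FAMILIES:
            fam = "Enzyme"
        dist[fam] = dist.get(fam, 0) + 1
    return dist


def annotation_coverage(
    pairs: Sequence[TargetPair],
    therapeutic_ids: Iterable[str],
    disease_map: Mapping[str, set[str]],
    pathway_map: Mapping[str, set[str]],
) -> AnnotationCoverage:
    """Fraction of pairs with prior therapeutic/disease/pathway knowledge."""
    therapeutic = set(therapeutic_ids)
    n = len(pairs)
    if n == 0:
        return AnnotationCoverage(0.0, 0.0, 0.0, 0.0)
    n_ther = n_dis = n_path = n_both = 0
    for p in pairs:
        a, b = p.target_a, p.target_b
        if a in therapeutic and b in therapeutic:
            n_ther += 1
        dis = bool(disease_map.get(a, set()) & disease_map.get(b, set()))
        path = bool(pathway_map.get(a, set()) & pathway_map.get(b, set()))
        n_dis += dis
        n_path += path
        n_both += dis and path
    pct = lambda k: round(100.0 * k / n, 1)
    return AnnotationCoverage(
        pct_therapeutic=pct(n_ther),
        pct_disease=pct(n_dis),
        pct_pathway=pct(n_path),
        pct_disease_and_pathway=pct(n_both),
    )


def network_stats(
    pairs: Sequence[TargetPair],
    families: Mapping[str, str],
    *,
    therapeutic_ids: Iterable[str] = (),
    disease_map: Mapping[str, set[str]] | None = None,
    pathway_map: Mapping[str, set[str]] | None = None,
) -> dict:
    """All descriptive statistics for a final pair set, JSON-serialisable."""
    net = build_network(pairs, families)
    bins = frequency_bins(pairs)
    cov = annotation_coverage(
        pairs, therapeutic_ids, disease_map or {}, pathway_map or {}
    )
    return {
        "n_pairs": len(pairs),
        "n_targets": net.n_nodes,
        "n_edges": net.n_edges,
        "n_components": len(net.components),
        "degree": dict(sorted(net.degree.items())),
        "frequency_bins": {"counts": bins.counts, "percentages": bins.percentages},
        "family_matrix": {
            f"{a}|{b}": n for (a, b), n in sorted(family_matrix(pairs, families).items())
        },
        "family_distribution": target_family_distribution(pairs, families),
        "family_distribution_merged_enzymes": target_family_distribution(
            pairs, families, merge_enzymes=True
        ),
        "coverage": {
            "pct_therapeutic": cov.pct_therapeutic,
            "pct_disease": cov.pct_disease,
            "pct_pathway": cov.pct_pathway,
            "pct_disease_and_pathway": cov.pct_disease_and_pathway,
        },
    }
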