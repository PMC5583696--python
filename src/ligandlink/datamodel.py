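"""Domain types shared by every pipeline stage.

The pipeline links pharmaceutical targets through the active compounds they
share: raw activity records are curated into potency annotations, targets are
paired under two parallel selection protocols (family-based and
sequence-based), and the intersection of the two pair sets becomes the final
set of compound-based target relationships.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, replace

UNASSIGNED = "UNASSIGNED"

#: The 20 standard amino acids plus 'X' (unknown residue).
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class MeasureType(str, enum.Enum):
    """Potency measurement class. Only Ki and IC50 survive curation."""

    KI = "Ki"
    IC50 = "IC50"
    OTHER = "other"


class Relation(str, enum.Enum):
    """Relation between the reported value and the true potency.

    Approximate measurements ('>', '<', '~') are parsed and retained so their
    later rejection is attributable; only exact values are curated.
    """

    EXACT = "exact"
    GREATER = "greater"
    LESS = "less"
    APPROX = "approx"


#: Mapping from relation symbols found in activity exports.
RELATION_SYMBOLS = {
    "=": Relation.EXACT,
    ">": Relation.GREATER,
    "<": Relation.LESS,
    "~": Relation.APPROX,
    "∼": Relation.APPROX,  # '∼' TILDE OPERATOR, as printed in exports
}


@dataclass(frozen=True)
class ActivityRecord:
    """One raw measurement linking a compound to a target."""

    compound_id: str
    structure: str
    target_id: str
    organism: str
    relationship_type: str
    confidence_score: int
    measure_type: MeasureType
    relation: Relation
    value_nM: float

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_score <= 9:
            raise ValueError(
                f"confidence_score must be in [0, 9], got {self.confidence_score}"
            )
        if self.relation is Relation.EXACT and not self.value_nM > 0:
            raise ValueError("exact potency values must be positive")


@dataclass(frozen=True)
class TargetInfo:
    """A target protein with its family label and sequence.

    ``family`` is :data:`UNASSIGNED` when the classification scheme does not
    cover the target; such targets are excluded from the family-based
    selection protocol only. ``sequence`` may be empty, excluding the target
    from the sequence-based protocol only.
    """

    target_id: str
    name: str = ""
    family: str = UNASSIGNED
    sequence: str = ""
    is_antitarget: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RESIDUE_ALPHABET
        if bad:
            raise ValueError(
                f"target {self.target_id}: non-residue characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class CompoundInfo:
    """A standardized compound entity.

    ``canonical_key`` identifies the parent structure after salt/solvent
    stripping, isotope and stereo removal and neutralization; input records
    whose structures differ only in those respects collapse onto one entity.
    ``member_ids`` are all raw compound ids that mapped onto this entity;
    ``compound_id`` is the lexicographically smallest member.
    """

    compound_id: str
    canonical_key: str
    flags: frozenset[str] = frozenset()
    is_drug: bool = False
    member_ids: frozenset[str] = frozenset()


@dataclass
class CurationCriteria:
    """Every numeric selection criterion of the mining protocol.

    Defaults reproduce the published rules: direct interactions ('D') with
    human targets at confidence 9, exact Ki/IC50 values only, multi-value
    potencies aggregated by geometric mean when they agree within one order
    of magnitude, pairs requiring at least three shared compounds, and
    sequence-similar pairs (identity > 20% or >= 30 identical residues)
    removed from the sequence-based protocol.
    """

    required_relationship_type: str = "D"
    required_confidence: int = 9
    allowed_measure_types: frozenset[MeasureType] = frozenset(
        {MeasureType.KI, MeasureType.IC50}
    )
    organism: str = "human"
    same_order_ratio: float = 10.0
    min_shared_compounds: int = 3
    max_identity_pct: float = 20.0
    max_identical_residues: int = 30

    def __post_init__(self) -> None:
        if self.same_order_ratio <= 0 or self.max_identity_pct <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_shared_compounds < 1:
            raise ValueError("min_shared_compounds must be >= 1")
        if self.max_identical_residues <= 0:
            raise ValueError("max_identical_residues must be strictly positive")
        if isinstance(self.allowed_measure_types, (set, list, tuple)):
            self.allowed_measure_types = frozenset(self.allowed_measure_types)

    def replace(self, **kwargs) -> "CurationCriteria":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PotencyAnnotation:
    """The curated potency of one compound against one target.

    ``potency_nM`` is the geometric mean of all exact-relation measurements
    of one measure type; Ki and IC50 are never pooled.
    """

    compound_id: str
    target_id: str
    measure_type: MeasureType
    potency_nM: float
    n_measurements: int = 1

    def __post_init__(self) -> None:
        if self.potency_nM <= 0:
            raise ValueError("potency must be positive")
        if self.n_measurements < 1:
            raise ValueError("n_measurements must be >= 1")


@dataclass
class ReadReport:
    """Bookkeeping of an activity-table read: nothing is silently dropped."""

    total_rows: int = 0
    parsed: int = 0
    rejections: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejections[reason] += 1

    @property
    def consistent(self) -> bool:
        return self.total_rows == self.parsed + sum(self.rejections.values())


@dataclass
class CurationReport:
    """Counters per rejection reason across the whole curation stage.

    ``records`` counts raw records rejected (each exactly once, under the
    first failing criterion); ``compounds`` counts compound entities removed
    wholesale (interference / aggregator / antitarget activity).
    """

    records: Counter = field(default_factory=Counter)
    compounds: Counter = field(default_factory=Counter)
    compounds_in: int = 0
    compounds_out: int = 0
    targets_in: int = 0
    targets_out: int = 0

    def as_dict(self) -> dict:
        return {
            "records": dict(self.records),
            "compounds": dict(self.compounds),
            "compounds_in": self.compounds_in,
            "compounds_out": self.compounds_out,
            "targets_in": self.targets_in,
            "targets_out": self.targets_out,
        }


FAMILY_BASED = "family_based"
SEQUENCE_BASED = "sequence_based"


@dataclass(frozen=True)
class TargetPair:
    """An unordered pair of targets linked by shared active compounds."""

    target_a: str
    target_b: str
    shared_compounds: frozenset[str]
    origin: frozenset[str] = frozenset()
    n_drugs: int = 0
    previously_reported: bool = False

    def __post_init__(self) -> None:
        if self.target_a >= self.target_b:
            raise ValueError(
                "pair must be canonically ordered with target_a < target_b"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.target_a, self.target_b)

    @property
    def n_shared(self) -> int:
        return len(self.shared_compounds)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) order for an unordered target pair."""
    if a == b:
        raise ValueError(f"a pair needs two distinct targets, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a pairwise global alignment.

    ``n_identical`` is the number of aligned positions carrying the same
    residue, maximised over all score-optimal alignments; ``pct_identity``
    uses the shorter sequence as denominator (the conservative choice: it
    yields the larger identity, erring toward removal of related pairs).
    """

    pct_identity: float
    n_identical: int
    alignment_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity out of [0, 100]")
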