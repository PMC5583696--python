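"""High-confidence selection, standardization and potency aggregation.

Raw activity records are filtered down to direct ('D') human interactions at
confidence 9 with exact Ki/IC50 values; structures are standardized onto a
canonical parent key; multiple measurements for one compound-target-measure
combination are aggregated by geometric mean when they agree within one order
of magnitude; interference (PAINS) and aggregator compounds are removed; and
antitargets — plus every compound active against one — are excluded. No
potency cutoff is applied anywhere: weak actives are legitimate pair formers.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .datamodel import (
    ActivityRecord,
    CompoundInfo,
    CurationCriteria,
    CurationReport,
    PotencyAnnotation,
    Relation,
    TargetInfo,
)

RDLogger.DisableLog("rdApp.*")

#: Sentinel: multi-value potency spanning an order of magnitude, disregarded.
CONFLICT = None


class StructureError(ValueError):
    """An unparseable compound structure."""


def select_records(
    records: Iterable[ActivityRecord], criteria: CurationCriteria
) -> tuple[list[ActivityRecord], CurationReport]:
    """Keep records satisfying every selection criterion.

    Each rejected record increments exactly one counter, under the first
    failing criterion in a fixed precedence; the *kept* set is the plain
    conjunction of the criteria and therefore order-independent.
    """
    kept: list[ActivityRecord] = []
    report = CurationReport()
    for rec in records:
        reason = _rejection_reason(rec, criteria)
        if reason is None:
            kept.append(rec)
        else:
            report.records[reason] += 1
    return kept, report


def _rejection_reason(rec: ActivityRecord, c: CurationCriteria) -> str | None:
    if rec.relationship_type != c.required_relationship_type:
        return "wrong_relationship_type"
    if rec.confidence_score < c.required_confidence:
        return "low_confidence"
    if rec.organism.lower() != c.organism.lower():
        return "wrong_organism"
    if rec.measure_type not in c.allowed_measure_types:
        return "wrong_measure_type"
    if rec.relation is not Relation.EXACT:
        return "non_exact_relation"
    return None


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def canonical_key(structure: str) -> str:
    """Standardize a SMILES onto its canonical parent key.

    Keeps the largest organic fragment (dropping salts and solvents), clears
    isotope labels, removes stereochemistry, neutralizes simple charged acids
    and bases, and emits RDKit's canonical aromatic SMILES. Deterministic and
    invariant under input atom ordering.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparseable structure: {structure!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    Chem.RemoveStereochemistry(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def aggregate_potency(
    values: Sequence[float], same_order_ratio: float = 10.0
) -> float | None:
    """Geometric mean of potency values, or :data:`CONFLICT`.

    All values must share one measure type (the caller never mixes Ki with
    IC50). If max/min < ``same_order_ratio`` the values agree within one
    order of magnitude and their geometric mean is returned; otherwise the
    annotation is disregarded (returns ``CONFLICT`` i.e. ``None``).
    """
    if not values:
        raise ValueError("aggregate_potency needs at least one value")
    if any(v <= 0 for v in values):
        raise ValueError("potency values must be positive")
    if max(values) / min(values) >= same_order_ratio:
        return CONFLICT
    return math.exp(sum(math.log(v) for v in values) / len(values))


def flag_compounds(
    compounds: Mapping[str, CompoundInfo],
    smarts_list: Sequence[str],
    aggregator_ids: Iterable[str],
) -> dict[str, CompoundInfo]:
    """Attach interference / aggregator flags to compound entities.

    A compound is flagged ``interference`` iff any pattern matches its parent
    structure, and ``aggregator`` iff any of its raw ids or its canonical key
    appears in the aggregator list. Flagged compounds are removed from all
    downstream stages by the caller.
    """
    aggregators = set(aggregator_ids)
    queries = [Chem.MolFromSmarts(s) for s in smarts_list]
    if any(q is None for q in queries):
        raise ValueError("malformed SMARTS pattern in interference list")
    flagged: dict[str, CompoundInfo] = {}
    for cid, info in compounds.items():
        flags = set(info.flags)
        if queries:
            mol = Chem.MolFromSmiles(info.canonical_key)
            if mol is not None and any(mol.HasSubstructMatch(q) for q in queries):
                flags.add("interference")
        if (
            info.canonical_key in aggregators
            or info.member_ids & aggregators
            or info.compound_id in aggregators
        ):
            flags.add("aggregator")
        flagged[cid] = CompoundInfo(
            compound_id=info.compound_id,
            canonical_key=info.canonical_key,
            flags=frozenset(flags),
            is_drug=info.is_drug,
            member_ids=info.member_ids,
        )
    return flagged


def exclude_antitargets(
    annotations: Iterable[PotencyAnnotation],
    target_info: Mapping[str, TargetInfo],
) -> tuple[list[PotencyAnnotation], set[str]]:
    """Drop antitarget annotations and every compound active against one.

    A compound with any antitarget activity (hERG, CYP450 families) is not
    considered at all: all of its annotations are removed, not just the
    antitarget ones. Returns the surviving annotations and the ids of the
    compounds removed.
    """
    annotations = list(annotations)
    tainted = {
        a.compound_id
        for a in annotations
        if (t := target_info.get(a.target_id)) is not None and t.is_antitarget
    }
    survivors = [
        a
        for a in annotations
        if a.compound_id not in tainted
        and not (
            (t := target_info.get(a.target_id)) is not None and t.is_antitarget
        )
    ]
    return survivors, tainted


def curate(
    records: Iterable[ActivityRecord],
    target_info: Mapping[str, TargetInfo],
    criteria: CurationCriteria | None = None,
    *,
    smarts_list: Sequence[str] = (),
    aggregator_ids: Iterable[str] = (),
) -> tuple[list[PotencyAnnotation], dict[str, CompoundInfo], CurationReport]:
    """Run the full curation stage on parsed activity records.

    Returns curated potency annotations (keyed by compound entity id and
    target), the surviving compound entities, and a report whose counters
    account for every rejected record and removed compound.
    """
    criteria = criteria or CurationCriteria()
    selected, report = select_records(records, criteria)

    # Standardize structures; merge raw compounds that share a parent key.
    key_of: dict[str, str] = {}
    bad_compounds: set[str] = set()
    for rec in selected:
        if rec.compound_id in key_of or rec.compound_id in bad_compounds:
            continue
        try:
            key_of[rec.compound_id] = canonical_key(rec.structure)
        except StructureError:
            bad_compounds.add(rec.compound_id)
    members: dict[str, set[str]] = defaultdict(set)
    for cid, key in key_of.items():
        members[key].add(cid)
    entity_of = {
        cid: min(ids) for key, ids in members.items() for cid in ids
    }
    usable: list[ActivityRecord] = []
    for rec in selected:
        if rec.compound_id in bad_compounds:
            report.records["unparseable_structure"] += 1
        else:
            usable.append(rec)

    report.compounds_in = len(set(entity_of.values()))
    report.targets_in = len({r.target_id for r in usable})

    # Aggregate potencies per compound entity, target and measure type.
    groups: dict[tuple[str, str, object], list[float]] = defaultdict(list)
    for rec in usable:
        groups[(entity_of[rec.compound_id], rec.target_id, rec.measure_type)].append(
            rec.value_nM
        )
    annotations: list[PotencyAnnotation] = []
    for (entity, target, measure), values in groups.items():
        mean = aggregate_potency(values, criteria.same_order_ratio)
        if mean is CONFLICT:
            report.records["order_of_magnitude_conflict"] += len(values)
        else:
            annotations.append(
                PotencyAnnotation(
                    compound_id=entity,
                    target_id=target,
                    measure_type=measure,
                    potency_nM=mean,
                    n_measurements=len(values),
                )
            )

    compounds = {
        min(ids): CompoundInfo(
            compound_id=min(ids),
            canonical_key=key,
            member_ids=frozenset(ids),
        )
        for key, ids in members.items()
    }
    compounds = flag_compounds(compounds, smarts_list, aggregator_ids)
    removed = {
        cid for cid, info in compounds.items() if info.flags
    }
    for cid in removed:
        for flag in sorted(compounds[cid].flags):
            report.compounds[f"{flag}_flagged"] += 1
    annotations = [a for a in annotations if a.compound_id not in removed]

    annotations, tainted = exclude_antitargets(annotations, target_info)
    report.compounds["antitarget"] += len(tainted)
    removed |= tainted

    surviving = {a.compound_id for a in annotations}
    compounds = {cid: info for cid, info in compounds.items() if cid in surviving}
    report.compounds_out = len(surviving)
    report.targets_out = len({a.target_id for a in annotations})
    return annotations, compounds, report
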