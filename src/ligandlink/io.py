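"""Readers and writers for the standard formats the pipeline touches.

Activity extracts are delimited tables (tab-separated by default) with a
required header; column names are configurable because exports vary between
tools. Sequences are FASTA, lookup tables are two-column TSV, filter lists
are one id/pattern per line, pair tables are TSV and networks are written as
GraphML plus a TSV edge list.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from Bio import SeqIO

from .datamodel import (
    RELATION_SYMBOLS,
    RESIDUE_ALPHABET,
    ActivityRecord,
    MeasureType,
    ReadReport,
    TargetPair,
    pair_key,
)

log = logging.getLogger(__name__)

#: Default column names of an activity table.
DEFAULT_COLUMNS: dict[str, str] = {
    "compound_id": "compound_id",
    "structure": "smiles",
    "target_id": "target_id",
    "organism": "organism",
    "relationship_type": "relationship_type",
    "confidence_score": "confidence_score",
    "measure_type": "measure_type",
    "relation": "relation",
    "value": "value",
}

#: Conversion factors from the declared input unit to nM.
UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}


class InputError(ValueError):
    """A malformed or missing input file (exit code 1 territory)."""


def read_activity_table(
    path: str | Path,
    *,
    delimiter: str = "\t",
    columns: Mapping[str, str] | None = None,
    unit: str = "nM",
) -> tuple[list[ActivityRecord], ReadReport]:
    """Parse an activity extract into records plus a read report.

    Rows with non-numeric values, unknown relation symbols or missing fields
    are counted per rejection reason, never silently dropped. Unknown measure
    types parse as :attr:`MeasureType.OTHER` (curation rejects them
    attributably). Values are converted to nM once, here.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if unit not in UNIT_TO_NM:
        raise InputError(f"unknown unit {unit!r}; expected one of {sorted(UNIT_TO_NM)}")
    factor = UNIT_TO_NM[unit]

    records: list[ActivityRecord] = []
    report = ReadReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return records, report  # empty file
        missing = [c for c in cols.values() if c not in reader.fieldnames]
        if missing:
            raise InputError(f"activity table {path} lacks required column(s): {missing}")
        for row in reader:
            report.total_rows += 1
            rec = _parse_row(row, cols, factor, report)
            if rec is not None:
                records.append(rec)
                report.parsed += 1
    return records, report


def _parse_row(row, cols, factor, report) -> ActivityRecord | None:
    vals = {field: (row.get(col) or "").strip() for field, col in cols.items()}
    if any(v == "" for v in vals.values()):
        report.reject("missing_field")
        return None
    relation = RELATION_SYMBOLS.get(vals["relation"])
    if relation is None:
        report.reject("bad_relation")
        return None
    try:
        value = float(vals["value"])
    except ValueError:
        report.reject("bad_value")
        return None
    if value <= 0:
        report.reject("bad_value")
        return None
    try:
        confidence = int(vals["confidence_score"])
    except ValueError:
        report.reject("bad_confidence")
        return None
    if not 0 <= confidence <= 9:
        report.reject("bad_confidence")
        return None
    try:
        measure = MeasureType(vals["measure_type"])
    except ValueError:
        measure = MeasureType.OTHER
    return ActivityRecord(
        compound_id=vals["compound_id"],
        structure=vals["structure"],
        target_id=vals["target_id"],
        organism=vals["organism"],
        relationship_type=vals["relationship_type"],
        confidence_score=confidence,
        measure_type=measure,
        relation=relation,
        value_nM=value * factor,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read amino-acid sequences keyed by record id (up to first whitespace).

    Sequences are upper-cased and validated against the 20 standard residues
    plus 'X'; duplicate ids or foreign characters are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in sequences:
            raise InputError(f"duplicate FASTA record id {rec.id!r} in {path}")
        bad = set(seq) - RESIDUE_ALPHABET
        if bad:
            raise InputError(
                f"FASTA record {rec.id!r}: non-residue characters {sorted(bad)}"
            )
        sequences[rec.id] = seq
    return sequences


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line and not line.startswith("#"):
                yield lineno, line


def read_family_map(path: str | Path, *, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (target id, family) table; '#' lines are comments."""
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split(delimiter)
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected two columns, got {line!r}")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line list; '#' lines are comments."""
    return {line.split("\t")[0].strip() for _, line in _data_lines(path)}


def read_smarts_list(path: str | Path) -> list[str]:
    """Read substructure patterns, one SMARTS per line, validating each."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    patterns: list[str] = []
    for lineno, line in _data_lines(path):
        smarts = line.split("\t")[0].strip()
        if Chem.MolFromSmarts(smarts) is None:
            raise InputError(f"{path}:{lineno}: malformed SMARTS pattern {smarts!r}")
        patterns.append(smarts)
    return patterns


PAIR_COLUMNS = [
    "target_a",
    "target_b",
    "n_shared",
    "origin",
    "n_drugs",
    "previously_reported",
    "compounds",
]


def write_pairs(pairs: Iterable[TargetPair], path: str | Path) -> None:
    """Write a pair table; compound ids are ';'-joined in sorted order."""
    rows = sorted(pairs, key=lambda p: p.key)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PAIR_COLUMNS)
        for p in rows:
            writer.writerow(
                [
                    p.target_a,
                    p.target_b,
                    p.n_shared,
                    ";".join(sorted(p.origin)),
                    p.n_drugs,
                    int(p.previously_reported),
                    ";".join(sorted(p.shared_compounds)),
                ]
            )


def read_pairs(path: str | Path) -> list[TargetPair]:
    """Read back a pair table written by :func:`write_pairs`."""
    pairs: list[TargetPair] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in PAIR_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise InputError(f"pair table {path} lacks column(s): {missing}")
        for row in reader:
            compounds = frozenset(filter(None, row["compounds"].split(";")))
            pairs.append(
                TargetPair(
                    *pair_key(row["target_a"], row["target_b"]),
                    shared_compounds=compounds,
                    origin=frozenset(filter(None, row["origin"].split(";"))),
                    n_drugs=int(row["n_drugs"]),
                    previously_reported=bool(int(row["previously_reported"])),
                )
            )
    return pairs


def write_network(net, graphml_path: str | Path, edgelist_path: str | Path) -> None:
    """Export a target network as GraphML plus a TSV edge list."""
    nx.write_graphml(net.graph, str(graphml_path))
    with open(edgelist_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["target_a", "target_b", "n_shared"])
        for a, b, data in sorted(net.graph.edges(data=True)):
            a, b = pair_key(a, b)
            writer.writerow([a, b, data.get("n_shared", "")])
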