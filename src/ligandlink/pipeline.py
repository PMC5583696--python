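"""End-to-end orchestration: curate -> pair -> network.

One configuration document drives the whole run; every selection threshold
defaults to the published mining rules, so a bare run on a fresh extract
reproduces them. The run is deterministic for fixed inputs and writes every
stage output plus a machine-readable summary of the flow counts.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .curation import curate
from .datamodel import (
    CurationCriteria,
    MeasureType,
    PotencyAnnotation,
    TargetInfo,
    UNASSIGNED,
    pair_key,
)
from .io import (
    InputError,
    read_activity_table,
    read_family_map,
    read_fasta,
    read_id_list,
    read_smarts_list,
    write_network,
    write_pairs,
)
from .network import build_network, network_stats
from .pairing import (
    AlignmentParams,
    annotate_drugs,
    enumerate_family_pairs,
    enumerate_sequence_diverse_pairs,
    form_pairs,
    intersect_and_finalize,
    new_pairs,
    pair_summary,
)
from .datamodel import FAMILY_BASED, SEQUENCE_BASED

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one mining run."""

    activities: str
    sequences: str | None = None
    families: str | None = None
    antitarget_families: str | None = None
    pains: str | None = None
    aggregators: str | None = None
    drugs: str | None = None
    known_pairs: str | None = None
    therapeutic: str | None = None
    disease_map: str | None = None
    pathway_map: str | None = None
    unit: str = "nM"
    columns: dict[str, str] = field(default_factory=dict)
    criteria: CurationCriteria = field(default_factory=CurationCriteria)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        inputs = doc.get("inputs", {})
        crit = dict(doc.get("criteria", {}))
        if "allowed_measure_types" in crit:
            crit["allowed_measure_types"] = frozenset(
                MeasureType(m) for m in crit["allowed_measure_types"]
            )
        align = doc.get("alignment", {})
        return cls(
            **inputs,
            unit=doc.get("unit", "nM"),
            columns=doc.get("columns", {}),
            criteria=CurationCriteria(**crit),
            alignment=AlignmentParams(**align),
            out_dir=doc.get("out_dir", "."),
        )

    def for_bundle(self, paths: Mapping[str, Path], out_dir: str | Path):
        """Point this config at the files of a written synthetic bundle."""
        return PipelineConfig(
            activities=str(paths["activities"]),
            sequences=str(paths["sequences"]),
            families=str(paths["families"]),
            antitarget_families=str(paths["antitarget_families"]),
            pains=str(paths["pains"]),
            aggregators=str(paths["aggregators"]),
            drugs=str(paths["drugs"]),
            known_pairs=str(paths["known_pairs"]),
            therapeutic=str(paths["therapeutic"]),
            disease_map=str(paths["disease_map"]),
            pathway_map=str(paths["pathway_map"]),
            unit=self.unit,
            columns=dict(self.columns),
            criteria=self.criteria,
            alignment=self.alignment,
            out_dir=str(out_dir),
        )


@dataclass
class RunSummary:
    """Flow counts of one pipeline run, serialisable as JSON."""

    read: dict
    curation: dict
    family_protocol: dict
    sequence_protocol: dict
    intersection: dict
    final: dict
    config_hash: str = ""
    version: str = __version__

    def as_dict(self) -> dict:
        return {
            "read": self.read,
            "curation": self.curation,
            "family_protocol": self.family_protocol,
            "sequence_protocol": self.sequence_protocol,
            "intersection": self.intersection,
            "final": self.final,
            "config_hash": self.config_hash,
            "version": self.version,
        }


def _config_hash(cfg: PipelineConfig) -> str:
    doc = {
        "unit": cfg.unit,
        "columns": cfg.columns,
        "criteria": {
            k: sorted(v) if isinstance(v, frozenset) else v
            for k, v in vars(cfg.criteria).items()
        },
        "alignment": vars(cfg.alignment),
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _read_annotation_map(path: str | None) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    if path:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tid, ann = line.split("\t")[:2]
                mapping.setdefault(tid, set()).add(ann)
    return mapping


def read_pair_keys(path: str | Path) -> set[tuple[str, str]]:
    """Two-column file of previously reported pairs."""
    keys: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            keys.add(pair_key(a, b))
    return keys


def write_annotations(annotations, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["compound_id", "target_id", "measure_type", "potency_nM",
             "n_measurements"]
        )
        for a in sorted(annotations, key=lambda a: (a.compound_id, a.target_id,
                                                    a.measure_type.value)):
            writer.writerow(
                [a.compound_id, a.target_id, a.measure_type.value,
                 f"{a.potency_nM:.6g}", a.n_measurements]
            )


def read_annotations(path: str | Path) -> list[PotencyAnnotation]:
    out: list[PotencyAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PotencyAnnotation(
                    compound_id=row["compound_id"],
                    target_id=row["target_id"],
                    measure_type=MeasureType(row["measure_type"]),
                    potency_nM=float(row["potency_nM"]),
                    n_measurements=int(row["n_measurements"]),
                )
            )
    return out


def build_target_info(
    record_targets: set[str],
    families: Mapping[str, str],
    sequences: Mapping[str, str],
    antitarget_families: set[str],
) -> dict[str, TargetInfo]:
    """Merge family map and sequences into per-target metadata."""
    info: dict[str, TargetInfo] = {}
    for tid in sorted(record_targets | set(families) | set(sequences)):
        fam = families.get(tid, UNASSIGNED)
        info[tid] = TargetInfo(
            target_id=tid,
            family=fam,
            sequence=sequences.get(tid, ""),
            is_antitarget=fam in antitarget_families,
        )
    return info


def run_pipeline(cfg: PipelineConfig) -> RunSummary:
    """Execute curate -> pair -> network and write all stage outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading activity table %s", cfg.activities)
    records, read_report = read_activity_table(
        cfg.activities, columns=cfg.columns, unit=cfg.unit
    )
    log.info("parsed %d of %d rows", read_report.parsed, read_report.total_rows)

    families = read_family_map(cfg.families) if cfg.families else {}
    sequences = read_fasta(cfg.sequences) if cfg.sequences else {}
    antitarget_families = (
        read_id_list(cfg.antitarget_families) if cfg.antitarget_families else set()
    )
    smarts = read_smarts_list(cfg.pains) if cfg.pains else []
    aggregators = read_id_list(cfg.aggregators) if cfg.aggregators else set()
    drugs = read_id_list(cfg.drugs) if cfg.drugs else set()
    known = read_pair_keys(cfg.known_pairs) if cfg.known_pairs else set()
    therapeutic = read_id_list(cfg.therapeutic) if cfg.therapeutic else set()
    disease_map = _read_annotation_map(cfg.disease_map)
    pathway_map = _read_annotation_map(cfg.pathway_map)

    target_info = build_target_info(
        {r.target_id for r in records}, families, sequences, antitarget_families
    )

    annotations, compounds, curation_report = curate(
        records, target_info, cfg.criteria,
        smarts_list=smarts, aggregator_ids=aggregators,
    )
    log.info(
        "curation: %d annotations, %d compounds, %d targets",
        len(annotations), curation_report.compounds_out,
        curation_report.targets_out,
    )
    write_annotations(annotations, out / "annotations.tsv")

    annotated = [target_info[t] for t in sorted({a.target_id for a in annotations})]
    fam_candidates = enumerate_family_pairs(annotated)
    seq_candidates = enumerate_sequence_diverse_pairs(
        annotated, cfg.criteria, cfg.alignment
    )
    family_pairs = form_pairs(annotations, fam_candidates, cfg.criteria,
                              origin=FAMILY_BASED)
    sequence_pairs = form_pairs(annotations, seq_candidates, cfg.criteria,
                                origin=SEQUENCE_BASED)
    log.info("family protocol: %d pairs; sequence protocol: %d pairs",
             len(family_pairs), len(sequence_pairs))

    final = intersect_and_finalize(family_pairs, sequence_pairs, known)
    # drug ids refer to raw compound ids; translate onto standardized entities
    entity_of = {
        member: info.compound_id
        for info in compounds.values()
        for member in info.member_ids
    }
    drug_entities = {entity_of[d] for d in drugs if d in entity_of}
    final, _ = annotate_drugs(final, drug_entities)
    novel = new_pairs(final)
    novel, n_drugs_involved = annotate_drugs(novel, drug_entities)
    log.info("intersection: %d pairs, %d previously reported, %d new",
             len(final), len(final) - len(novel), len(novel))

    write_pairs(family_pairs, out / "pairs_family.tsv")
    write_pairs(sequence_pairs, out / "pairs_sequence.tsv")
    write_pairs(final, out / "pairs_final.tsv")
    write_pairs(novel, out / "pairs_new.tsv")

    stats = network_stats(
        novel, families,
        therapeutic_ids=therapeutic,
        disease_map=disease_map,
        pathway_map=pathway_map,
    )
    net = build_network(novel, families)
    write_network(net, out / "network.graphml", out / "network_edges.tsv")
    with open(out / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats, fh, indent=1)
    with open(out / "curation_report.json", "w", encoding="utf-8") as fh:
        json.dump(curation_report.as_dict(), fh, indent=1)

    summary = RunSummary(
        read={
            "total_rows": read_report.total_rows,
            "parsed": read_report.parsed,
            "rejections": dict(read_report.rejections),
        },
        curation=curation_report.as_dict(),
        family_protocol={
            "n_candidate_pairs": len(fam_candidates),
            **pair_summary(family_pairs),
        },
        sequence_protocol={
            "n_candidate_pairs": len(seq_candidates),
            **pair_summary(sequence_pairs),
        },
        intersection={
            **pair_summary(final),
            "n_previously_reported": len(final) - len(novel),
        },
        final={
            **pair_summary(novel),
            "n_drugs_involved": n_drugs_involved,
            "stats": stats,
        },
        config_hash=_config_hash(cfg),
    )
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary.as_dict(), fh, indent=1)
    return summary
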