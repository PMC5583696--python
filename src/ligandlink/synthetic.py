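"""Synthetic activity extracts with known ground truth.

The generator emulates a public bioactivity-database export: planted
cross-family, sequence-diverse target pairs whose shared compounds carry
clean high-confidence records, surrounded by realistic nuisance — low
confidence scores, approximate relations ('>', '<', '~'), interference
(PAINS-matching) structures, aggregator ids, multi-measurement potency sets
a share of which straddle an order of magnitude, salt-decorated structures,
and antitarget (hERG) activity. Every nuisance class is planted as a *decoy
pair* whose records must be rejected, so recovery tests have teeth: the
pipeline must find exactly the planted pairs, nothing else.

Compound structures are simple generated valid SMILES (amide-linked alkyl
chains on a set of ring scaffolds); chemical realism is irrelevant to
pipeline correctness, uniqueness of the standardized parent key is what
matters and is verified at generation time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import TargetInfo, pair_key
from .pairing import AlignmentParams, compute_identity, is_sequence_diverse
from .datamodel import CurationCriteria

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

FAMILY_NAMES = [
    "GPCR", "Kinase", "Hydrolase", "Oxidoreductase", "Transporter",
    "TranscriptionFactor", "IonChannel", "NuclearReceptor", "Protease",
    "Transferase", "Lyase", "Isomerase",
]

ANTITARGET_FAMILY = "hERG"

#: Substructure written to the generated PAINS file; interference compounds
#: carry a matching quinone core.
QUINONE_SMARTS = "O=C1C=CC(=O)C=C1"

_RING_SCAFFOLDS = ["", "c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1ccoc1",
                   "c1ccsc1", "C1CCNCC1", "C1CCOCC1"]


class GenerationError(ValueError):
    """Inconsistent synthetic configuration."""


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    n_families: int = 8
    targets_per_family: int = 6
    within_family_identity: float = 0.8
    sequence_length: int = 120
    n_background_compounds: int = 120
    n_planted_pairs: int = 5
    shared_per_planted_pair: int = 6
    frac_low_confidence: float = 0.05
    frac_approx_relation: float = 0.05
    frac_interference: float = 0.02
    frac_aggregator: float = 0.02
    frac_multimeasure: float = 0.20
    frac_order_conflict: float = 0.10
    potency_log_range: tuple[float, float] = (1.0, 1e6)
    n_drugs: int = 10
    n_antitarget_decoys: int = 1
    n_reported_pairs: int = 0

    def __post_init__(self) -> None:
        fracs = [self.frac_low_confidence, self.frac_approx_relation,
                 self.frac_interference, self.frac_aggregator,
                 self.frac_multimeasure, self.frac_order_conflict]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise GenerationError("nuisance fractions must lie in [0, 1]")
        # < 3 is allowed deliberately: pairs planted below the minimum shared
        # count must NOT be recovered, which recovery tests exercise
        if self.shared_per_planted_pair < 1:
            raise GenerationError("shared_per_planted_pair must be >= 1")
        if not 0.0 < self.within_family_identity <= 1.0:
            raise GenerationError("within_family_identity must be in (0, 1]")
        lo, hi = self.potency_log_range
        if not 0 < lo < hi:
            raise GenerationError("potency_log_range must be 0 < min < max")

    @property
    def has_nuisance(self) -> bool:
        return (
            any(f > 0 for f in (self.frac_low_confidence, self.frac_approx_relation,
                                self.frac_interference, self.frac_aggregator,
                                self.frac_multimeasure, self.frac_order_conflict))
            or self.n_antitarget_decoys > 0
        )

    @classmethod
    def noise_free(cls, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """The clean-recovery condition: planted signal, zero nuisance."""
        return cls(
            seed=seed,
            frac_low_confidence=0.0, frac_approx_relation=0.0,
            frac_interference=0.0, frac_aggregator=0.0,
            frac_multimeasure=0.0, frac_order_conflict=0.0,
            n_antitarget_decoys=0,
            **kwargs,
        )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the pipeline should recover from a synthetic bundle."""

    planted_pairs: dict[tuple[str, str], tuple[str, ...]]
    decoy_pairs: dict[tuple[str, str], str] = field(default_factory=dict)
    record_labels: list[dict] = field(default_factory=list)
    planted_bin_histogram: dict[str, int] | None = None

    def as_json(self) -> dict:
        return {
            "planted_pairs": [
                {"target_a": a, "target_b": b, "shared_compounds": list(c)}
                for (a, b), c in sorted(self.planted_pairs.items())
            ],
            "decoy_pairs": [
                {"target_a": a, "target_b": b, "reason": r}
                for (a, b), r in sorted(self.decoy_pairs.items())
            ],
            "record_labels": self.record_labels,
            "planted_bin_histogram": self.planted_bin_histogram,
        }


@dataclass
class SyntheticBundle:
    """An in-memory synthetic study: inputs plus ground truth."""

    config: SyntheticConfig
    targets: list[TargetInfo]
    family_map: dict[str, str]
    antitarget_families: set[str]
    activity_rows: list[dict]
    structures: dict[str, str]
    pains_smarts: list[str]
    aggregator_ids: set[str]
    drug_ids: set[str]
    therapeutic_ids: set[str]
    disease_map: dict[str, set[str]]
    pathway_map: dict[str, set[str]]
    known_pairs: set[tuple[str, str]]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# targets

def generate_targets(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[TargetInfo]:
    """Grow each family from an independent random ancestor sequence.

    Members conserve ``within_family_identity`` of ancestor positions (so
    same-family pairs are sequence-similar and removable), while sequences
    from different families are independent, keeping cross-family identity
    near the random baseline. One antitarget (hERG) family is appended.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    families = list(FAMILY_NAMES[: cfg.n_families])
    while len(families) < cfg.n_families:
        families.append(f"FAM{len(families):02d}")
    targets: list[TargetInfo] = []
    idx = 0
    for fam in families + [ANTITARGET_FAMILY]:
        n_members = cfg.targets_per_family if fam != ANTITARGET_FAMILY else 2
        ancestor = rng.choice(AMINO_ACIDS, size=cfg.sequence_length)
        for _ in range(n_members):
            idx += 1
            seq = ancestor.copy()
            mutate = rng.random(cfg.sequence_length) > cfg.within_family_identity
            for pos in np.nonzero(mutate)[0]:
                choices = AMINO_ACIDS[AMINO_ACIDS != seq[pos]]
                seq[pos] = rng.choice(choices)
            targets.append(
                TargetInfo(
                    target_id=f"T{idx:03d}",
                    name=f"{fam} member {idx}",
                    family=fam,
                    sequence="".join(seq),
                    is_antitarget=(fam == ANTITARGET_FAMILY),
                )
            )
    return targets


# ---------------------------------------------------------------------------
# compounds

def _base_smiles(i: int) -> str:
    """Deterministic distinct valid SMILES for compound index ``i``."""
    a, rest = i % 16, i // 16
    b, rest = rest % 16, rest // 16
    if rest >= len(_RING_SCAFFOLDS):
        raise GenerationError(f"compound index {i} exceeds structure capacity")
    return _RING_SCAFFOLDS[rest] + "C" * a + "C(=O)N" + "C" * b


def _quinone_smiles(k: int) -> str:
    """A substituted p-benzoquinone: matches the generated PAINS pattern."""
    return "C" * (k + 1) + "C1=CC(=O)C=CC1=O"


class _CompoundFactory:
    """Hands out unique compound ids with deterministic structures."""

    def __init__(self) -> None:
        self.structures: dict[str, str] = {}
        self._i = 0
        self._quinones = 0

    def new(self, *, interference: bool = False, salt: bool = False) -> str:
        self._i += 1
        cid = f"CPD{self._i:05d}"
        if interference:
            self._quinones += 1
            smi = _quinone_smiles(self._quinones)
        else:
            smi = _base_smiles(self._i)
            if salt:
                smi += ".Cl"
        self.structures[cid] = smi
        return cid


# ---------------------------------------------------------------------------
# activities

_COLUMNS = ["compound_id", "smiles", "target_id", "organism",
            "relationship_type", "confidence_score", "measure_type",
            "relation", "value"]


def _log_uniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


class _ActivityWriter:
    def __init__(self, bundle_structures: dict[str, str], labels: list[dict]):
        self.rows: list[dict] = []
        self.structures = bundle_structures
        self.labels = labels

    def add(
        self,
        compound_id: str,
        target_id: str,
        values: Sequence[float],
        *,
        measure: str = "Ki",
        relation: str = "=",
        confidence: int = 9,
        rel_type: str = "D",
        organism: str = "human",
        survive: bool = True,
        reason: str | None = None,
    ) -> None:
        for v in values:
            self.rows.append(
                {
                    "compound_id": compound_id,
                    "smiles": self.structures[compound_id],
                    "target_id": target_id,
                    "organism": organism,
                    "relationship_type": rel_type,
                    "confidence_score": confidence,
                    "measure_type": measure,
                    "relation": relation,
                    "value": f"{v:.6g}",
                }
            )
            self.labels.append(
                {
                    "compound_id": compound_id,
                    "target_id": target_id,
                    "should_survive_curation": survive,
                    "rejection_reason": reason,
                }
            )


def _pick_cross_family_pair(
    regular: list[TargetInfo],
    used: set[str],
    rng: np.random.Generator,
    criteria: CurationCriteria,
    params: AlignmentParams,
) -> tuple[TargetInfo, TargetInfo]:
    """A fresh cross-family, sequence-diverse target pair (verified)."""
    unused = [t for t in regular if t.target_id not in used]
    if len(unused) < 2:
        raise GenerationError(
            "not enough unused targets to place another pair; "
            "increase targets or decrease planted pairs"
        )
    for _ in range(200):
        a, b = rng.choice(len(unused), size=2, replace=False)
        ta, tb = unused[a], unused[b]
        if ta.family == tb.family:
            continue
        res = compute_identity(ta.sequence, tb.sequence, params)
        if is_sequence_diverse(res, criteria):
            used |= {ta.target_id, tb.target_id}
            return ta, tb
    raise GenerationError(
        "could not place a cross-family sequence-diverse pair; "
        "increase targets or decrease planted pairs"
    )


def generate_activities(
    cfg: SyntheticConfig,
    targets: list[TargetInfo],
    rng: np.random.Generator | None = None,
    *,
    shared_counts: Sequence[int] | None = None,
) -> SyntheticBundle:
    """Plant pairs, decoys and background records around the given targets."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    regular = [t for t in targets if not t.is_antitarget]
    antitargets = [t for t in targets if t.is_antitarget]
    if 2 * cfg.n_planted_pairs > len(regular):
        raise GenerationError(
            f"{cfg.n_planted_pairs} planted pairs need "
            f"{2 * cfg.n_planted_pairs} distinct targets, have {len(regular)}"
        )
    criteria = CurationCriteria()
    params = AlignmentParams()
    lo, hi = cfg.potency_log_range

    factory = _CompoundFactory()
    labels: list[dict] = []
    writer = _ActivityWriter(factory.structures, labels)
    aggregator_ids: set[str] = set()
    used_targets: set[str] = set()

    def potency() -> float:
        return _log_uniform(rng, lo, hi)

    def clean_values() -> list[float]:
        v = potency()
        if rng.random() < cfg.frac_multimeasure:
            return [v, v * float(rng.uniform(1.0, 3.0))]
        return [v]

    # --- planted pairs -----------------------------------------------------
    planted: dict[tuple[str, str], tuple[str, ...]] = {}
    for p in range(cfg.n_planted_pairs):
        ta, tb = _pick_cross_family_pair(regular, used_targets, rng, criteria, params)
        n_shared = (
            shared_counts[p] if shared_counts is not None
            else cfg.shared_per_planted_pair
        )
        shared = []
        for c in range(n_shared):
            cid = factory.new(salt=(c % 5 == 4))
            shared.append(cid)
            for t in (ta.target_id, tb.target_id):
                measure = "Ki" if rng.random() < 0.5 else "IC50"
                writer.add(cid, t, clean_values(), measure=measure)
        planted[pair_key(ta.target_id, tb.target_id)] = tuple(sorted(shared))

    # --- decoy pairs: one per active nuisance class ------------------------
    decoys: dict[tuple[str, str], str] = {}

    def plant_decoy(reason: str, flaw) -> None:
        ta, tb = _pick_cross_family_pair(regular, used_targets, rng, criteria, params)
        key = pair_key(ta.target_id, tb.target_id)
        decoys[key] = reason
        for _ in range(3):
            flaw(ta, tb)

    if cfg.frac_low_confidence > 0:
        plant_decoy(
            "low_confidence",
            lambda ta, tb: _dual(writer, factory, (ta, tb), [potency()],
                                 confidence=7, reason="low_confidence"),
        )
    if cfg.frac_approx_relation > 0:
        plant_decoy(
            "non_exact_relation",
            lambda ta, tb: _dual(
                writer, factory, (ta, tb), [potency()],
                relation=str(rng.choice([">", "<", "~"])),
                reason="non_exact_relation",
            ),
        )
    if cfg.frac_interference > 0:
        plant_decoy(
            "interference_flagged",
            lambda ta, tb: _dual(
                writer, factory, (ta, tb), [potency()],
                interference=True, reason="interference_flagged",
            ),
        )
    if cfg.frac_aggregator > 0:
        def aggregator_flaw(ta, tb):
            cid = _dual(writer, factory, (ta, tb), [potency()],
                        reason="aggregator_flagged")
            aggregator_ids.add(cid)
        plant_decoy("aggregator_flagged", aggregator_flaw)
    if cfg.frac_order_conflict > 0:
        plant_decoy(
            "order_of_magnitude_conflict",
            lambda ta, tb: _dual(
                writer, factory, (ta, tb),
                [(v := potency()), v * float(rng.uniform(10.0, 100.0))],
                reason="order_of_magnitude_conflict",
            ),
        )
    if cfg.n_antitarget_decoys > 0 and antitargets:
        for _ in range(cfg.n_antitarget_decoys):
            def antitarget_flaw(ta, tb):
                cid = _dual(writer, factory, (ta, tb), [potency()],
                            reason="antitarget", survive_pair_records=True)
                at = antitargets[int(rng.integers(len(antitargets)))]
                writer.add(cid, at.target_id, [potency()],
                           survive=False, reason="antitarget")
            plant_decoy("antitarget", antitarget_flaw)
    if cfg.has_nuisance:
        # a clean same-family pair: excluded by both selection protocols
        fam_pool: dict[str, list[TargetInfo]] = {}
        for t in regular:
            if t.target_id not in used_targets:
                fam_pool.setdefault(t.family, []).append(t)
        for fam in sorted(fam_pool):
            if len(fam_pool[fam]) >= 2:
                ta, tb = fam_pool[fam][0], fam_pool[fam][1]
                used_targets |= {ta.target_id, tb.target_id}
                key = pair_key(ta.target_id, tb.target_id)
                decoys[key] = "same_family"
                for _ in range(3):
                    _dual(writer, factory, (ta, tb), [potency()],
                          survive_pair_records=True)
                break
        # a cross-family pair sharing only two compounds: below the minimum
        ta, tb = _pick_cross_family_pair(regular, used_targets, rng, criteria,
                                         params)
        key = pair_key(ta.target_id, tb.target_id)
        decoys[key] = "below_min_shared"
        for _ in range(criteria.min_shared_compounds - 1):
            _dual(writer, factory, (ta, tb), [potency()],
                  survive_pair_records=True)

    # --- background: single-target compounds with per-record nuisance ------
    for _ in range(cfg.n_background_compounds):
        r = rng.random()
        interference = r < cfg.frac_interference
        cid = factory.new(interference=interference,
                          salt=(not interference and rng.random() < 0.15))
        if rng.random() < cfg.frac_aggregator:
            aggregator_ids.add(cid)
        t = targets[int(rng.integers(len(targets)))]
        flaw = rng.random()
        kwargs: dict = {}
        reason = None
        if flaw < cfg.frac_low_confidence:
            kwargs["confidence"] = int(rng.integers(3, 9))
            reason = "low_confidence"
        elif flaw < cfg.frac_low_confidence + cfg.frac_approx_relation:
            kwargs["relation"] = str(rng.choice([">", "<", "~"]))
            reason = "non_exact_relation"
        elif flaw < cfg.frac_low_confidence + cfg.frac_approx_relation + 0.05 \
                and cfg.has_nuisance:
            kwargs["measure"] = "Kd"
            reason = "wrong_measure_type"
        values = [potency()]
        if rng.random() < cfg.frac_multimeasure:
            if rng.random() < cfg.frac_order_conflict:
                values = [values[0], values[0] * float(rng.uniform(10.0, 100.0))]
                reason = reason or "order_of_magnitude_conflict"
            else:
                values = [values[0], values[0] * float(rng.uniform(1.0, 3.0))]
        if interference:
            reason = reason or "interference_flagged"
        elif cid in aggregator_ids:
            reason = reason or "aggregator_flagged"
        if t.is_antitarget:
            reason = "antitarget"
        writer.add(cid, t.target_id, values, survive=(reason is None),
                   reason=reason, **kwargs)

    # --- overlays ----------------------------------------------------------
    planted_compounds = sorted({c for comps in planted.values() for c in comps})
    n_from_planted = min(len(planted_compounds), int(round(0.7 * cfg.n_drugs)))
    drug_ids = set(
        rng.choice(planted_compounds, size=n_from_planted, replace=False)
    ) if n_from_planted else set()
    others = sorted(set(factory.structures) - set(planted_compounds))
    n_rest = min(len(others), cfg.n_drugs - len(drug_ids))
    if n_rest:
        drug_ids |= set(rng.choice(others, size=n_rest, replace=False))

    diseases = [f"DIS{i:02d}" for i in range(15)]
    pathways = [f"PATH{i:02d}" for i in range(10)]
    disease_map: dict[str, set[str]] = {}
    pathway_map: dict[str, set[str]] = {}
    therapeutic: set[str] = set()
    planted_targets = {t for key in planted for t in key}
    for t in targets:
        disease_map[t.target_id] = set(
            rng.choice(diseases, size=int(rng.integers(0, 4)), replace=False)
        )
        pathway_map[t.target_id] = set(
            rng.choice(pathways, size=int(rng.integers(0, 3)), replace=False)
        )
        in_pair = t.target_id in planted_targets
        if rng.random() < (0.85 if in_pair else 0.3):
            therapeutic.add(t.target_id)
    for (a, b) in planted:
        if rng.random() < 0.3:
            d = str(rng.choice(diseases))
            disease_map[a].add(d)
            disease_map[b].add(d)
        if rng.random() < 0.2:
            pw = str(rng.choice(pathways))
            pathway_map[a].add(pw)
            pathway_map[b].add(pw)

    known = set(sorted(planted)[: cfg.n_reported_pairs])

    return SyntheticBundle(
        config=cfg,
        targets=targets,
        family_map={t.target_id: t.family for t in targets},
        antitarget_families={ANTITARGET_FAMILY},
        activity_rows=writer.rows,
        structures=dict(factory.structures),
        pains_smarts=[QUINONE_SMARTS],
        aggregator_ids=aggregator_ids,
        drug_ids=drug_ids,
        therapeutic_ids=therapeutic,
        disease_map=disease_map,
        pathway_map=pathway_map,
        known_pairs=known,
        ground_truth=GroundTruth(
            planted_pairs=planted,
            decoy_pairs=decoys,
            record_labels=labels,
        ),
    )


def _dual(
    writer: _ActivityWriter,
    factory: _CompoundFactory,
    pair: tuple[TargetInfo, TargetInfo],
    values: Sequence[float],
    *,
    interference: bool = False,
    survive_pair_records: bool = False,
    reason: str | None = None,
    **record_kwargs,
) -> str:
    """One fresh compound with the same records against both pair targets."""
    cid = factory.new(interference=interference)
    for t in pair:
        writer.add(cid, t.target_id, values,
                   survive=survive_pair_records and reason is None,
                   reason=reason, **record_kwargs)
    return cid


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """The full synthetic study: targets plus activities, one seed."""
    rng = np.random.default_rng(cfg.seed)
    targets = generate_targets(cfg, rng)
    return generate_activities(cfg, targets, rng)


# ---------------------------------------------------------------------------
# paper-shaped frequency profile

BIN_RANGES = {"3-9": (3, 9), "10-19": (10, 19), "20-49": (20, 49),
              ">=50": (50, 80)}
DEFAULT_BIN_WEIGHTS = (0.21, 0.46, 0.21, 0.07)


def emulate_paper_shape(
    cfg: SyntheticConfig,
    bin_weights: Sequence[float] = DEFAULT_BIN_WEIGHTS,
) -> SyntheticBundle:
    """Plant pairs whose shared-compound counts follow a bin distribution.

    Shared counts are sampled per pair from the four frequency bins with the
    given weights (uniform within a bin), so the reporting stage can be
    exercised against a known bin histogram, recorded in the ground truth.
    """
    if len(bin_weights) != 4:
        raise GenerationError("bin_weights must have four entries")
    w = np.asarray(bin_weights, dtype=float)
    if w.sum() <= 0:
        raise GenerationError("bin_weights must not all be zero")
    w = w / w.sum()
    rng = np.random.default_rng(cfg.seed)
    targets = generate_targets(cfg, rng)
    labels = list(BIN_RANGES)
    chosen = rng.choice(len(labels), size=cfg.n_planted_pairs, p=w)
    counts = [
        int(rng.integers(BIN_RANGES[labels[c]][0], BIN_RANGES[labels[c]][1] + 1))
        for c in chosen
    ]
    bundle = generate_activities(cfg, targets, rng, shared_counts=counts)
    hist = {label: 0 for label in labels}
    for c in chosen:
        hist[labels[c]] += 1
    bundle.ground_truth.planted_bin_histogram = hist
    return bundle


# ---------------------------------------------------------------------------
# serialization

def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the pipeline's plain-text input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("activities", "activities.tsv"),
        ("structures", "structures.smi"),
        ("sequences", "targets.fasta"),
        ("families", "families.tsv"),
        ("antitarget_families", "antitarget_families.txt"),
        ("pains", "pains.smarts"),
        ("aggregators", "aggregators.txt"),
        ("drugs", "drugs.txt"),
        ("therapeutic", "therapeutic.txt"),
        ("disease_map", "disease_map.tsv"),
        ("pathway_map", "pathway_map.tsv"),
        ("known_pairs", "known_pairs.tsv"),
        ("ground_truth", "ground_truth.json"),
    ]}
    with open(paths["activities"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for row in bundle.activity_rows:
            fh.write("\t".join(str(row[c]) for c in _COLUMNS) + "\n")
    with open(paths["structures"], "w", encoding="utf-8") as fh:
        for cid in sorted(bundle.structures):
            fh.write(f"{bundle.structures[cid]}\t{cid}\n")
    with open(paths["sequences"], "w", encoding="utf-8") as fh:
        for t in bundle.targets:
            fh.write(f">{t.target_id} {t.name}\n")
            for i in range(0, len(t.sequence), 60):
                fh.write(t.sequence[i : i + 60] + "\n")
    with open(paths["families"], "w", encoding="utf-8") as fh:
        fh.write("# target_id\tfamily\n")
        for t in bundle.targets:
            fh.write(f"{t.target_id}\t{t.family}\n")
    for name, items in [
        ("antitarget_families", sorted(bundle.antitarget_families)),
        ("pains", bundle.pains_smarts),
        ("aggregators", sorted(bundle.aggregator_ids)),
        ("drugs", sorted(bundle.drug_ids)),
        ("therapeutic", sorted(bundle.therapeutic_ids)),
    ]:
        with open(paths[name], "w", encoding="utf-8") as fh:
            fh.writelines(f"{x}\n" for x in items)
    for name, mapping in [("disease_map", bundle.disease_map),
                          ("pathway_map", bundle.pathway_map)]:
        with open(paths[name], "w", encoding="utf-8") as fh:
            for tid in sorted(mapping):
                for ann in sorted(mapping[tid]):
                    fh.write(f"{tid}\t{ann}\n")
    with open(paths["known_pairs"], "w", encoding="utf-8") as fh:
        for a, b in sorted(bundle.known_pairs):
            fh.write(f"{a}\t{b}\n")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {"config": asdict(bundle.config),
             **bundle.ground_truth.as_json()},
            fh, indent=1, default=list,
        )
    return paths
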