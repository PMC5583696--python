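# Methods

## The mining protocol

`ligandlink` establishes relationships between pharmaceutical targets from
the active compounds they share. The unit of evidence is a curated potency
annotation: one compound, one target, one measure type (K_i or IC50), one
potency. Two targets are related when at least three compounds are annotated
against both, and the relationship is considered *unexpected* — the object
of interest — only when the targets belong to different families **and**
have diverse sequences. The two selection protocols run independently and
their pair sets are intersected, so a surviving pair is cross-family by the
classification scheme and sequence-diverse by alignment, i.e. distantly
related or unrelated by either measure.

### Curation rules and their rationale

- **Record selection.** Relationship type `D` (direct interaction),
  confidence 9 (single-protein assignment), organism match
  (case-insensitive; default `human`), measure type in {K_i, IC50}, exact
  relation only. Each rejected record is counted under the *first* failing
  criterion in that fixed order; the kept set is the conjunction and is
  order-independent and idempotent.
- **Standardization.** Compound identity is the canonical parent key:
  largest organic fragment, isotopes cleared, stereochemistry removed,
  simple acids/bases neutralized, RDKit canonical aromatic SMILES. Raw
  compound ids whose structures collapse onto one key are merged into one
  entity (the lexicographically smallest id represents it); drug and
  aggregator id lists are matched against *any* member id or the key
  itself.
- **Potency aggregation.** Geometric mean per (entity, target, measure
  type), accepted only when max/min < `same_order_ratio` (default 10.0,
  i.e. spread < 1 log10 unit). The ratio form avoids decade-boundary
  artifacts: 9.9 and 10.1 nM agree under this rule although they straddle a
  decade, while 10 and 100 nM (ratio exactly 10) conflict. K_i and IC50 are
  never pooled into one mean; pair mining only requires that *some*
  annotation exists.
- **Antitargets.** A compound with any hERG/CYP450-family annotation is
  removed entirely, not just its antitarget annotations — the stricter of
  the two possible readings, chosen because liability-prone chemistry makes
  every annotation of such a compound suspect for relationship mining.
- **No potency cutoff**, anywhere: weak (micromolar–millimolar) actives are
  informative precisely for remote relationships, and the tests assert that
  a 1 mM-only compound can still form pairs.

### Sequence identity

The similarity filter needs one number per target pair. It is computed from
a global affine-gap alignment (Gotoh three-state recursion) with BLOSUM62,
gap open 10, gap extend 0.5 — the alignment community's standard global
parameters. Two conventions had to be fixed:

- **Denominator.** Percent identity divides identical aligned residues by
  the *shorter* sequence's length. This is the conservative choice: it
  yields the larger identity and errs toward removing related pairs.
- **Tie-break.** Among all score-optimal alignments, the one maximizing the
  number of identical residues is used (the pair scores (score, identity)
  propagate lexicographically through the dynamic program, which is exact
  because both components are additive along an alignment). This makes
  `n_identical` a well-defined function of the two sequences rather than an
  artifact of traceback order, is symmetric (arguments are canonically
  ordered), and again errs toward removal. Scores are doubled to integers
  so half-point gap extensions stay exact; the kernel is numba-compiled.

A pair is removed as similar when identity > `max_identity_pct` (20.0) or
`n_identical` ≥ `max_identical_residues` (30). Note an interaction between
the two rules and sequence length: under a gapped global alignment with the
shorter-sequence denominator, two *random* uniform-composition protein
sequences already show ≈ 19–20 % mean identity, and for sequences beyond
~250 residues the absolute 30-identical-residue rule alone removes
essentially all pairs. On real proteome-scale data, users tuning these
thresholds should inspect the candidate-pair survival rate; both thresholds
and all alignment parameters are configurable.

## The synthetic study

The generator emulates the *structure* of a public bioactivity export, not
its chemistry or its promiscuity statistics. Defaults (all overridable in
`SyntheticConfig`):

| parameter | default | why |
|---|---|---|
| families × members | 8 × 6 (+ hERG antitarget family of 2) | enough cross-family slots for planted pairs and decoys |
| sequence length | 120 residues | random-baseline identical count (~23, max ~29) sits safely below the 30-residue removal bar, so cross-family pairs are removable only for real similarity |
| within-family conservation | 0.8 of ancestor positions | members align at ≈ 65–80 % identity, far above the removal threshold |
| planted pairs | 5, each with 6 shared compounds | dual-target compounds annotated exactly against the two pair targets |
| background compounds | 120, single-target | cannot form pairs; carry the per-record nuisance |
| potency range | 1 nM – 1 mM, log-uniform | spans the no-cutoff regime including weak actives |
| nuisance fractions | 0.05 low-confidence, 0.05 approximate, 0.02 interference, 0.02 aggregator, 0.20 multi-measurement, 0.10 order-conflict | modest contamination typical of raw exports |

Every active nuisance class additionally plants a *decoy pair* — three
dual-target compounds whose records all carry that single flaw (plus a
clean same-family pair and a clean pair sharing only two compounds). Decoys
are what give recovery tests teeth: a pipeline that under-filters produces
false-positive pairs, one that over-filters loses planted pairs. Planted
pairs are verified cross-family and sequence-diverse at construction
(resampled otherwise), so ground truth is exact by construction. Compound
structures are generated amide/ring SMILES (some salt-decorated,
interference compounds quinone-bearing); their standardized keys are unique,
which a test asserts.

What the generator does **not** emulate: ChEMBL's heavy-tailed
target-promiscuity distribution, realistic chemistry, assay heterogeneity,
or correlated measurement error. Passing recovery tests therefore shows the
*logic* of the pipeline is right, not that real-data curation yields any
particular pair count.

`emulate_paper_shape` draws each planted pair's shared-compound count from
the four frequency bins (3–9, 10–19, 20–49, ≥50) with configurable weights
(default 0.21/0.46/0.21/0.07), recording the planted histogram so the
binning stage can be checked against it.

## Numerical and degenerate-input conventions

- Pair identity is the lexicographically ordered target-id tuple; compound
  lists serialize sorted, so outputs are byte-reproducible.
- Empty activity table: the pipeline completes with all counts zero. Empty
  pair set: frequency percentages report 0 with a warning.
- Potency unit is nM throughout; the input unit (`nM`/`uM`/`M`) is declared
  once and converted at read time.
- Frequency-bin percentages are integers (rounded); coverage percentages
  carry one decimal.
- Unknown measure types parse as `other` and are rejected *at curation*
  (attributably), not at read time; unknown relation symbols are read-time
  rejections.
- Targets without a family are excluded from the family protocol only;
  targets without a sequence from the sequence protocol only — the
  intersection therefore implicitly requires both attributes.

## Problem sizes

The test suite and the acceptance script run studies of 50–102 targets,
120–800 compounds and up to 40 planted pairs; oracle-equivalence checks use
100 random pairing instances (≤ 20 targets, ≤ 80 compounds) and 50 random
sequence pairs (≤ 60 residues) against a pure-Python exhaustive dynamic
program. These sizes exercise every rule of the protocol while keeping a
full run in seconds.

## Known limitations

- The identity convention (global alignment, shorter-sequence denominator)
  is a declared convention, not a community standard; BLAST-style local
  identity would give systematically different percentages.
- The family-combination matrix and family distribution depend entirely on
  the supplied classification; `UNASSIGNED` targets propagate as their own
  label.
- The curation counters attribute each rejected record to exactly one
  reason via a fixed precedence; a record violating several criteria is
  counted under the first.
- Disease/pathway coverage uses exact identifier intersection; no ontology
  expansion is attempted.
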