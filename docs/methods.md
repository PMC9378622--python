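# Methods

This note documents the models, rules and numerical choices behind
`gpcrchimera`, and what the synthetic fixtures do and do not demonstrate.

## Reference-anchored domain annotation

**Model.** GPCR domain architecture is treated as a labelled partition of
the residue axis into the canonical 15 segments (N-term, TM1–7, ECL1–3,
ICL1–3, C-term). The architecture of an annotated reference receptor is
transferred to any target through a protein alignment: a target residue
aligned in the same column as a reference residue inherits that residue's
segment label.

**Snapping rule.** Label transfer leaves two kinds of residues unassigned:
target residues aligned against reference gaps (insertions), and target
overhangs beyond the reference termini. The package resolves them
deterministically: an internal insertion joins the *preceding* segment (so a
2-residue insertion inside TM1 grows TM1 by 2 and shifts everything
downstream); N- and C-terminal overhangs extend the outermost projected
segments. A reference segment whose columns are all gapped in the target is
omitted from the projection with a warning rather than invented. These rules
guarantee that projected segments are ordered, disjoint and tile the target.
The alignment literature offers no canonical convention here; attaching
insertions to the earlier segment was chosen because it is the unique rule
that is simultaneously order-preserving, deterministic and
boundary-monotone, and the test suite pins it against an independent
per-residue label-transfer oracle.

**Aligner.** Two routes produce the alignment: ingestion of a pre-computed
multiple alignment (aligned FASTA or Clustal; any pair of rows is reduced to
a pairwise alignment by dropping columns gapped in both), or a built-in
global Needleman–Wunsch aligner with affine gaps (Gotoh recurrences).
Defaults are BLOSUM62 with gap open −10 and extend −0.5 (the first gap
residue costs the open penalty, each further residue the extend penalty).
Ties in the dynamic program are broken deterministically — match/mismatch
over gap-in-query over gap-in-reference — so alignments are reproducible
across platforms. The aligner's optimal scores are cross-checked in the test
suite against exhaustive enumeration on tiny pairs and against an
independent reference implementation on longer ones.

**Reference asset.** The shipped reference (`data/rhodopsin_domains.yaml`)
carries bovine rhodopsin (348 aa) with standard topology boundaries
(UniProt P02699), documented and editable; any complete, tiling reference
can be substituted. Tests never rely on the shipped coordinates — they build
synthetic references whose ground truth is known exactly.

## Transmembrane-helix prediction and the flanking gate

**Predictor.** Mean Kyte–Doolittle hydropathy in a centred sliding window
(default 19 residues, the standard setting for membrane-spanning
prediction). A helix is a maximal run of residue positions whose window mean
exceeds the threshold (default 1.6 hydropathy units); runs separated by
fewer than 3 residues are merged; runs shorter than 15 residues are
discarded. The helix interval is the run of qualifying window *centres*
itself — on a block of hydrophobic residues flanked by polar loops this run
tracks the block boundaries to within a residue or two, which is the
resolution the downstream flanking check needs. Sequences shorter than the
window yield an empty prediction with a warning. Externally computed TM
intervals can be ingested instead from a 1-based-inclusive id/start/end TSV.

**Flanking check.** The check quantifies the qualitative expectation that
predicted TMs tightly flank alignment-derived signaling segments. Each
signaling segment is paired with its architecturally adjacent TMs (ICLk with
TMk and TMk+1; the C-terminus with TM7 upstream only). When the annotation
contains those TM segments, the paired predicted helix is the one
overlapping the annotated TM interval — if no predicted helix overlaps it,
the side is reported MISSING (this is what a receptor with an undetected
seventh TM produces: C-terminus verdict *fail* with upstream MISSING).
Without annotated TMs the nearest helix on the required side is used. Gaps
are absolute residue distances between segment boundary and helix boundary;
verdicts are *seamless* (all gaps ≤ 0 by default), *minor-deviation*
(≤ 5), else *fail*. The tolerance of 5 residues encodes "minor deviations
from seamless flanking" as a testable quantity; verdicts are monotone in the
tolerance. The design pipeline fails closed on a *fail* verdict (override
with `--force`), mirroring the use of TM prediction as a verification gate
before committing a design to synthesis.

## Chimera assembly

**Protein level.** The donor's annotation must tile its sequence; each
segment in the swap set (any non-empty subset of ICL1–3 and C-term) is
replaced by the acceptor's corresponding segment, in canonical order. The
full swap gives a DREADD-β2AR-style chimera; the ICL2+ICL3 partial swap
reproduces the rM3Ds-style design. N-terminal modifications are prepended
as [Met] + signal peptide (`KTIIALSYIFCLVFA`) + VSV-G epitope
(`YTDIEMNRLGK`) + linker (`DSL`), and the donor's own initiator Met is
dropped whenever mods are applied. The printed signal peptide carries no
start Met, but an ORF cannot express without ATG, so the package prepends an
initiator Met by default (`include_initiator_met=True`) and documents it as
its own tag block; disable it to model a vector supplying the start codon.
Every chimera carries a provenance list (label, origin ∈ donor/acceptor/tag,
coordinates) that tiles its sequence exactly.

**DNA level.** Receptor segments are spliced from their parent's native
coding sequence (CCDS-style ORFs) — they are deliberately *not* re-optimised,
so the synthesised DNA is faithful to the parent genes codon-for-codon. Only
tag blocks are back-translated, with a most-frequent-human-codon table
(deterministic; a usage-weighted seedable sampler exists for recoding). One
stop codon (TAA by default, configurable) is appended. The defining
invariant — in-frame translation of the ORF equals the chimera protein — is
re-validated after every transformation.

**Restriction flanks.** Recognition sites (EcoRI `GAATTC` or NotI
`GCGGCCGC` upstream, BamHI `GGATCC` downstream) are added outside the ORF.
A uniqueness screen then requires each chosen site to occur exactly once in
the whole construct. A site occurring inside the ORF is removed by
exhaustive synonymous recoding of the codons it spans (candidate codons
ordered by human usage; a candidate is accepted only if it strictly reduces
the number of unwanted sites without breaking translation); junction-spanning
occurrences created by the flanks themselves are handled by the same loop.
If no synonymous combination removes a site, assembly fails with the
offending positions listed. With the natural code and these three enzymes a
recoding escape virtually always exists (the only rigid codons are Met and
Trp); the error path is therefore exercised through an explicitly restricted
synonymous table.

## Cell-type specificity statistic

The expression screen works on a gene × cell-group matrix of replicate means
(*mean data*). For a chosen split into selected (*sc*) and disjoint
non-selected (*n-sc*) groups, each gene receives

* `sr = min(sc row) / max(n-sc row)` — strictly greater than 1 exactly when
  every selected group exceeds every non-selected group; an all-zero n-sc
  row yields an infinite (flagged) ratio rather than an exception. `sr` is
  invariant under global rescaling of the matrix.
* a Wilcoxon rank-sum p-value comparing the sc and n-sc values. For combined
  n ≤ 12 the p-value is computed by exact enumeration of all rank
  assignments (midranks for ties; all-tied input gives p = 1); above that, a
  tie-corrected normal approximation is used. The exact small-sample route
  matters because the intended group sizes are triplicate-scale, where the
  approximation is unreliable. Sidedness defaults to two-sided
  (conservative); `greater` is available for enrichment screening.
* heatmap normalisation: each gene row divided by its row maximum (zero rows
  stay zero, flagged).

## Synthetic fixtures

`synthetic` generates every test input with machine-readable ground truth:

* **Toy receptors**: N-term + 7 × (21-residue TM block + 15-residue loop
  pattern) + C-term, blocks drawn from a hydrophobic alphabet (default LIV,
  mean hydropathy ≈ 4.2) and loops from a polar one (default STG, ≈ −0.6).
  The alphabets are deliberately narrow so the window-19/threshold-1.6
  predictor recovers block boundaries within ±2 residues across seeds; the
  fixture and predictor defaults are linked by this construction.
  `weak_tms={7}` draws the seventh block from the polar alphabet to emulate
  a receptor whose last TM falls below prediction confidence.
* **Matched CDS** by back-translation (most-frequent table or seeded
  usage-weighted sampling), always translating back exactly.
* **Random projection cases**: complete references with random segment
  lengths and column-wise derived targets (substitutions, insertions,
  deletions, terminal overhangs).
* **Expression matrices**: per-gene lognormal baselines (around 100 array
  units), multiplicative lognormal noise σ = 0.3, and a planted fold-4
  enrichment of 10 of 200 genes in one target group of a 7-group triplicate
  layout. σ = 0.3 and fold 4 make the planted effect reliably detectable at
  triplicate scale without being trivial.

These fixtures emulate architecture and effect structure, not reality: real
GPCRs have heterogeneous helix lengths, amphipathic helices and re-entrant
loops; real microarray data have correlated noise, batch structure and
mean–variance coupling. Passing tests therefore demonstrate correctness of
the algorithms under their stated assumptions, not field performance of
hydropathy prediction or microarray screening.

## Problem sizes and numerical choices

The test-suite and acceptance computations use 200 random alignments for the
projection oracle, 50 seeds for topology recovery, a 12-design panel for
construct invariants, and 100 simulations of 200-gene matrices for
enrichment recovery — sizes at which every check is exact or at negligible
Monte-Carlo error while the whole suite runs in seconds. All coordinates are
0-based half-open internally, converted to 1-based inclusive only at
GenBank/TSV boundaries. All randomness flows through per-call
`numpy.random.Generator` seeds; the pipeline embeds tool version, config
hash and seed in every output and is byte-identical across repeated runs
(GenBank LOCUS dates are pinned for this reason).

## Known limitations

* The built-in aligner is pairwise; fidelity to a many-sequence alignment
  requires ingesting an external MSA.
* Hydropathy prediction is a deliberately simple surrogate for HMM-based TM
  predictors and has no posterior-confidence notion; "insufficient
  certainty" maps onto helices falling below the fixed threshold.
* Signal-peptide presence is declared by configuration, not predicted.
* Vector context (promoter, backbone) is metadata only; the package models
  the synthesised insert, not the expression vector.
* sc/n-sc splits are explicit choices; the package does not enumerate or
  optimise group combinations.
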