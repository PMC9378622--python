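"""Synthetic test-input generators with machine-readable ground truth.

Everything the test suite and the acceptance checks consume is generated
here: toy seven-transmembrane proteins with exactly known architecture,
matching coding sequences, randomized reference/target alignment pairs for
exercising domain projection, and expression matrices with planted
cell-group enrichment.  All randomness flows through one seeded
``numpy.random.Generator`` per call; no global state.

The toy receptors emulate only the architectural skeleton of a GPCR —
hydrophobic 21-residue membrane blocks separated by polar loops — not real
sequence statistics.  The default alphabets are chosen so the block/loop
hydropathy contrast is decisive for the default Kyte–Doolittle predictor
settings (window 19, threshold 1.6): LIV blocks average ≈ 4.2, STG loops
≈ −0.6, which keeps predicted helix boundaries within a residue or two of
the planted blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import backtranslate_most_frequent, backtranslate_sampled, check_codon_table
from .errors import ConfigError
from .records import CANONICAL_ORDER, CdsRecord, DomainAnnotation, ProteinRecord, Segment
from .alignment import AlignedPair, ReferenceAnnotation


@dataclass(frozen=True)
class ToyGpcrSpec:
    """Parameters of a synthetic n-TM receptor with known architecture."""

    n_tm: int = 7
    tm_len: int = 21
    loop_len: int = 15
    nterm_len: int = 20
    cterm_len: int = 25
    hydrophobic_alphabet: str = "LIV"
    polar_alphabet: str = "STG"
    weak_tms: frozenset[int] = frozenset()  # 1-based TM indices drawn polar
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tm < 1:
            raise ConfigError("n_tm must be >= 1")
        for name in ("tm_len", "loop_len", "nterm_len", "cterm_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if set(self.hydrophobic_alphabet) & set(self.polar_alphabet):
            raise ConfigError("hydrophobic and polar alphabets must be disjoint")
        bad = {k for k in self.weak_tms if not (1 <= k <= self.n_tm)}
        if bad:
            raise ConfigError(f"weak_tms indices out of range: {sorted(bad)}")


def _loop_label(k: int) -> str:
    """Label of the loop after TM k: ICLs after odd TMs, ECLs after even."""
    return f"ICL{(k + 1) // 2}" if k % 2 == 1 else f"ECL{k // 2}"


def make_toy_gpcr(spec: ToyGpcrSpec) -> tuple[ProteinRecord, DomainAnnotation]:
    """Build a toy receptor and its exact ground-truth annotation.

    Architecture: N-term + (TM + loop) × (n_tm − 1) + TM + C-term, with TM
    blocks drawn from the hydrophobic alphabet (except ``weak_tms``, drawn
    polar to emulate a membrane span an external predictor misses) and
    everything else from the polar alphabet.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    hydro = list(spec.hydrophobic_alphabet)
    polar = list(spec.polar_alphabet)

    def draw(alphabet: list[str], n: int) -> str:
        return "".join(rng.choice(alphabet, size=n))

    parts: list[str] = []
    segments: list[Segment] = []
    pos = 0

    def emit(label: str, seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        segments.append(Segment(label, pos, pos + len(seq)))
        pos += len(seq)

    emit("N-term", "M" + draw(polar, spec.nterm_len - 1))
    for k in range(1, spec.n_tm + 1):
        block_alphabet = polar if k in spec.weak_tms else hydro
        emit(f"TM{k}", draw(block_alphabet, spec.tm_len))
        if k < spec.n_tm:
            emit(_loop_label(k), draw(polar, spec.loop_len))
    emit("C-term", draw(polar, spec.cterm_len))

    protein = ProteinRecord(id=f"toy7tm_{spec.seed}", seq="".join(parts))
    annotation = DomainAnnotation(
        protein_id=protein.id, segments=segments, protein_length=len(protein)
    )
    return protein, annotation


def make_toy_reference(spec: ToyGpcrSpec) -> tuple[ProteinRecord, ReferenceAnnotation]:
    """A toy receptor packaged as a complete, tiling reference annotation."""
    protein, annotation = make_toy_gpcr(spec)
    ref = ReferenceAnnotation(
        protein_id=protein.id,
        annotation=annotation,
        source=f"synthetic toy reference, seed {spec.seed}",
    )
    return protein, ref


def back_translate(
    protein: ProteinRecord,
    codon_table: str = "human-most-frequent",
    seed: int | None = None,
) -> CdsRecord:
    """A CDS whose translation is exactly ``protein.seq`` (stop appended).

    With ``seed`` set, codons are sampled by usage fraction (synonymous but
    generally unequal CDS across seeds); without, the deterministic
    most-frequent table is used.
    """
    check_codon_table(codon_table)
    if seed is None:
        coding = backtranslate_most_frequent(protein.seq)
    else:
        coding = backtranslate_sampled(protein.seq, np.random.default_rng(seed))
    return CdsRecord(id=protein.id, seq=coding + "TAA", has_stop=True)


# --- randomized alignment pairs for projection testing ---------------------


def make_toy_alignment(
    seed: int,
    n_segments: int = 15,
    min_seg: int = 2,
    max_seg: int = 12,
    p_insert: float = 0.08,
    p_delete: float = 0.08,
    p_substitute: float = 0.1,
) -> tuple[ReferenceAnnotation, AlignedPair]:
    """A random complete reference annotation plus a reference/target alignment.

    The reference tiles the canonical 15-segment architecture with random
    segment lengths; the target is derived column-by-column with random
    substitutions, deletions (gap in target) and insertions (gap in
    reference).  Terminal target overhangs are added occasionally to exercise
    the N-/C-terminal extension rule.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    labels = list(CANONICAL_ORDER[:n_segments])

    seg_lens = rng.integers(min_seg, max_seg + 1, size=len(labels))
    ref_seq = "".join(rng.choice(alphabet, size=int(seg_lens.sum())))
    segments, pos = [], 0
    for label, ln in zip(labels, seg_lens):
        segments.append(Segment(label, pos, pos + int(ln)))
        pos += int(ln)
    ref_ann = ReferenceAnnotation(
        protein_id=f"toyref_{seed}",
        annotation=DomainAnnotation(
            protein_id=f"toyref_{seed}", segments=segments, protein_length=pos
        ),
        source="synthetic",
    )

    ref_cols: list[str] = []
    qry_cols: list[str] = []
    # optional N-terminal target overhang (aligned against reference gaps)
    for _ in range(int(rng.integers(0, 4))):
        ref_cols.append("-")
        qry_cols.append(str(rng.choice(alphabet)))
    for ch in ref_seq:
        r = rng.random()
        if r < p_delete:
            ref_cols.append(ch)
            qry_cols.append("-")
        else:
            ref_cols.append(ch)
            if rng.random() < p_substitute:
                qry_cols.append(str(rng.choice(alphabet)))
            else:
                qry_cols.append(ch)
        if rng.random() < p_insert:
            for _ in range(int(rng.integers(1, 4))):
                ref_cols.append("-")
                qry_cols.append(str(rng.choice(alphabet)))
    for _ in range(int(rng.integers(0, 4))):
        ref_cols.append("-")
        qry_cols.append(str(rng.choice(alphabet)))

    pair = AlignedPair(
        ref_id=ref_ann.protein_id,
        qry_id=f"toytgt_{seed}",
        ref_aln="".join(ref_cols),
        qry_aln="".join(qry_cols),
        score=float("nan"),
    )
    return ref_ann, pair


# --- expression matrices with planted enrichment ---------------------------

DEFAULT_GROUPS = (
    "microglia",
    "rod",
    "cone",
    "bipolar",
    "amacrine",
    "ganglion",
    "muller",
)


@dataclass
class ExpressionFixture:
    """A simulated expression matrix plus its ground truth."""

    expr: pd.DataFrame  # genes × samples
    grouping: dict[str, str]  # sample → group
    enriched_genes: list[str]
    target_group: str


def make_expression_matrix(
    n_genes: int = 200,
    groups: dict[str, int] | None = None,
    enriched_genes: list[int] | None = None,
    target_group: str = "microglia",
    fold: float = 4.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> ExpressionFixture:
    """Lognormal expression with a planted fold-enrichment in one group.

    Baseline per-gene levels are lognormal around ~100 array units; every
    sample adds multiplicative lognormal noise of σ ``noise_sigma``; the
    ``enriched_genes`` (default: the first 10) are multiplied by ``fold`` in
    the ``target_group`` samples.  Deterministic per seed.
    """
    if fold <= 1:
        raise ConfigError("fold must be > 1")
    if groups is None:
        groups = {g: 3 for g in DEFAULT_GROUPS}
    for g, k in groups.items():
        if k < 1:
            raise ConfigError(f"group {g!r} has no samples")
    if target_group not in groups:
        raise ConfigError(f"target group {target_group!r} not among groups")
    if enriched_genes is None:
        enriched_genes = list(range(min(10, n_genes)))
    if any(i < 0 or i >= n_genes for i in enriched_genes):
        raise ConfigError("enriched gene index out of range")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))

    columns: list[str] = []
    grouping: dict[str, str] = {}
    data: list[np.ndarray] = []
    enriched_mask = np.zeros(n_genes, dtype=bool)
    enriched_mask[list(enriched_genes)] = True
    for g, k in groups.items():
        for r in range(1, k + 1):
            sample = f"{g}_{r}"
            columns.append(sample)
            grouping[sample] = g
            values = baseline * np.exp(rng.normal(0.0, noise_sigma, size=n_genes))
            if g == target_group:
                values = values * np.where(enriched_mask, fold, 1.0)
            data.append(values)

    expr = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=columns)
    return ExpressionFixture(
        expr=expr,
        grouping=grouping,
        enriched_genes=[gene_ids[i] for i in enriched_genes],
        target_group=target_group,
    )
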