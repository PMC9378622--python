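"""Reference-anchored domain identification.

The library-building step: the domain architecture of bovine rhodopsin (RHO)
is projected through a protein alignment onto any GPCR of interest, yielding
ligand-binding (N-term, TMs, ECLs) and signaling (ICL1-3, C-term) domains for
that receptor.  Two alignment routes are supported:

* ingesting a pre-computed multiple alignment (aligned FASTA or Clustal,
  e.g. MUSCLE output), which preserves fidelity to a many-sequence alignment;
* a built-in pairwise global aligner (Needleman–Wunsch with affine gaps,
  BLOSUM62, gap open −10 / extend −0.5 by default) so the tool runs with no
  external aligner.

Projection walks alignment columns and transfers each reference residue's
segment label to the target residue aligned in the same column.  Target
residues aligned against reference gaps are attached by the snapping rule
documented in ``docs/methods.md``: internal insertions join the preceding
segment; unaligned target overhangs extend the terminal segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .errors import AnnotationError, ConfigError, LookupError_, ParseError, ValidationError
from .records import (
    CANONICAL_ORDER,
    DomainAnnotation,
    ProteinRecord,
    Segment,
    SIGNALING_LABELS,
)


class ProjectionWarning(UserWarning):
    """A reference segment collapsed to zero length in the target."""


class LibraryWarning(UserWarning):
    """A protein was skipped during signaling-library export."""


# --- alignment containers --------------------------------------------------


@dataclass(frozen=True)
class AlignedPair:
    """A pairwise global alignment between a query and the reference."""

    ref_id: str
    qry_id: str
    ref_aln: str
    qry_aln: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.qry_aln):
            raise ValidationError("aligned rows differ in length")
        for c, (r, q) in enumerate(zip(self.ref_aln, self.qry_aln)):
            if r == "-" and q == "-":
                raise ValidationError(f"column {c} is gap in both rows")

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace("-", "")

    @property
    def qry_seq(self) -> str:
        return self.qry_aln.replace("-", "")


@dataclass
class Msa:
    """A multiple alignment as an ordered id → gapped-row map."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.rows.values()}
        if len(lengths) > 1:
            raise ParseError(f"ragged alignment rows: lengths {sorted(lengths)}")
        for rid, row in self.rows.items():
            if not row.replace("-", ""):
                raise ValidationError(f"row {rid!r} is empty after gap removal")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def pair(self, ref_id: str, qry_id: str) -> AlignedPair:
        """Extract a two-row alignment, dropping columns gapped in both."""
        for rid in (ref_id, qry_id):
            if rid not in self.rows:
                raise LookupError_(f"alignment lacks row {rid!r}")
        ref, qry = [], []
        for r, q in zip(self.rows[ref_id], self.rows[qry_id]):
            if r == "-" and q == "-":
                continue
            ref.append(r)
            qry.append(q)
        return AlignedPair(ref_id, qry_id, "".join(ref), "".join(qry), float("nan"))


@dataclass
class ReferenceAnnotation:
    """The sequence-tiling architecture of the reference receptor.

    A production reference carries the complete 15-segment canonical
    architecture; ``partial=True`` relaxes that to any tiling subset, which
    keeps small hand-built references usable in exploratory work.
    """

    protein_id: str
    annotation: DomainAnnotation
    source: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.partial and not self.annotation.is_complete():
            raise AnnotationError(
                f"reference {self.protein_id!r} must carry the complete "
                f"15-segment architecture in canonical order"
            )
        if self.annotation.protein_length is None or not self.annotation.tiles():
            raise AnnotationError(
                f"reference {self.protein_id!r} segments must tile the full sequence"
            )

    @property
    def length(self) -> int:
        return self.annotation.protein_length  # type: ignore[return-value]


def load_reference_annotation(path: str) -> ReferenceAnnotation:
    """Load a reference annotation from its YAML schema.

    Schema: ``{protein_id, source, length, segments: [{label, start, end}]}``
    with 0-based half-open coordinates.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        segments = [
            Segment(s["label"], int(s["start"]), int(s["end"]))
            for s in data["segments"]
        ]
        ann = DomainAnnotation(
            protein_id=data["protein_id"],
            segments=segments,
            protein_length=int(data["length"]),
        )
        return ReferenceAnnotation(
            protein_id=data["protein_id"],
            annotation=ann,
            source=str(data.get("source", "")),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed reference annotation: {exc}") from exc


# --- built-in pairwise aligner --------------------------------------------

_NEG = float("-inf")


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except Exception as exc:
        raise ConfigError(f"unknown substitution matrix {name!r}") from exc


def align_pairwise(
    query: ProteinRecord,
    reference: ProteinRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignedPair:
    """Global Needleman–Wunsch alignment with affine gaps (Gotoh).

    The first residue of a gap costs ``gap_open``; each further residue costs
    ``gap_extend``.  Ties are broken deterministically: match/mismatch is
    preferred over a gap in the query, which is preferred over a gap in the
    reference.
    """
    sub = _load_matrix(matrix)
    a, b = query.seq, reference.seq  # a = query rows, b = reference columns
    n, m = len(a), len(b)

    def s(i: int, j: int) -> float:
        return float(sub[a[i - 1], b[j - 1]])

    # state M: a[i-1] ~ b[j-1]; GQ: gap in query (consumes reference);
    # GR: gap in reference (consumes query)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    GQ = [[_NEG] * (m + 1) for _ in range(n + 1)]
    GR = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        GQ[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        GR[i][0] = gap_open + (i - 1) * gap_extend

    # back-pointers: state entered from, per cell/state
    bpM = [[0] * (m + 1) for _ in range(n + 1)]
    bpGQ = [[0] * (m + 1) for _ in range(n + 1)]
    bpGR = [[0] * (m + 1) for _ in range(n + 1)]
    STATES = (0, 1, 2)  # M, GQ, GR in tie-break priority order

    for i in range(1, n + 1):
        Mi, GQi, GRi = M[i], GQ[i], GR[i]
        Mp, GQp, GRp = M[i - 1], GQ[i - 1], GR[i - 1]
        for j in range(1, m + 1):
            sij = s(i, j)
            cand = (Mp[j - 1], GQp[j - 1], GRp[j - 1])
            k = max(STATES, key=lambda t: (cand[t], -t))
            Mi[j] = cand[k] + sij
            bpM[i][j] = k

            cand = (Mi[j - 1] + gap_open, GQi[j - 1] + gap_extend, GRi[j - 1] + gap_open)
            k = max(STATES, key=lambda t: (cand[t], -t))
            GQi[j] = cand[k]
            bpGQ[i][j] = k

            cand = (Mp[j] + gap_open, GQp[j] + gap_open, GRp[j] + gap_extend)
            k = max(STATES, key=lambda t: (cand[t], -t))
            GRi[j] = cand[k]
            bpGR[i][j] = k

    finals = (M[n][m], GQ[n][m], GR[n][m])
    state = max(STATES, key=lambda t: (finals[t], -t))
    score = finals[state]

    qry_cols: list[str] = []
    ref_cols: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            qry_cols.append(a[i - 1])
            ref_cols.append(b[j - 1])
            state = bpM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            qry_cols.append("-")
            ref_cols.append(b[j - 1])
            if i == 0 and j > 0:
                state = 1
            else:
                state = bpGQ[i][j]
            j -= 1
        else:
            qry_cols.append(a[i - 1])
            ref_cols.append("-")
            if j == 0 and i > 0:
                state = 2
            else:
                state = bpGR[i][j]
            i -= 1
    return AlignedPair(
        ref_id=reference.id,
        qry_id=query.id,
        ref_aln="".join(reversed(ref_cols)),
        qry_aln="".join(reversed(qry_cols)),
        score=score,
    )


# --- MSA ingestion ---------------------------------------------------------


def ingest_msa(path: str, format: str = "aligned-fasta") -> Msa:
    """Read a pre-computed multiple alignment (e.g. MUSCLE output)."""
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ConfigError(f"unknown MSA format {format!r}")
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise ParseError(f"{path}: could not parse as {format}: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(rows) != len(aln):
        raise ValidationError(f"{path}: duplicate row ids in alignment")
    return Msa(rows=rows)


# --- domain projection -----------------------------------------------------


def project_domains(
    ref_annotation: ReferenceAnnotation,
    alignment: AlignedPair | Msa,
    target_id: str | None = None,
) -> DomainAnnotation:
    """Project the reference architecture onto a target through an alignment.

    Returns a :class:`DomainAnnotation` on target coordinates with segments
    disjoint, ordered and labeled as in the reference.  A reference segment
    aligned entirely against target gaps is omitted, with a
    :class:`ProjectionWarning`.
    """
    if isinstance(alignment, Msa):
        if target_id is None:
            raise ValueError("target_id required when projecting through an MSA")
        pair = alignment.pair(ref_annotation.protein_id, target_id)
    else:
        pair = alignment
        if pair.ref_id != ref_annotation.protein_id:
            raise LookupError_(
                f"alignment reference {pair.ref_id!r} does not match "
                f"annotation {ref_annotation.protein_id!r}"
            )
        target_id = target_id or pair.qry_id

    ref_len = len(pair.ref_seq)
    if ref_len != ref_annotation.length:
        raise AnnotationError(
            f"reference row length {ref_len} does not match annotated "
            f"length {ref_annotation.length}"
        )
    tgt_len = len(pair.qry_seq)

    # per-column residue indices (None at gaps)
    ref_pos: list[int | None] = []
    qry_pos: list[int | None] = []
    ri = qi = 0
    for r, q in zip(pair.ref_aln, pair.qry_aln):
        ref_pos.append(ri if r != "-" else None)
        qry_pos.append(qi if q != "-" else None)
        if r != "-":
            ri += 1
        if q != "-":
            qi += 1

    # per-segment target intervals from label transfer within segment columns
    intervals: list[tuple[str, int, int]] = []  # (label, tgt_start, tgt_end)
    for seg in ref_annotation.annotation.segments:
        tgt_hits = [
            qp
            for rp, qp in zip(ref_pos, qry_pos)
            if rp is not None and seg.start <= rp < seg.end and qp is not None
        ]
        if not tgt_hits:
            warnings.warn(
                f"{target_id}: segment {seg.label} collapsed to zero length "
                f"in projection",
                ProjectionWarning,
                stacklevel=2,
            )
            continue
        intervals.append((seg.label, min(tgt_hits), max(tgt_hits) + 1))

    if not intervals:
        return DomainAnnotation(protein_id=target_id, segments=[], protein_length=tgt_len)

    # snapping: terminal overhangs extend the outermost segments; internal
    # insertions (target residues in reference-gap columns between segments)
    # join the earlier segment
    snapped: list[tuple[str, int, int]] = []
    for k, (label, start, end) in enumerate(intervals):
        if k == 0:
            start = 0
        if k + 1 < len(intervals):
            end = intervals[k + 1][1]
        else:
            end = tgt_len
        snapped.append((label, start, end))

    return DomainAnnotation(
        protein_id=target_id,
        segments=[Segment(lbl, s, e) for lbl, s, e in snapped],
        protein_length=tgt_len,
    )


# --- signaling-domain library export --------------------------------------


@dataclass(frozen=True)
class SignalingLibraryEntry:
    """The four intracellular (signaling) sequences of one GPCR."""

    gpcr_id: str
    icl1: str
    icl2: str
    icl3: str
    cterm: str

    def __post_init__(self) -> None:
        for name in ("icl1", "icl2", "icl3", "cterm"):
            if not getattr(self, name):
                raise ValidationError(f"{self.gpcr_id}: empty {name} sequence")


def export_signaling_library(
    annotations: list[DomainAnnotation],
    proteins: list[ProteinRecord],
) -> list[SignalingLibraryEntry]:
    """Extract ICL1-3 and C-terminus sequences for each annotated protein.

    Proteins whose annotation lacks any signaling segment are skipped with a
    :class:`LibraryWarning` (the GPR109A-style ambiguous-TM7 case).
    """
    by_id = {p.id: p for p in proteins}
    entries: list[SignalingLibraryEntry] = []
    for ann in annotations:
        protein = by_id.get(ann.protein_id)
        if protein is None:
            warnings.warn(
                f"no protein sequence for annotation {ann.protein_id!r}; skipped",
                LibraryWarning,
                stacklevel=2,
            )
            continue
        missing = [lbl for lbl in SIGNALING_LABELS if not ann.has(lbl)]
        if missing:
            warnings.warn(
                f"{ann.protein_id}: missing signaling segment(s) "
                f"{', '.join(missing)}; skipped",
                LibraryWarning,
                stacklevel=2,
            )
            continue
        segs = {lbl: ann.get(lbl) for lbl in SIGNALING_LABELS}
        entries.append(
            SignalingLibraryEntry(
                gpcr_id=ann.protein_id,
                icl1=protein.seq[segs["ICL1"].start : segs["ICL1"].end],
                icl2=protein.seq[segs["ICL2"].start : segs["ICL2"].end],
                icl3=protein.seq[segs["ICL3"].start : segs["ICL3"].end],
                cterm=protein.seq[segs["C-term"].start : segs["C-term"].end],
            )
        )
    return entries


def write_signaling_library_tsv(entries: list[SignalingLibraryEntry], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gpcr_id\tICL1\tICL2\tICL3\tC-term\n")
        for e in entries:
            fh.write(f"{e.gpcr_id}\t{e.icl1}\t{e.icl2}\t{e.icl3}\t{e.cterm}\n")


def read_signaling_library_tsv(path: str) -> list[SignalingLibraryEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gpcr_id", "ICL1", "ICL2", "ICL3", "C-term"]:
            raise ParseError(f"{path}: unexpected library header {header}")
        for line in fh:
            gpcr_id, icl1, icl2, icl3, cterm = line.rstrip("\n").split("\t")
            entries.append(SignalingLibraryEntry(gpcr_id, icl1, icl2, icl3, cterm))
    return entries
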