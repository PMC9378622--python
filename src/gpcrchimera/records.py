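"""Core sequence and annotation types.

Conventions used throughout the package:

* All coordinates are 0-based, half-open ``[start, end)``.  Human-facing
  serialisations (GenBank, TM-interval TSV) convert to 1-based inclusive at
  the boundary and nowhere else.
* Protein sequences use the 20 canonical residues plus ``X``; DNA is strict
  ``ACGT`` (CCDS-style ORFs, no RNA dialect).  Lowercase input is uppercased
  on construction; anything else is rejected rather than silently mapped,
  because chimera synthesis requires the exact sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import AnnotationError, ValidationError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Canonical seven-transmembrane architecture, N- to C-terminal.
CANONICAL_ORDER = (
    "N-term",
    "TM1",
    "ICL1",
    "TM2",
    "ECL1",
    "TM3",
    "ICL2",
    "TM4",
    "ECL2",
    "TM5",
    "ICL3",
    "TM6",
    "ECL3",
    "TM7",
    "C-term",
)

SEGMENT_LABELS = frozenset(CANONICAL_ORDER)

#: The intracellular face swapped between receptors when building chimeras.
SIGNALING_LABELS = ("ICL1", "ICL2", "ICL3", "C-term")

#: The face retained from the CNO-binding donor.
LIGAND_BINDING_LABELS = tuple(
    lbl for lbl in CANONICAL_ORDER if lbl not in SIGNALING_LABELS
)


def translate_dna(dna: str) -> str:
    """Translate an in-frame DNA string with the standard code ('*' for stops)."""
    if len(dna) % 3 != 0:
        raise ValidationError(f"DNA length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())


def _check_alphabet(seq: str, alphabet: frozenset[str], record_id: str, kind: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValidationError(
                f"record {record_id!r}: invalid {kind} character {ch!r} at position {i}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (canonical residues, optional X)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty protein sequence")
        _check_alphabet(self.seq, PROTEIN_ALPHABET, self.id, "residue")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsRecord:
    """A coding DNA sequence, frame 0, CCDS-style.

    ``has_stop`` declares whether the final codon is a stop; when set, the
    final codon must be TAA/TAG/TGA and no in-frame internal stop may occur.
    """

    id: str
    seq: str
    frame: int = 0
    has_stop: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.id:
            raise ValidationError("CDS record id must be non-empty")
        if self.frame != 0:
            raise ValidationError(f"record {self.id!r}: frame must be 0")
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty CDS")
        _check_alphabet(self.seq, DNA_ALPHABET, self.id, "base")
        if len(self.seq) % 3 != 0:
            raise ValidationError(
                f"record {self.id!r}: CDS length {len(self.seq)} not divisible by 3"
            )
        codons = [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]
        internal = codons[:-1] if self.has_stop else codons
        for k, codon in enumerate(internal):
            if codon in STOP_CODONS:
                raise ValidationError(
                    f"record {self.id!r}: internal stop codon {codon} at codon {k}"
                )
        if self.has_stop and codons[-1] not in STOP_CODONS:
            raise ValidationError(
                f"record {self.id!r}: has_stop set but final codon is {codons[-1]}"
            )

    @property
    def coding(self) -> str:
        """The ORF without the trailing stop codon (if declared)."""
        return self.seq[:-3] if self.has_stop else self.seq

    def translation(self) -> str:
        return translate_dna(self.coding)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Segment:
    """A labeled residue interval ``[start, end)`` on one protein."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValidationError(f"unknown segment label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"segment {self.label}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DomainAnnotation:
    """Ordered, pairwise-disjoint labeled segments on one protein.

    ``protein_length`` is optional but required for :attr:`coverage` and for
    bounds checking against the sequence the annotation describes.
    """

    protein_id: str
    segments: list[Segment] = field(default_factory=list)
    protein_length: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        prev_end = 0
        for seg in self.segments:
            if seg.label in seen:
                raise AnnotationError(
                    f"{self.protein_id}: duplicate segment label {seg.label}"
                )
            seen.add(seg.label)
            if seg.start < prev_end:
                raise AnnotationError(
                    f"{self.protein_id}: segment {seg.label} at {seg.start} overlaps "
                    f"or is out of order (previous end {prev_end})"
                )
            prev_end = seg.end
        if self.protein_length is not None and prev_end > self.protein_length:
            raise AnnotationError(
                f"{self.protein_id}: annotation extends to {prev_end} beyond "
                f"protein length {self.protein_length}"
            )

    def get(self, label: str) -> Segment | None:
        for seg in self.segments:
            if seg.label == label:
                return seg
        return None

    def has(self, label: str) -> bool:
        return self.get(label) is not None

    @property
    def labels(self) -> list[str]:
        return [seg.label for seg in self.segments]

    @property
    def coverage(self) -> float:
        """Fraction of residues assigned to some segment."""
        if self.protein_length is None:
            raise ValueError("coverage requires protein_length")
        assigned = sum(len(seg) for seg in self.segments)
        return assigned / self.protein_length

    def is_complete(self) -> bool:
        """True when all 15 canonical segments are present in canonical order."""
        return self.labels == list(CANONICAL_ORDER)

    def tiles(self, length: int | None = None) -> bool:
        """True when segments partition ``[0, length)`` without holes."""
        length = length if length is not None else self.protein_length
        if length is None:
            raise ValueError("tiles() requires a protein length")
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                return False
            pos = seg.end
        return pos == length
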