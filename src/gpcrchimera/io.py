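"""Readers and writers for the formats the tool touches.

FASTA parsing/writing and the GenBank flat file go through Biopython; this
module adds the validation layer (alphabets, gap rejection, bounds) and the
0-based → 1-based conversion policy described in :mod:`gpcrchimera.records`.
"""

from __future__ import annotations

import os
from typing import Iterable, TYPE_CHECKING

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .records import CdsRecord, ProteinRecord

if TYPE_CHECKING:  # pragma: no cover
    from .chimera import ConstructRecord


def _check_fasta_shape(path: str) -> None:
    """Reject files that are not FASTA at all, naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            return  # first non-blank line is a header; let Biopython take over


def read_fasta(
    path: str, alphabet: str = "protein", allow_gaps: bool = False
) -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into validated records.

    ``alphabet`` is ``"protein"`` or ``"dna"``.  Ids are taken from the header
    up to the first whitespace; sequences are uppercased.  Gap characters are
    rejected unless ``allow_gaps`` (aligned FASTA goes through
    :func:`gpcrchimera.alignment.ingest_msa` instead).
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"alphabet must be 'protein' or 'dna', got {alphabet!r}")
    if os.path.getsize(path) == 0:
        return []
    _check_fasta_shape(path)
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not allow_gaps and "-" in seq:
            raise ValidationError(
                f"record {rec.id!r}: gap characters in unaligned input"
            )
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        if alphabet == "protein":
            records.append(
                ProteinRecord(id=rec.id, seq=seq, description=rec.description)
            )
        else:
            records.append(CdsRecord(id=rec.id, seq=seq, has_stop=_ends_in_stop(seq)))
    return records


def _ends_in_stop(seq: str) -> bool:
    return len(seq) % 3 == 0 and seq[-3:] in ("TAA", "TAG", "TGA")


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id}" + (f" {desc}" if desc and desc != rec.id else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --- GenBank ---------------------------------------------------------------

#: Fixed LOCUS date so repeated runs are byte-identical.
_GENBANK_DATE = "01-JAN-1980"


def write_genbank(construct: "ConstructRecord", path: str, comment: str | None = None) -> None:
    """Write a construct as a GenBank flat file.

    One ``misc_feature`` per provenance segment, tag and restriction site.
    Internal coordinates are 0-based half-open; Biopython's writer emits the
    1-based inclusive GenBank convention (+1 on start only).
    """
    n = len(construct.dna)
    for label, start, end, _origin in construct.features:
        if not (0 <= start < end <= n):
            raise ValidationError(
                f"feature {label!r} [{start}, {end}) out of bounds for "
                f"sequence of length {n}"
            )
    record = SeqRecord(
        Seq(construct.dna),
        id=construct.name[:16] or "construct",
        name=construct.name[:16] or "construct",
        description=f"synthetic chimeric GPCR construct {construct.name}",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"
    record.annotations["data_file_division"] = "SYN"
    record.annotations["date"] = _GENBANK_DATE
    if comment:
        record.annotations["comment"] = comment
    for label, start, end, origin in construct.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=1),
                type="misc_feature",
                qualifiers={"label": [label], "note": [f"origin:{origin}"]},
            )
        )
    SeqIO.write([record], path, "genbank")


def read_genbank_features(path: str) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Re-parse a written GenBank file: (sequence, [(label, start, end, origin)])."""
    rec = SeqIO.read(path, "genbank")
    feats = []
    for f in rec.features:
        if f.type != "misc_feature":
            continue
        label = f.qualifiers.get("label", ["?"])[0]
        note = f.qualifiers.get("note", ["origin:?"])[0]
        origin = note.split("origin:", 1)[-1]
        feats.append((label, int(f.location.start), int(f.location.end), origin))
    return str(rec.seq), feats
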