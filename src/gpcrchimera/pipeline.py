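"""End-to-end design pipeline: annotate → topology check → assemble → export.

Given parent protein and CDS FASTA files, a reference annotation and a
design (donor, acceptor, swap set), the pipeline projects the reference
architecture onto both parents, verifies the flanking of the signaling
segments against hydropathy-predicted TMs (fail-closed: a ``fail`` verdict
blocks the design unless forced), assembles the chimera at protein and DNA
level, adds restriction flanks, and writes GenBank/FASTA outputs, the
flanking report and a provenance JSON.  All outputs embed the tool version,
a config hash and the seed, and are byte-identical across repeated runs
with the same inputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .alignment import ReferenceAnnotation, align_pairwise, ingest_msa, project_domains
from .chimera import (
    ChimeraDesign,
    NTerminalMods,
    add_restriction_flanks,
    assemble_cds,
    assemble_protein,
)
from .errors import GpcrChimeraError, LookupError_, PipelineError
from .io import write_fasta, write_genbank
from .records import CdsRecord, ProteinRecord
from .topology import check_flanking, predict_tm, write_flanking_report_tsv


@dataclass
class RunConfig:
    """Everything a design run depends on, hashable for provenance."""

    reference: ReferenceAnnotation
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    seamless_tol: int = 0
    minor_tol: int = 5
    mods: NTerminalMods | None = field(default_factory=NTerminalMods)
    enzyme_5p: str = "EcoRI"
    enzyme_3p: str = "BamHI"
    codon_table: str = "human-most-frequent"
    seed: int = 0
    msa_path: str | None = None

    def digest(self) -> str:
        payload = {
            "reference": self.reference.protein_id,
            "reference_source": self.reference.source,
            "matrix": self.matrix,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "tm_window": self.tm_window,
            "tm_threshold": self.tm_threshold,
            "tm_min_len": self.tm_min_len,
            "seamless_tol": self.seamless_tol,
            "minor_tol": self.minor_tol,
            "mods": asdict(self.mods) if self.mods is not None else None,
            "enzyme_5p": self.enzyme_5p,
            "enzyme_3p": self.enzyme_3p,
            "codon_table": self.codon_table,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    construct: object
    annotations: dict
    flanking: dict
    outputs: list[str]


def _pick(records: list, record_id: str, what: str):
    for rec in records:
        if rec.id == record_id:
            return rec
    raise LookupError_(f"{what} id {record_id!r} not found in input")


def run_design_pipeline(
    config: RunConfig,
    donor_id: str,
    acceptor_id: str,
    swap_set: frozenset[str] | set[str],
    proteins: list[ProteinRecord],
    cds_records: list[CdsRecord],
    outdir: str,
    force: bool = False,
) -> PipelineResult:
    """Run the full design workflow and write its outputs to ``outdir``.

    Raises :class:`PipelineError` (naming the stage) on any failure; partial
    outputs are removed so a failed run leaves nothing behind.
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(outdir, name)
        written.append(path)
        return path

    stamp = f"gpcrchimera {__version__} | config {config.digest()} | seed {config.seed}"

    try:
        donor_protein = _pick(proteins, donor_id, "donor")
        acceptor_protein = _pick(proteins, acceptor_id, "acceptor")
        donor_cds = _pick(cds_records, donor_id, "donor CDS")
        acceptor_cds = _pick(cds_records, acceptor_id, "acceptor CDS")

        # stage: annotate
        try:
            msa = ingest_msa(config.msa_path) if config.msa_path else None
            annotations = {}
            for protein in (donor_protein, acceptor_protein):
                if msa is not None:
                    ann = project_domains(config.reference, msa, protein.id)
                else:
                    ref_protein = ProteinRecord(
                        id=config.reference.protein_id,
                        seq=_reference_sequence(config.reference, proteins),
                    )
                    pair = align_pairwise(
                        protein, ref_protein, config.matrix,
                        config.gap_open, config.gap_extend,
                    )
                    ann = project_domains(config.reference, pair)
                annotations[protein.id] = ann
        except GpcrChimeraError as exc:
            raise PipelineError(f"annotate: {exc}") from exc

        # stage: topology check
        try:
            flanking = {}
            for protein in (donor_protein, acceptor_protein):
                tm = predict_tm(
                    protein, config.tm_window, config.tm_threshold, config.tm_min_len
                )
                flanking[protein.id] = check_flanking(
                    annotations[protein.id], tm, config.seamless_tol, config.minor_tol
                )
            blocked = [pid for pid, rep in flanking.items() if not rep.all_ok()]
            if blocked and not force:
                raise PipelineError(
                    f"topology-check: flanking verdict 'fail' for "
                    f"{', '.join(blocked)} (use force to override)"
                )
        except PipelineError:
            raise
        except GpcrChimeraError as exc:
            raise PipelineError(f"topology-check: {exc}") from exc

        # stage: assemble
        try:
            design = ChimeraDesign(
                donor_id=donor_id,
                acceptor_id=acceptor_id,
                swap_set=frozenset(swap_set),
                mods=config.mods,
            )
            chimera = assemble_protein(
                (donor_protein, annotations[donor_id]),
                (acceptor_protein, annotations[acceptor_id]),
                design,
            )
            construct = assemble_cds(
                donor_cds, acceptor_cds, chimera, config.codon_table
            )
            construct = add_restriction_flanks(
                construct, config.enzyme_5p, config.enzyme_3p
            )
        except GpcrChimeraError as exc:
            raise PipelineError(f"assemble: {exc}") from exc

        # stage: export
        try:
            write_genbank(construct, out(f"{construct.name}.gb"), comment=stamp)
            write_fasta(
                [ProteinRecord(id=construct.name, seq=chimera.seq, description=stamp)],
                out(f"{construct.name}_protein.fasta"),
            )
            write_fasta(
                [CdsRecord(id=construct.name, seq=construct.orf, has_stop=True)],
                out(f"{construct.name}_dna.fasta"),
            )
            write_flanking_report_tsv(
                list(flanking.values()),
                out("flanking_report.tsv"),
                header_lines=[stamp],
            )
            provenance = {
                "tool": "gpcrchimera",
                "version": __version__,
                "config_hash": config.digest(),
                "seed": config.seed,
                "design": {
                    "donor": donor_id,
                    "acceptor": acceptor_id,
                    "swap_set": sorted(swap_set),
                },
                "segments": [
                    {
                        "label": seg.label,
                        "origin": seg.origin,
                        "start": seg.start,
                        "end": seg.end,
                    }
                    for seg in chimera.provenance
                ],
                "enzymes": {"5p": config.enzyme_5p, "3p": config.enzyme_3p},
                "construct_length": len(construct.dna),
            }
            with open(out("provenance.json"), "w") as fh:
                json.dump(provenance, fh, indent=2, sort_keys=True)
                fh.write("\n")
        except GpcrChimeraError as exc:
            raise PipelineError(f"export: {exc}") from exc

    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise

    return PipelineResult(
        construct=construct,
        annotations=annotations,
        flanking=flanking,
        outputs=written,
    )


def _reference_sequence(
    reference: ReferenceAnnotation, proteins: list[ProteinRecord]
) -> str:
    """The reference protein must accompany the inputs in pairwise mode."""
    for rec in proteins:
        if rec.id == reference.protein_id:
            return rec.seq
    raise LookupError_(
        f"pairwise mode needs the reference sequence {reference.protein_id!r} "
        f"among the input proteins"
    )
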