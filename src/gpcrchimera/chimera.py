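"""Assembly of DREADD-based chimeric receptors at protein and DNA level.

A chimera keeps the CNO-binding donor scaffold (N-terminus, TMs, ECLs) and
replaces a chosen subset of the intracellular segments (ICL1-3, C-terminus)
with the acceptor receptor's — the full swap gives a DREADD-β2AR-style
chimera, the partial ICL2+ICL3 swap an rM3Ds-style one.  N-terminal
modifications for surface-expression read-out are prepended in the order
[Met] + signal peptide + VSV-G epitope + linker, and the donor's own
initiator Met is dropped so the only in-frame start is the construct's.

DNA assembly splices the native parent codons for every receptor segment
(CCDS-style ORFs), back-translates only the tag region, removes the donor's
original ATG, appends one stop codon, and finally adds unique restriction
sites as cloning flanks, recoding synonymously if a chosen site occurs
inside the ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codons import (
    SYNONYMOUS_CODONS,
    backtranslate_most_frequent,
    check_codon_table,
)
from .errors import AnnotationError, ConfigError, DesignError, ValidationError
from .records import (
    CdsRecord,
    DomainAnnotation,
    PROTEIN_ALPHABET,
    ProteinRecord,
    SIGNALING_LABELS,
    STOP_CODONS,
    translate_dna,
)

#: Recognition sites for the cloning flanks.
RESTRICTION_SITES = {"EcoRI": "GAATTC", "NotI": "GCGGCCGC", "BamHI": "GGATCC"}

ORIGIN_DONOR = "donor"
ORIGIN_ACCEPTOR = "acceptor"
ORIGIN_TAG = "tag"

#: Tag segment labels, in prepending order.
TAG_MET = "Met"
TAG_SIGNAL = "signal_peptide"
TAG_EPITOPE = "VSV-G"
TAG_LINKER = "DSL_linker"


def _check_peptide(name: str, seq: str) -> None:
    for ch in seq:
        if ch not in PROTEIN_ALPHABET:
            raise ValidationError(f"{name}: invalid residue {ch!r}")


@dataclass(frozen=True)
class NTerminalMods:
    """N-terminal modifications: signal peptide, epitope tag, linker.

    Defaults are the hemagglutinin-derived signal peptide, the VSV-G epitope
    and a DSL linker.  The printed signal peptide carries no initiator Met of
    its own, so the construct prepends one by default
    (``include_initiator_met``) — an ORF has to begin with ATG to express.
    """

    signal_peptide: str = "KTIIALSYIFCLVFA"
    epitope: str = "YTDIEMNRLGK"
    linker: str = "DSL"
    include_initiator_met: bool = True

    def __post_init__(self) -> None:
        _check_peptide("signal_peptide", self.signal_peptide)
        _check_peptide("epitope", self.epitope)
        _check_peptide("linker", self.linker)

    def tag_segments(self) -> list[tuple[str, str]]:
        """(label, peptide) pairs in prepending order, empty parts skipped."""
        parts = []
        if self.include_initiator_met:
            parts.append((TAG_MET, "M"))
        if self.signal_peptide:
            parts.append((TAG_SIGNAL, self.signal_peptide))
        if self.epitope:
            parts.append((TAG_EPITOPE, self.epitope))
        if self.linker:
            parts.append((TAG_LINKER, self.linker))
        return parts


@dataclass(frozen=True)
class ChimeraDesign:
    """Which signaling segments to take from the acceptor, plus the mods."""

    donor_id: str
    acceptor_id: str
    swap_set: frozenset[str]
    mods: NTerminalMods | None = NTerminalMods()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.swap_set:
            raise ValidationError("swap_set must be non-empty")
        bad = set(self.swap_set) - set(SIGNALING_LABELS)
        if bad:
            raise ValidationError(
                f"swap_set may only contain signaling segments; got {sorted(bad)}"
            )
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.donor_id}-{self.acceptor_id}"
            )


@dataclass(frozen=True)
class ProvenanceSegment:
    """One block of the chimera: its label, origin and coordinates.

    ``start``/``end`` are chimera protein coordinates; ``parent_start`` /
    ``parent_end`` locate receptor segments on their parent protein (None
    for tag blocks).
    """

    label: str
    origin: str
    start: int
    end: int
    parent_start: int | None = None
    parent_end: int | None = None


@dataclass
class ChimeraProtein:
    """A designed chimera with provenance tiling its sequence exactly."""

    name: str
    seq: str
    provenance: list[ProvenanceSegment]
    donor_id: str
    acceptor_id: str

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.provenance:
            if seg.start != pos or seg.end <= seg.start:
                raise ValidationError(
                    f"{self.name}: provenance does not tile the sequence at "
                    f"{seg.label} [{seg.start}, {seg.end})"
                )
            pos = seg.end
        if pos != len(self.seq):
            raise ValidationError(
                f"{self.name}: provenance covers {pos} of {len(self.seq)} residues"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def receptor_segments(self) -> list[ProvenanceSegment]:
        return [s for s in self.provenance if s.origin != ORIGIN_TAG]


@dataclass
class ConstructRecord:
    """Synthesis-ready DNA for a chimera, with features and optional flanks.

    ``orf_start``/``orf_end`` delimit the coding region including its stop
    codon; the invariant ``translate(ORF) == protein.seq`` is re-checked by
    :meth:`validate_coherence` after every transformation.
    """

    name: str
    dna: str
    features: list[tuple[str, int, int, str]]
    protein: ChimeraProtein
    orf_start: int = 0
    orf_end: int = 0
    enzymes_5p: str | None = None
    enzymes_3p: str | None = None

    @property
    def orf(self) -> str:
        return self.dna[self.orf_start : self.orf_end]

    def validate_coherence(self) -> None:
        orf = self.orf
        if len(orf) % 3 != 0:
            raise ValidationError(f"{self.name}: ORF length not divisible by 3")
        if orf[-3:] not in STOP_CODONS:
            raise ValidationError(f"{self.name}: ORF does not end in a stop codon")
        if translate_dna(orf[:-3]) != self.protein.seq:
            raise ValidationError(
                f"{self.name}: ORF translation does not match chimera protein"
            )


# --- protein-level assembly ------------------------------------------------


def assemble_protein(
    donor: tuple[ProteinRecord, DomainAnnotation],
    acceptor: tuple[ProteinRecord, DomainAnnotation],
    design: ChimeraDesign,
) -> ChimeraProtein:
    """Swap the designed signaling segments of the donor for the acceptor's.

    The donor annotation must tile the donor protein; the acceptor annotation
    must contain every swapped segment.  When mods are present the donor's
    initiator Met is dropped and [Met]+signal+epitope+linker is prepended.
    """
    donor_protein, donor_ann = donor
    acceptor_protein, acceptor_ann = acceptor
    if donor_ann.protein_length != len(donor_protein) or not donor_ann.tiles():
        raise AnnotationError(
            f"donor annotation must tile the donor protein {donor_protein.id!r}"
        )
    for label in sorted(design.swap_set):
        if not donor_ann.has(label):
            raise DesignError(f"donor lacks swap segment {label}")
        if not acceptor_ann.has(label):
            raise DesignError(f"acceptor lacks swap segment {label}")

    provenance: list[ProvenanceSegment] = []
    parts: list[str] = []
    pos = 0

    if design.mods is not None:
        for label, peptide in design.mods.tag_segments():
            provenance.append(
                ProvenanceSegment(label, ORIGIN_TAG, pos, pos + len(peptide))
            )
            parts.append(peptide)
            pos += len(peptide)

    drop_met = design.mods is not None and donor_protein.seq.startswith("M")
    for k, seg in enumerate(donor_ann.segments):
        if seg.label in design.swap_set:
            src = acceptor_ann.get(seg.label)
            peptide = acceptor_protein.seq[src.start : src.end]
            origin, p_start, p_end = ORIGIN_ACCEPTOR, src.start, src.end
        else:
            p_start, p_end = seg.start, seg.end
            if k == 0 and drop_met:
                p_start += 1  # donor's own initiator Met removed with mods
            peptide = donor_protein.seq[p_start:p_end]
            origin = ORIGIN_DONOR
        if not peptide:
            continue
        provenance.append(
            ProvenanceSegment(seg.label, origin, pos, pos + len(peptide), p_start, p_end)
        )
        parts.append(peptide)
        pos += len(peptide)

    return ChimeraProtein(
        name=design.name,
        seq="".join(parts),
        provenance=provenance,
        donor_id=design.donor_id,
        acceptor_id=design.acceptor_id,
    )


# --- DNA-level assembly ----------------------------------------------------


def map_protein_segments_to_cds(
    protein: ProteinRecord,
    annotation: DomainAnnotation,
    cds: CdsRecord,
) -> list[tuple[str, int, int]]:
    """Map each protein segment ``[a, b)`` to CDS coordinates ``[3a, 3b)``.

    Requires ``translate(cds) == protein.seq``; a mismatch is reported at the
    first differing residue.
    """
    translated = cds.translation()
    if translated != protein.seq:
        if len(translated) != len(protein.seq):
            raise ValidationError(
                f"{protein.id}: CDS translates to {len(translated)} residues, "
                f"protein has {len(protein.seq)}"
            )
        for i, (a, b) in enumerate(zip(translated, protein.seq)):
            if a != b:
                raise ValidationError(
                    f"{protein.id}: CDS translation mismatch at residue {i}: "
                    f"{a} != {b}"
                )
    return [(seg.label, 3 * seg.start, 3 * seg.end) for seg in annotation.segments]


def assemble_cds(
    donor_cds: CdsRecord,
    acceptor_cds: CdsRecord,
    chimera: ChimeraProtein,
    codon_table: str = "human-most-frequent",
    stop_codon: str = "TAA",
) -> ConstructRecord:
    """Splice the chimera's DNA from its parents' native codons.

    Receptor segments take the codons of their parent of origin; tag segments
    are back-translated with ``codon_table``; the donor's original initiator
    ATG is absent because the protein-level assembly already excluded that
    residue; one stop codon is appended.
    """
    check_codon_table(codon_table)
    if stop_codon not in STOP_CODONS:
        raise ConfigError(f"stop codon must be one of {sorted(STOP_CODONS)}")

    parent = {
        ORIGIN_DONOR: donor_cds.coding,
        ORIGIN_ACCEPTOR: acceptor_cds.coding,
    }
    blocks: list[str] = []
    features: list[tuple[str, int, int, str]] = []
    pos = 0
    for seg in chimera.provenance:
        peptide = chimera.seq[seg.start : seg.end]
        if seg.origin == ORIGIN_TAG:
            dna = backtranslate_most_frequent(peptide)
        else:
            coding = parent[seg.origin]
            dna = coding[3 * seg.parent_start : 3 * seg.parent_end]
            if translate_dna(dna) != peptide:
                raise ValidationError(
                    f"{chimera.name}: {seg.origin} CDS does not encode segment "
                    f"{seg.label}"
                )
        blocks.append(dna)
        features.append((seg.label, pos, pos + len(dna), seg.origin))
        pos += len(dna)
    blocks.append(stop_codon)

    construct = ConstructRecord(
        name=chimera.name,
        dna="".join(blocks),
        features=features,
        protein=chimera,
        orf_start=0,
        orf_end=pos + 3,
    )
    construct.validate_coherence()
    return construct


# --- restriction flanks ----------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, p = [], haystack.find(needle)
    while p != -1:
        hits.append(p)
        p = haystack.find(needle, p + 1)
    return hits


def _unwanted_sites(
    dna: str, sites: list[str], allowed: set[tuple[str, int]]
) -> list[tuple[str, int]]:
    found = []
    for site in sites:
        for p in _find_all(dna, site):
            if (site, p) not in allowed:
                found.append((site, p))
    return sorted(found, key=lambda t: (t[1], t[0]))


def _recode_site(
    dna: str,
    protein_seq: str,
    orf_start: int,
    orf_end: int,
    site: str,
    pos: int,
    sites: list[str],
    allowed: set[tuple[str, int]],
    synonymous_table: dict[str, list[str]],
) -> str | None:
    """Try synonymous alternatives at the codons a site spans; None if stuck."""
    import itertools

    lo = max(pos, orf_start)
    hi = min(pos + len(site), orf_end)
    if lo >= hi:
        return None  # site does not touch the ORF: nothing to recode
    c0 = (lo - orf_start) // 3
    c1 = (hi - 1 - orf_start) // 3
    n_res = len(protein_seq)

    def residue(ci: int) -> str:
        return protein_seq[ci] if ci < n_res else "*"

    options: list[list[str]] = []
    for ci in range(c0, c1 + 1):
        current = dna[orf_start + 3 * ci : orf_start + 3 * ci + 3]
        codons = synonymous_table.get(residue(ci), [current])
        ordered = [c for c in codons if c != current]
        options.append([current] + ordered)

    before = len(_unwanted_sites(dna, sites, allowed))
    for combo in itertools.product(*options):
        if all(c == o[0] for c, o in zip(combo, options)):
            continue  # unchanged
        candidate = (
            dna[: orf_start + 3 * c0]
            + "".join(combo)
            + dna[orf_start + 3 * (c1 + 1) :]
        )
        remaining = _unwanted_sites(candidate, sites, allowed)
        if (site, pos) not in remaining and len(remaining) < before:
            return candidate
    return None


def add_restriction_flanks(
    construct: ConstructRecord,
    five_prime: str = "EcoRI",
    three_prime: str = "BamHI",
    synonymous_table: dict[str, list[str]] | None = None,
) -> ConstructRecord:
    """Add unique cloning sites up- and downstream of the ORF.

    Each chosen enzyme's recognition site must occur exactly once in the
    final construct, in its flank.  Sites found inside the ORF are removed by
    exhaustive synonymous recoding of the spanned codons (translation is
    preserved by construction); an unresolvable site raises
    :class:`DesignError` listing the positions.  ``synonymous_table``
    overrides the default human table (e.g. to restrict the codon repertoire).
    """
    if five_prime not in ("EcoRI", "NotI"):
        raise ConfigError(f"5' enzyme must be EcoRI or NotI, got {five_prime!r}")
    if three_prime not in RESTRICTION_SITES:
        raise ConfigError(f"unknown 3' enzyme {three_prime!r}")
    if five_prime == three_prime:
        raise ConfigError("5' and 3' enzymes must differ")
    if construct.enzymes_5p is not None or construct.enzymes_3p is not None:
        raise ValidationError(f"{construct.name}: flanks already added")
    table = synonymous_table if synonymous_table is not None else SYNONYMOUS_CODONS

    site5 = RESTRICTION_SITES[five_prime]
    site3 = RESTRICTION_SITES[three_prime]
    sites = [site5, site3]

    dna = site5 + construct.dna + site3
    orf_start = construct.orf_start + len(site5)
    orf_end = construct.orf_end + len(site5)
    allowed = {(site5, 0), (site3, len(dna) - len(site3))}

    max_rounds = len(dna)  # generous; each round strictly removes a site
    for _ in range(max_rounds):
        bad = _unwanted_sites(dna, sites, allowed)
        if not bad:
            break
        site, pos = bad[0]
        recoded = _recode_site(
            dna, construct.protein.seq, orf_start, orf_end, site, pos,
            sites, allowed, table,
        )
        if recoded is None:
            positions = [p - len(site5) for _s, p in bad]
            raise DesignError(
                f"{construct.name}: internal {five_prime}/{three_prime} site(s) "
                f"at ORF position(s) {positions} cannot be removed by "
                f"synonymous recoding"
            )
        dna = recoded
    else:  # pragma: no cover - defensive
        raise DesignError(f"{construct.name}: site recoding did not converge")

    features = [
        (five_prime, 0, len(site5), "flank"),
        *[
            (label, start + len(site5), end + len(site5), origin)
            for label, start, end, origin in construct.features
        ],
        (three_prime, len(dna) - len(site3), len(dna), "flank"),
    ]
    out = ConstructRecord(
        name=construct.name,
        dna=dna,
        features=features,
        protein=construct.protein,
        orf_start=orf_start,
        orf_end=orf_end,
        enzymes_5p=five_prime,
        enzymes_3p=three_prime,
    )
    out.validate_coherence()
    for enzyme, site in ((five_prime, site5), (three_prime, site3)):
        count = len(_find_all(out.dna, site))
        if count != 1:  # pragma: no cover - guarded by the recoding loop
            raise DesignError(
                f"{construct.name}: {enzyme} site occurs {count} times"
            )
    return out
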