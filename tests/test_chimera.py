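"""Chimera assembly at protein and DNA level, and restriction flanks."""

import itertools

import pytest

from gpcrchimera.chimera import (
    ChimeraDesign,
    NTerminalMods,
    ORIGIN_ACCEPTOR,
    ORIGIN_DONOR,
    ORIGIN_TAG,
    RESTRICTION_SITES,
    add_restriction_flanks,
    assemble_cds,
    assemble_protein,
    map_protein_segments_to_cds,
)
from gpcrchimera.codons import SYNONYMOUS_CODONS
from gpcrchimera.errors import ConfigError, DesignError, ValidationError
from gpcrchimera.records import (
    CdsRecord,
    DomainAnnotation,
    ProteinRecord,
    Segment,
    translate_dna,
)
from gpcrchimera.synthetic import ToyGpcrSpec, back_translate, make_toy_gpcr

FULL_SWAP = frozenset({"ICL1", "ICL2", "ICL3", "C-term"})


def _toy_parent(seed):
    protein, ann = make_toy_gpcr(ToyGpcrSpec(seed=seed))
    return protein, ann


class TestAssembleProtein:
    def test_self_swap_without_mods_is_identity(self):
        donor = _toy_parent(20)
        design = ChimeraDesign("d", "d", FULL_SWAP, mods=None)
        chim = assemble_protein(donor, donor, design)
        assert chim.seq == donor[0].seq

    def test_manual_concatenation_on_tiny_receptor(self):
        # donor M AAA WWWWW RRR WWWWW KKK with labeled architecture
        donor_protein = ProteinRecord(id="d", seq="MAAAWWWWWRRRWWWWWKKK")
        donor_ann = DomainAnnotation(
            "d",
            [
                Segment("N-term", 0, 4),
                Segment("TM1", 4, 9),
                Segment("ICL1", 9, 12),
                Segment("TM2", 12, 17),
                Segment("C-term", 17, 20),
            ],
            20,
        )
        acceptor_protein = ProteinRecord(id="a", seq="MGGGFFFFFQQQQFFFFFHH")
        acceptor_ann = DomainAnnotation(
            "a",
            [
                Segment("N-term", 0, 4),
                Segment("TM1", 4, 9),
                Segment("ICL1", 9, 13),
                Segment("TM2", 13, 18),
                Segment("C-term", 18, 20),
            ],
            20,
        )
        design = ChimeraDesign("d", "a", frozenset({"ICL1"}), mods=None)
        chim = assemble_protein(
            (donor_protein, donor_ann), (acceptor_protein, acceptor_ann), design
        )
        assert chim.seq == "M" + "AAA" + "WWWWW" + "QQQQ" + "WWWWW" + "KKK"
        origins = {s.label: s.origin for s in chim.provenance}
        assert origins["ICL1"] == ORIGIN_ACCEPTOR
        assert origins["TM1"] == ORIGIN_DONOR

    def test_default_mods_prefix_is_signal_epitope_linker(self):
        donor, acceptor = _toy_parent(21), _toy_parent(22)
        design = ChimeraDesign("d", "a", FULL_SWAP)
        chim = assemble_protein(donor, acceptor, design)
        assert chim.seq.startswith("M" + "KTIIALSYIFCLVFA" + "YTDIEMNRLGK" + "DSL")
        tags = [s.label for s in chim.provenance if s.origin == ORIGIN_TAG]
        assert tags == ["Met", "signal_peptide", "VSV-G", "DSL_linker"]

    def test_donor_initiator_met_dropped_only_with_mods(self):
        donor, acceptor = _toy_parent(23), _toy_parent(24)
        with_mods = assemble_protein(
            donor, acceptor, ChimeraDesign("d", "a", FULL_SWAP)
        )
        nterm = next(s for s in with_mods.provenance if s.label == "N-term")
        assert nterm.parent_start == 1  # Met removed
        without = assemble_protein(
            donor, acceptor, ChimeraDesign("d", "a", FULL_SWAP, mods=None)
        )
        nterm = next(s for s in without.provenance if s.label == "N-term")
        assert nterm.parent_start == 0

    def test_length_conservation_identity(self):
        donor, acceptor = _toy_parent(25), _toy_parent(26)
        for swap in (FULL_SWAP, frozenset({"ICL2", "ICL3"})):
            chim = assemble_protein(donor, acceptor, ChimeraDesign("d", "a", swap))
            swapped_donor = sum(len(donor[1].get(l)) for l in swap)
            swapped_acceptor = sum(len(acceptor[1].get(l)) for l in swap)
            tags = 1 + 15 + 11 + 3  # Met + signal + VSV-G + DSL
            expected = (
                len(donor[0]) - swapped_donor + swapped_acceptor + tags - 1
            )  # −1: donor's own Met dropped
            assert len(chim) == expected

    def test_provenance_tiles_sequence(self):
        donor, acceptor = _toy_parent(27), _toy_parent(28)
        chim = assemble_protein(donor, acceptor, ChimeraDesign("d", "a", FULL_SWAP))
        pos = 0
        for seg in chim.provenance:
            assert seg.start == pos
            pos = seg.end
        assert pos == len(chim)

    def test_partial_swap_matches_rm3ds_style(self):
        donor, acceptor = _toy_parent(29), _toy_parent(30)
        design = ChimeraDesign("d", "a", frozenset({"ICL2", "ICL3"}), mods=None)
        chim = assemble_protein(donor, acceptor, design)
        acceptor_labels = [
            s.label for s in chim.receptor_segments() if s.origin == ORIGIN_ACCEPTOR
        ]
        assert acceptor_labels == ["ICL2", "ICL3"]

    def test_swap_applied_twice_is_idempotent(self):
        donor, acceptor = _toy_parent(31), _toy_parent(32)
        design = ChimeraDesign("d", "a", FULL_SWAP, mods=None)
        once = assemble_protein(donor, acceptor, design)
        # rebuild an annotation for the chimera from its provenance
        ann = DomainAnnotation(
            "chimera",
            [Segment(s.label, s.start, s.end) for s in once.provenance],
            len(once),
        )
        twice = assemble_protein(
            (ProteinRecord(id="chimera", seq=once.seq), ann), acceptor, design
        )
        assert twice.seq == once.seq

    def test_missing_segment_is_design_error_naming_it(self):
        donor = _toy_parent(33)
        protein, ann = _toy_parent(34)
        truncated = DomainAnnotation(
            protein.id,
            [s for s in ann.segments if s.label != "ICL3"],
            len(protein),
        )
        with pytest.raises(DesignError, match="ICL3"):
            assemble_protein(
                donor, (protein, truncated), ChimeraDesign("d", "a", FULL_SWAP)
            )

    def test_empty_swap_set_rejected(self):
        with pytest.raises(ValidationError):
            ChimeraDesign("d", "a", frozenset())


class TestMapProteinSegmentsToCds:
    def test_codon_coordinate_arithmetic(self):
        protein, ann = _toy_parent(40)
        cds = back_translate(protein, seed=1)
        mapping = dict(
            (label, (a, b)) for label, a, b in map_protein_segments_to_cds(protein, ann, cds)
        )
        for seg in ann.segments:
            assert mapping[seg.label] == (3 * seg.start, 3 * seg.end)

    def test_synonymous_codon_change_still_passes(self):
        protein, ann = _toy_parent(41)
        cds = back_translate(protein, seed=2)
        # swap a codon for a synonymous alternative (residue 1: polar, so
        # never the single-codon Met)
        aa = protein.seq[1]
        alternative = next(c for c in SYNONYMOUS_CODONS[aa] if c != cds.seq[3:6])
        mutated = CdsRecord(
            protein.id, cds.seq[:3] + alternative + cds.seq[6:], has_stop=True
        )
        assert map_protein_segments_to_cds(protein, ann, mutated)

    def test_missense_codon_reports_residue(self):
        protein, ann = _toy_parent(42)
        cds = back_translate(protein, seed=3)
        residue = 5
        wrong_aa = "W" if protein.seq[residue] != "W" else "C"
        wrong = SYNONYMOUS_CODONS[wrong_aa][0]
        mutated = CdsRecord(
            protein.id,
            cds.seq[: 3 * residue] + wrong + cds.seq[3 * residue + 3 :],
            has_stop=True,
        )
        with pytest.raises(ValidationError, match=f"residue {residue}"):
            map_protein_segments_to_cds(protein, ann, mutated)

    def test_concatenated_blocks_translate_back(self):
        protein, ann = _toy_parent(43)
        cds = back_translate(protein, seed=4)
        blocks = [
            cds.seq[a:b] for _label, a, b in map_protein_segments_to_cds(protein, ann, cds)
        ]
        assert translate_dna("".join(blocks)) == protein.seq


class TestAssembleCds:
    def _chimera(self, swap=FULL_SWAP, mods=NTerminalMods()):
        donor, acceptor = _toy_parent(50), _toy_parent(51)
        chim = assemble_protein(donor, acceptor, ChimeraDesign("d", "a", swap, mods))
        return donor, acceptor, chim

    def test_orf_translation_equals_chimera(self):
        donor, acceptor, chim = self._chimera()
        construct = assemble_cds(
            back_translate(donor[0], seed=10), back_translate(acceptor[0], seed=11), chim
        )
        assert translate_dna(construct.orf[:-3]) == chim.seq

    def test_spliced_blocks_keep_parent_codons(self):
        """Parents with distinguishable synonymous styles stay distinguishable."""
        donor, acceptor, chim = self._chimera()
        donor_cds = back_translate(donor[0])  # most-frequent style
        acceptor_cds = back_translate(acceptor[0], seed=99)  # sampled style
        construct = assemble_cds(donor_cds, acceptor_cds, chim)
        for feat_label, start, end, origin in construct.features:
            seg = next(s for s in chim.provenance if s.label == feat_label)
            block = construct.dna[start:end]
            if origin == ORIGIN_DONOR:
                assert block == donor_cds.coding[3 * seg.parent_start : 3 * seg.parent_end]
            elif origin == ORIGIN_ACCEPTOR:
                assert (
                    block
                    == acceptor_cds.coding[3 * seg.parent_start : 3 * seg.parent_end]
                )

    def test_single_inframe_start_and_donor_atg_absent_at_junction(self):
        donor, acceptor, chim = self._chimera()
        donor_cds = back_translate(donor[0], seed=12)
        construct = assemble_cds(donor_cds, back_translate(acceptor[0], seed=13), chim)
        # exactly one in-frame ATG-initiated start: the construct's own
        assert construct.dna[:3] == "ATG"
        nterm = next(f for f in construct.features if f[0] == "N-term")
        # the donor's original first codon (its ATG) is absent from the junction
        assert construct.dna[nterm[1] : nterm[1] + 3] != donor_cds.seq[:3]
        seg = next(s for s in chim.provenance if s.label == "N-term")
        assert seg.parent_start == 1

    def test_stop_codon_appended_and_configurable(self):
        donor, acceptor, chim = self._chimera()
        construct = assemble_cds(
            back_translate(donor[0], seed=14),
            back_translate(acceptor[0], seed=15),
            chim,
            stop_codon="TGA",
        )
        assert construct.dna.endswith("TGA")
        with pytest.raises(ConfigError):
            assemble_cds(
                back_translate(donor[0], seed=14),
                back_translate(acceptor[0], seed=15),
                chim,
                stop_codon="AAA",
            )

    def test_unknown_codon_table_is_config_error(self):
        donor, acceptor, chim = self._chimera()
        with pytest.raises(ConfigError):
            assemble_cds(
                back_translate(donor[0]), back_translate(acceptor[0]), chim,
                codon_table="klingon",
            )


def _search_all_synonymous(dna, protein_seq, sites, table):
    """Exhaustive oracle: does any synonymous encoding of the spanned codons
    remove all internal sites?"""
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    residues = list(protein_seq) + ["*"]
    options = [table.get(aa, [c]) for aa, c in zip(residues, codons)]
    for combo in itertools.product(*options):
        candidate = "".join(combo)
        if not any(site in candidate for site in sites):
            return True
    return False


class TestRestrictionFlanks:
    def _construct(self, seed=60):
        donor, acceptor = _toy_parent(seed), _toy_parent(seed + 1)
        chim = assemble_protein(donor, acceptor, ChimeraDesign("d", "a", FULL_SWAP))
        return assemble_cds(
            back_translate(donor[0], seed=seed), back_translate(acceptor[0], seed=seed + 1), chim
        )

    def test_clean_orf_gains_exactly_flank_lengths(self):
        construct = self._construct()
        for enz5, extra in (("EcoRI", 6), ("NotI", 8)):
            flanked = add_restriction_flanks(construct, enz5, "BamHI")
            assert len(flanked.dna) == len(construct.dna) + extra + 6
            assert flanked.dna.startswith(RESTRICTION_SITES[enz5])
            assert flanked.dna.endswith(RESTRICTION_SITES["BamHI"])

    def test_each_site_exactly_once_and_outside_orf(self):
        for seed in (60, 62, 64, 66):
            flanked = add_restriction_flanks(self._construct(seed))
            for enz in ("EcoRI", "BamHI"):
                site = RESTRICTION_SITES[enz]
                assert flanked.dna.count(site) == 1
                assert site not in flanked.orf
            flanked.validate_coherence()

    def test_internal_site_recoded_synonymously(self):
        # engineer a construct whose ORF contains one internal BamHI site:
        # Gly-Ser encoded GGA+TCC spells GGATCC and has synonymous escapes
        protein = ProteinRecord(id="p", seq="MGSKLV")
        dna = "ATG" + "GGA" + "TCC" + "AAA" + "CTG" + "GTG" + "TAA"
        assert "GGATCC" in dna
        from gpcrchimera.chimera import ChimeraProtein, ConstructRecord, ProvenanceSegment

        chim = ChimeraProtein(
            "p", protein.seq,
            [ProvenanceSegment("N-term", ORIGIN_DONOR, 0, 6, 0, 6)], "d", "a",
        )
        construct = ConstructRecord(
            name="p", dna=dna, features=[("N-term", 0, 18, ORIGIN_DONOR)],
            protein=chim, orf_start=0, orf_end=21,
        )
        flanked = add_restriction_flanks(construct, "EcoRI", "BamHI")
        assert flanked.dna.count("GGATCC") == 1  # only the 3' flank
        assert translate_dna(flanked.orf[:-3]) == protein.seq
        # oracle agrees an escape exists
        assert _search_all_synonymous(
            dna, protein.seq, ["GGATCC", "GAATTC"], SYNONYMOUS_CODONS
        )

    def test_unresolvable_site_is_design_error(self):
        # restrict the codon repertoire so no synonymous escape exists, and
        # confirm the exhaustive oracle agrees before asserting the error
        protein = ProteinRecord(id="p", seq="MGSKX".replace("X", "V"))
        dna = "ATG" + "GGA" + "TCC" + "AAA" + "GTG" + "TAA"
        restricted = {aa: codons[:1] for aa, codons in SYNONYMOUS_CODONS.items()}
        restricted["G"] = ["GGA"]
        restricted["S"] = ["TCC"]
        assert not _search_all_synonymous(
            dna, protein.seq, ["GGATCC", "GAATTC"], restricted
        )
        from gpcrchimera.chimera import ChimeraProtein, ConstructRecord, ProvenanceSegment

        chim = ChimeraProtein(
            "p", protein.seq,
            [ProvenanceSegment("N-term", ORIGIN_DONOR, 0, 5, 0, 5)], "d", "a",
        )
        construct = ConstructRecord(
            name="p", dna=dna, features=[("N-term", 0, 15, ORIGIN_DONOR)],
            protein=chim, orf_start=0, orf_end=18,
        )
        with pytest.raises(DesignError, match="cannot be removed"):
            add_restriction_flanks(
                construct, "EcoRI", "BamHI", synonymous_table=restricted
            )

    def test_flanks_cannot_be_added_twice(self):
        flanked = add_restriction_flanks(self._construct())
        with pytest.raises(ValidationError):
            add_restriction_flanks(flanked)

    def test_same_enzyme_both_ends_rejected(self):
        with pytest.raises(ConfigError):
            add_restriction_flanks(self._construct(), "EcoRI", "EcoRI")
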