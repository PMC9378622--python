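"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive expected results by the dumbest possible
means (per-residue label transfer, exhaustive alignment enumeration, loop
arithmetic) so they stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from gpcrchimera.alignment import AlignedPair, ReferenceAnnotation
from gpcrchimera.records import DomainAnnotation, Segment
from gpcrchimera.synthetic import (
    ToyGpcrSpec,
    back_translate,
    make_toy_gpcr,
    make_toy_reference,
)


# --- oracles ---------------------------------------------------------------


def label_transfer_oracle(
    ref_ann: ReferenceAnnotation, pair: AlignedPair
) -> list[tuple[str, int, int]]:
    """Brute-force per-column label transfer plus the documented snapping.

    Each target residue takes the segment label of the reference residue in
    its column; unassigned residues (reference-gap columns) join the previous
    labelled residue's segment, and a leading unassigned run takes the first
    label seen.  Returns (label, start, end) triples.
    """
    ref_pos, qry_pos, ri, qi = [], [], 0, 0
    for r, q in zip(pair.ref_aln, pair.qry_aln):
        ref_pos.append(ri if r != "-" else None)
        qry_pos.append(qi if q != "-" else None)
        ri += r != "-"
        qi += q != "-"

    def segment_of(rp: int) -> str | None:
        for seg in ref_ann.annotation.segments:
            if seg.start <= rp < seg.end:
                return seg.label
        return None

    labels: list[str | None] = [None] * qi
    for rp, qp in zip(ref_pos, qry_pos):
        if rp is not None and qp is not None:
            labels[qp] = segment_of(rp)

    first = next((lab for lab in labels if lab is not None), None)
    if first is None:
        return []
    for i in range(len(labels)):
        if labels[i] is None and i > 0 and labels[i - 1] is not None:
            labels[i] = labels[i - 1]
    i = 0
    while i < len(labels) and labels[i] is None:
        labels[i] = first
        i += 1

    out: list[list] = []
    for i, lab in enumerate(labels):
        if out and out[-1][0] == lab:
            out[-1][2] = i + 1
        else:
            out.append([lab, i, i + 1])
    return [(lab, s, e) for lab, s, e in out]


def window_hydropathy_runs(
    seq: str, scale: dict[str, float], window: int, threshold: float
) -> list[tuple[int, int]]:
    """Direct window-sum oracle: centres whose mean exceeds the threshold."""
    half = window // 2
    flags = []
    for c in range(half, len(seq) - half):
        mean = sum(scale[ch] for ch in seq[c - half : c + half + 1]) / window
        flags.append((c, mean > threshold))
    runs: list[list[int]] = []
    for c, on in flags:
        if not on:
            continue
        if runs and c == runs[-1][1]:
            runs[-1][1] = c + 1
        else:
            runs.append([c, c + 1])
    return [(s, e) for s, e in runs]


def enumerate_alignment_scores(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by exhaustive recursion (tiny inputs only)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 start/match, 1 gap run consuming b, 2 gap run consuming a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(float(sub[a[i], b[j]]) + best(i + 1, j + 1, 0))
        if j < len(b):
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i, j + 1, 1))
        if i < len(a):
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i + 1, j, 2))
        return max(options)

    return best(0, 0, 0)


# --- fixtures --------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_gpcr():
    """One toy 7TM protein with its exact ground-truth annotation."""
    return make_toy_gpcr(ToyGpcrSpec(seed=7))


@pytest.fixture(scope="session")
def toy_family():
    """Reference + donor + acceptor toy receptors with matching CDS."""
    ref_protein, reference = make_toy_reference(ToyGpcrSpec(seed=42))
    donor_protein, donor_ann = make_toy_gpcr(ToyGpcrSpec(seed=43))
    acceptor_protein, acceptor_ann = make_toy_gpcr(ToyGpcrSpec(seed=44))
    return {
        "reference": reference,
        "ref_protein": ref_protein,
        "donor": (donor_protein, donor_ann),
        "acceptor": (acceptor_protein, acceptor_ann),
        "donor_cds": back_translate(donor_protein, seed=430),
        "acceptor_cds": back_translate(acceptor_protein, seed=440),
        "ref_cds": back_translate(ref_protein, seed=420),
    }


@pytest.fixture
def tiny_annotation():
    """Hand-written three-segment annotation on a 13-residue toy protein."""
    segments = [
        Segment("N-term", 0, 4),
        Segment("TM1", 4, 9),
        Segment("ICL1", 9, 13),
    ]
    return DomainAnnotation("tinyref", segments, protein_length=13)
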