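"""Transmembrane-helix prediction and the flanking consistency check.

The alignment-derived annotation is verified against an independent source of
topology: predicted TM helices should tightly flank the intracellular loops
and the C-terminus.  A built-in Kyte–Doolittle hydropathy predictor stands in
for an external tool, and externally computed TM intervals (TMHMM-style
tables) can be ingested instead.

A helix is the maximal run of residues whose centred sliding-window mean
hydropathy exceeds the threshold; runs separated by fewer than ``merge_gap``
residues are merged and runs shorter than ``min_len`` are discarded.  The
defaults (window 19, threshold 1.6, minimum length 15) are the standard
Kyte–Doolittle settings for membrane-spanning segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .records import DomainAnnotation, ProteinRecord, SIGNALING_LABELS

#: Kyte–Doolittle hydropathy scale (X treated as neutral).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

MISSING = "MISSING"
NA = "NA"

VERDICT_SEAMLESS = "seamless"
VERDICT_MINOR = "minor-deviation"
VERDICT_FAIL = "fail"


class TopologyWarning(UserWarning):
    """Sequence too short to scan; an empty prediction was returned."""


@dataclass
class TmPrediction:
    """Predicted membrane-spanning intervals on one protein (0-based, half-open)."""

    protein_id: str
    helices: list[tuple[int, int]]
    source: str = "builtin-hydropathy"

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.helices:
            if start >= end:
                raise ValidationError(
                    f"{self.protein_id}: empty helix interval [{start}, {end})"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"{self.protein_id}: helix intervals overlap or are unsorted "
                    f"at [{start}, {end})"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.helices)


def predict_tm(
    protein: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    merge_gap: int = 3,
) -> TmPrediction:
    """Predict TM helices by sliding-window Kyte–Doolittle hydropathy.

    Deterministic.  Returns an empty prediction (with a warning) when the
    sequence is shorter than the window.
    """
    if window % 2 != 1 or window < 3:
        raise ValidationError(f"window must be an odd integer >= 3, got {window}")
    seq = protein.seq
    if len(seq) < window:
        warnings.warn(
            f"{protein.id}: sequence length {len(seq)} < window {window}; "
            f"no prediction",
            TopologyWarning,
            stacklevel=2,
        )
        return TmPrediction(protein.id, [])

    values = np.array([KYTE_DOOLITTLE[ch] for ch in seq])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")  # means[k] centred at k + w//2
    half = window // 2
    above = means > threshold
    centers = np.flatnonzero(above) + half

    runs: list[list[int]] = []
    for c in centers.tolist():
        if runs and c == runs[-1][1]:
            runs[-1][1] = c + 1
        else:
            runs.append([c, c + 1])

    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    helices = [(s, e) for s, e in merged if e - s >= min_len]
    return TmPrediction(protein.id, helices)


# --- external predictions --------------------------------------------------


def write_tm_table(predictions: list[TmPrediction], path: str) -> None:
    """Write TM intervals as a TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\n")
        for pred in predictions:
            for start, end in pred.helices:
                fh.write(f"{pred.protein_id}\t{start + 1}\t{end}\n")


def ingest_tm_table(path: str, protein_id: str | None = None) -> TmPrediction:
    """Read one protein's TM intervals from an id/start/end TSV (1-based incl.).

    ``protein_id`` selects one protein from a multi-protein table; omit it for
    a single-protein table.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing_cols = {"id", "start", "end"} - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing column(s) {sorted(missing_cols)}")
    if protein_id is None:
        ids = df["id"].unique()
        if len(ids) != 1:
            raise ValidationError(
                f"{path}: table holds {len(ids)} proteins; pass protein_id"
            )
        protein_id = str(ids[0])
    sub = df[df["id"] == protein_id]
    helices = sorted(
        (int(row.start) - 1, int(row.end)) for row in sub.itertuples()
    )
    return TmPrediction(protein_id, helices, source="external")


# --- flanking check --------------------------------------------------------


@dataclass(frozen=True)
class FlankingRecord:
    """Flanking gaps for one signaling segment.

    ``upstream_gap``/``downstream_gap`` are residue distances between the
    segment boundary and the paired predicted helix; the strings ``MISSING``
    (no helix pairs with the required side) and ``NA`` (not applicable: the
    C-terminus has no downstream helix) replace the integer where needed.
    """

    label: str
    upstream_gap: int | str
    downstream_gap: int | str
    verdict: str


@dataclass
class FlankingReport:
    protein_id: str
    records: list[FlankingRecord]

    def verdicts(self) -> dict[str, str]:
        return {r.label: r.verdict for r in self.records}

    def all_ok(self) -> bool:
        return all(r.verdict != VERDICT_FAIL for r in self.records)


_ADJACENT_TM = {
    "ICL1": ("TM1", "TM2"),
    "ICL2": ("TM3", "TM4"),
    "ICL3": ("TM5", "TM6"),
    "C-term": ("TM7", None),
}


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _paired_helix(
    annotation: DomainAnnotation,
    helices: list[tuple[int, int]],
    tm_label: str | None,
    side_anchor: int,
    side: str,
) -> tuple[int, int] | None:
    """Find the predicted helix standing for ``tm_label``.

    When the annotation carries the TM segment, the predicted helix must
    overlap its interval (no overlap → the TM is missing from the prediction,
    the GPR109A-style failure).  Without annotated TMs, fall back to the
    nearest helix on the required side of the anchor boundary.
    """
    if tm_label is None:
        return None
    seg = annotation.get(tm_label)
    if seg is not None:
        candidates = [h for h in helices if _overlap(h, (seg.start, seg.end)) > 0]
        if not candidates:
            return None
        return max(candidates, key=lambda h: _overlap(h, (seg.start, seg.end)))
    if side == "up":
        candidates = [h for h in helices if h[0] < side_anchor]
        return max(candidates, key=lambda h: h[1]) if candidates else None
    candidates = [h for h in helices if h[1] > side_anchor]
    return min(candidates, key=lambda h: h[0]) if candidates else None


def check_flanking(
    annotation: DomainAnnotation,
    tm: TmPrediction,
    seamless_tol: int = 0,
    minor_tol: int = 5,
) -> FlankingReport:
    """Check that predicted TMs tightly flank the signaling segments.

    For each ICL the upstream gap is the distance between the paired upstream
    helix end and the segment start, the downstream gap between segment end
    and the paired downstream helix start; the C-terminus has an upstream gap
    only.  Verdicts: ``seamless`` when all gaps ≤ ``seamless_tol``,
    ``minor-deviation`` when all ≤ ``minor_tol``, ``fail`` otherwise or when
    a required helix is MISSING.
    """
    present = [lbl for lbl in SIGNALING_LABELS if annotation.has(lbl)]
    if not present:
        raise ValidationError(
            f"{annotation.protein_id}: annotation has no signaling segment"
        )
    records: list[FlankingRecord] = []
    for label in present:
        seg = annotation.get(label)
        up_label, down_label = _ADJACENT_TM[label]
        up = _paired_helix(annotation, tm.helices, up_label, seg.start, "up")
        down = _paired_helix(annotation, tm.helices, down_label, seg.end, "down")

        up_gap: int | str = MISSING if up is None else int(abs(seg.start - up[1]))
        if label == "C-term":
            down_gap: int | str = NA
        else:
            down_gap = MISSING if down is None else int(abs(down[0] - seg.end))

        gaps = [g for g in (up_gap, down_gap) if isinstance(g, int)]
        any_missing = up_gap == MISSING or down_gap == MISSING
        if any_missing:
            verdict = VERDICT_FAIL
        elif all(g <= seamless_tol for g in gaps):
            verdict = VERDICT_SEAMLESS
        elif all(g <= minor_tol for g in gaps):
            verdict = VERDICT_MINOR
        else:
            verdict = VERDICT_FAIL
        records.append(FlankingRecord(label, up_gap, down_gap, verdict))
    return FlankingReport(annotation.protein_id, records)


def write_flanking_report_tsv(reports: list[FlankingReport], path: str, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tsegment\tupstream_gap\tdownstream_gap\tverdict\n")
        for rep in reports:
            for r in rep.records:
                fh.write(
                    f"{rep.protein_id}\t{r.label}\t{r.upstream_gap}\t"
                    f"{r.downstream_gap}\t{r.verdict}\n"
                )
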