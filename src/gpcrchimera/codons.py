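"""Codon usage tables and back-translation helpers.

Receptor segments of a construct always keep their native parent codons; only
tag regions (signal peptide, epitope, linker, initiator Met) and the appended
stop are back-translated, using a most-frequent-human-codon table by default.
The per-codon human usage fractions below are the commonly tabulated values;
only their ranking matters here (deterministic choices, alphabetical
tie-break), not their exact magnitudes.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError

#: Human codon usage fractions per amino acid (stop = '*').
CODON_FREQUENCY: dict[str, float] = {
    # Phe / Leu
    "TTT": 0.46, "TTC": 0.54,
    "TTA": 0.08, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.07, "CTG": 0.40,
    # Ile / Met
    "ATT": 0.36, "ATC": 0.47, "ATA": 0.17, "ATG": 1.00,
    # Val
    "GTT": 0.18, "GTC": 0.24, "GTA": 0.12, "GTG": 0.46,
    # Ser
    "TCT": 0.19, "TCC": 0.22, "TCA": 0.15, "TCG": 0.05, "AGT": 0.15, "AGC": 0.24,
    # Pro
    "CCT": 0.29, "CCC": 0.32, "CCA": 0.28, "CCG": 0.11,
    # Thr
    "ACT": 0.25, "ACC": 0.36, "ACA": 0.28, "ACG": 0.11,
    # Ala
    "GCT": 0.27, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11,
    # Tyr / stop
    "TAT": 0.44, "TAC": 0.56, "TAA": 0.30, "TAG": 0.24, "TGA": 0.47,
    # His / Gln
    "CAT": 0.42, "CAC": 0.58, "CAA": 0.27, "CAG": 0.73,
    # Asn / Lys
    "AAT": 0.47, "AAC": 0.53, "AAA": 0.43, "AAG": 0.57,
    # Asp / Glu
    "GAT": 0.46, "GAC": 0.54, "GAA": 0.42, "GAG": 0.58,
    # Cys / Trp
    "TGT": 0.46, "TGC": 0.54, "TGG": 1.00,
    # Arg
    "CGT": 0.08, "CGC": 0.18, "CGA": 0.11, "CGG": 0.20, "AGA": 0.21, "AGG": 0.21,
    # Gly
    "GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25,
}

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S", "AGT": "S", "AGC": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*", "TGA": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _build_synonymous() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_CODE.items():
        table.setdefault(aa, []).append(codon)
    # frequency-descending, alphabetical tie-break, deterministic
    for aa in table:
        table[aa].sort(key=lambda c: (-CODON_FREQUENCY[c], c))
    return table


#: amino acid (or '*') → codons ordered by descending human usage.
SYNONYMOUS_CODONS: dict[str, list[str]] = _build_synonymous()

#: amino acid → single most frequent human codon.
MOST_FREQUENT: dict[str, str] = {aa: codons[0] for aa, codons in SYNONYMOUS_CODONS.items()}

CODON_TABLES = ("human-most-frequent",)


def check_codon_table(name: str) -> None:
    if name not in CODON_TABLES:
        raise ConfigError(
            f"unknown codon table {name!r}; available: {', '.join(CODON_TABLES)}"
        )


def backtranslate_most_frequent(peptide: str) -> str:
    """Deterministic back-translation with the most frequent human codons."""
    try:
        return "".join(MOST_FREQUENT[aa] for aa in peptide)
    except KeyError as exc:
        raise ConfigError(f"cannot back-translate residue {exc.args[0]!r}") from exc


def backtranslate_sampled(peptide: str, rng: np.random.Generator) -> str:
    """Seedable back-translation sampling codons by their usage fractions."""
    out: list[str] = []
    for aa in peptide:
        codons = SYNONYMOUS_CODONS.get(aa)
        if codons is None:
            raise ConfigError(f"cannot back-translate residue {aa!r}")
        weights = np.array([CODON_FREQUENCY[c] for c in codons])
        out.append(codons[rng.choice(len(codons), p=weights / weights.sum())])
    return "".join(out)
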