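"""Standard genetic code and codon-position degeneracy classification."""

from __future__ import annotations

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "BASES",
    "classify_degeneracy",
    "translate_codon",
]

BASES = ("A", "C", "G", "T")

# Standard (NCBI table 1) genetic code.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) encoded by ``codon``."""
    return GENETIC_CODE[codon.upper()]


def classify_degeneracy(codon: str, position: int) -> str:
    """Classify a codon position as ``0fold``, ``2fold`` or ``4fold``.

    Degeneracy is the number of alternative bases at ``position`` (1-based,
    1..3) that preserve the encoded amino acid: 0 alternatives -> ``0fold``,
    3 -> ``4fold``, anything in between -> ``2fold`` (3-fold degenerate
    third positions of Ile are binned with 2-fold by convention).

    Raises ``ValueError`` for stop codons or codons containing anything
    other than A/C/G/T; callers are expected to exclude such sites.
    """
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1..3, got {position}")
    if codon not in GENETIC_CODE:
        raise ValueError(f"unclassifiable codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no degeneracy class")
    aa = GENETIC_CODE[codon]
    i = position - 1
    n_preserving = sum(
        1
        for b in BASES
        if b != codon[i] and GENETIC_CODE[codon[:i] + b + codon[i + 1:]] == aa
    )
    if n_preserving == 0:
        return "0fold"
    if n_preserving == 3:
        return "4fold"
    return "2fold"
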