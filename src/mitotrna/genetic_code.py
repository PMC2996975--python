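"""Vertebrate mitochondrial genetic code (translation table 2) and the
codon-family -> tRNA decoding map.

The 22 mitochondrial tRNAs partition the 60 sense codons into 8 four-codon
family boxes (read by a single tRNA via wobble) and 14 two-codon sets.
AGA/AGG are stop codons in the vertebrate mitochondrial code, so tRNA-Ser2
reads only AGY; AUA is Met and UGA is Trp.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]

STOP_CODONS: frozenset[str] = frozenset(_TABLE2.stop_codons)  # TAA TAG AGA AGG
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE2.forward_table))
CODON_TO_AA: dict[str, str] = dict(_TABLE2.forward_table)  # one-letter AA

assert len(SENSE_CODONS) == 60 and len(STOP_CODONS) == 4

#: Canonical labels of the 22 vertebrate mt-tRNAs. Leu1 reads UUR, Leu2 CUN,
#: Ser1 UCN, Ser2 AGY.
CANONICAL_TRNAS: tuple[str, ...] = (
    "Phe", "Val", "Leu1", "Leu2", "Ile", "Met", "Trp", "Ala", "Gly", "Pro",
    "Ser1", "Ser2", "Glu", "Asp", "Lys", "Arg", "Tyr", "Cys", "Asn", "His",
    "Gln", "Thr",
)

TRNA_TO_AA1: dict[str, str] = {
    "Phe": "F", "Val": "V", "Leu1": "L", "Leu2": "L", "Ile": "I", "Met": "M",
    "Trp": "W", "Ala": "A", "Gly": "G", "Pro": "P", "Ser1": "S", "Ser2": "S",
    "Glu": "E", "Asp": "D", "Lys": "K", "Arg": "R", "Tyr": "Y", "Cys": "C",
    "Asn": "N", "His": "H", "Gln": "Q", "Thr": "T",
}

AA1_TO_AA3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

#: Residues treated as hydrophobic throughout the analysis.
HYDROPHOBIC_AA1: frozenset[str] = frozenset("FVLIMWAGP")

HYDROPHOBIC_TRNAS: frozenset[str] = frozenset(
    t for t, a in TRNA_TO_AA1.items() if a in HYDROPHOBIC_AA1
)
HYDROPHILIC_TRNAS: frozenset[str] = frozenset(CANONICAL_TRNAS) - HYDROPHOBIC_TRNAS
assert len(HYDROPHOBIC_TRNAS) == 10 and len(HYDROPHILIC_TRNAS) == 12


def _build_codon_to_trna() -> dict[str, str]:
    mapping: dict[str, str] = {}
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        if aa == "L":
            label = "Leu1" if codon in ("TTA", "TTG") else "Leu2"
        elif aa == "S":
            label = "Ser2" if codon.startswith("AG") else "Ser1"
        else:
            # Every other amino acid is decoded by a single mt-tRNA.
            label = {v: k for k, v in TRNA_TO_AA1.items()
                     if k not in ("Leu1", "Leu2", "Ser1", "Ser2")}[aa]
        mapping[codon] = label
    return mapping


#: Decoding map: DNA sense codon (coding-strand) -> canonical tRNA label.
CODON_TO_TRNA: dict[str, str] = _build_codon_to_trna()

TRNA_TO_CODONS: dict[str, tuple[str, ...]] = {
    label: tuple(sorted(c for c, t in CODON_TO_TRNA.items() if t == label))
    for label in CANONICAL_TRNAS
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
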