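"""Codon usage over the 13 mitochondrial protein-coding genes.

Each CDS is read in its own frame from its own 5' start (L-strand genes
reverse-complemented first); bases shared by overlapping genes (ATP8/ATP6,
ND4L/ND4) are counted once *per gene*, in each gene's own frame. Complete
stop codons and incomplete terminal codons (polyadenylation-completed stops)
contribute nothing, since no tRNA decodes them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .genetic_code import (
    CANONICAL_TRNAS,
    CODON_TO_AA,
    CODON_TO_TRNA,
    HYDROPHOBIC_AA1,
    HYDROPHOBIC_TRNAS,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
)
from .model import MitoError, MtGenomeRecord

__all__ = [
    "CodonCountTable",
    "TrnaUsage",
    "AminoAcidFrequencySet",
    "count_codons",
    "codons_of_cds",
    "trna_usage",
    "hydrophobic_fraction",
    "classify_trna",
    "MTREV",
    "JTT",
    "write_usage_table",
]


@dataclass
class CodonCountTable:
    per_gene: dict[str, dict[str, int]]
    aggregate: dict[str, int]
    total_sense: int


@dataclass
class TrnaUsage:
    """Per-tRNA codon-family usage: raw count and relative frequency."""

    per_trna: dict[str, tuple[int, float]]

    @property
    def counts(self) -> dict[str, int]:
        return {t: c for t, (c, _) in self.per_trna.items()}

    @property
    def rel_freq(self) -> dict[str, float]:
        return {t: f for t, (_, f) in self.per_trna.items()}


@dataclass(frozen=True)
class AminoAcidFrequencySet:
    name: str
    freq: Mapping[str, float]  # one-letter code -> fraction

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if not math.isclose(total, 1.0, abs_tol=1e-3):
            raise MitoError(f"{self.name}: frequencies sum to {total}, not 1")


def codons_of_cds(record: MtGenomeRecord, label: str) -> list[str]:
    """The coding-strand codon walk of one CDS (stops included, tail dropped)."""
    feats = [f for f in record.features_of_kind("CDS") if f.label == label]
    if not feats:
        raise MitoError(f"{record.accession}: no CDS {label!r}")
    feat = feats[0]
    if feat.span_bp() == 0:
        raise MitoError(f"{record.accession}: CDS {label!r} has zero length")
    seq = record.subsequence(feat.intervals)
    if feat.strand == "L":
        seq = reverse_complement(seq)
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def count_codons(record: MtGenomeRecord) -> CodonCountTable:
    """Count sense-codon usage per protein-coding gene and in aggregate."""
    if record.sequence is None:
        raise MitoError(f"{record.accession}: codon counting needs a sequence")
    cds_labels = [f.label for f in record.features_of_kind("CDS")]
    if not cds_labels:
        raise MitoError(f"{record.accession}: no CDS features")
    per_gene: dict[str, dict[str, int]] = {}
    aggregate = {codon: 0 for codon in SENSE_CODONS}
    for label in cds_labels:
        codons = codons_of_cds(record, label)
        counts: dict[str, int] = {}
        for i, codon in enumerate(codons):
            if codon in STOP_CODONS:
                if i < len(codons) - 1:
                    warnings.warn(
                        f"{record.accession}/{label}: internal stop codon "
                        f"{codon} at codon {i + 1} (annotation noise?)",
                        stacklevel=2,
                    )
                continue
            if codon not in CODON_TO_AA:  # ambiguous base
                continue
            counts[codon] = counts.get(codon, 0) + 1
            aggregate[codon] += 1
        per_gene[label] = counts
    total = sum(aggregate.values())
    return CodonCountTable(per_gene=per_gene, aggregate=aggregate, total_sense=total)


def trna_usage(counts: CodonCountTable) -> TrnaUsage:
    """Sum each tRNA's codon family; relative frequencies sum to 1."""
    family_counts = {t: 0 for t in CANONICAL_TRNAS}
    for codon, n in counts.aggregate.items():
        family_counts[CODON_TO_TRNA[codon]] += n
    total = counts.total_sense
    return TrnaUsage(per_trna={
        t: (c, c / total if total else 0.0) for t, c in family_counts.items()
    })


def hydrophobic_fraction(freqs: AminoAcidFrequencySet) -> float:
    """Total frequency of the 9 hydrophobic residues (F V L I M W A G P)."""
    try:
        return sum(freqs.freq[a] for a in sorted(HYDROPHOBIC_AA1))
    except KeyError as exc:
        raise MitoError(f"{freqs.name}: missing amino acid {exc}") from None


def classify_trna(label: str) -> str:
    """'hydrophobic' or 'hydrophilic' by the decoded amino acid."""
    if label not in CANONICAL_TRNAS:
        raise MitoError(f"unknown tRNA label {label!r}")
    return "hydrophobic" if label in HYDROPHOBIC_TRNAS else "hydrophilic"


def _freqset(name: str, raw: Mapping[str, float]) -> AminoAcidFrequencySet:
    return AminoAcidFrequencySet(name=name, freq=dict(raw))


from .reference import JTT_FREQUENCIES, MTREV_FREQUENCIES  # noqa: E402

MTREV = _freqset("mtREV", MTREV_FREQUENCIES)
JTT = _freqset("JTT", JTT_FREQUENCIES)


def write_usage_table(record: MtGenomeRecord, path) -> pd.DataFrame:
    """TSV output: codon, amino_acid, trna, count, rel_freq."""
    table = count_codons(record)
    usage = trna_usage(table)
    rows = [{
        "codon": codon,
        "amino_acid": CODON_TO_AA[codon],
        "trna": CODON_TO_TRNA[codon],
        "count": table.aggregate[codon],
        "rel_freq": (table.aggregate[codon] / table.total_sense
                     if table.total_sense else 0.0),
    } for codon in SENSE_CODONS]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
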