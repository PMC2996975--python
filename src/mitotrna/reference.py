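"""Built-in reference data.

* A coordinates-only annotation of the human mitochondrial genome
  (accession AF347015, 16568 bp), reconstructed from the published reference
  human mtDNA gene coordinates with the single-base placeholder indel
  (reference position 3107) removed. No sequence is bundled; the record
  supports all geometry and replication analyses but not codon counting.
* The canonical vertebrate mt-tRNA anticodon table (human, coding-strand
  5'->3' DNA triplets).
* The typical vertebrate mitochondrial gene order.
* Equilibrium amino-acid frequencies of the mtREV and JTT substitution
  models (Adachi & Hasegawa 1996; Jones, Taylor & Thornton 1992).
"""

from __future__ import annotations

from .model import GenomeFeature, MtGenomeRecord

HUMAN_ACCESSION = "AF347015"
HUMAN_LENGTH_BP = 16568

# (label, kind, strand, start, end) -- 1-based inclusive, AF347015 numbering.
# The control region wraps the coordinate origin and is listed with its two
# intervals below.
_HUMAN_FEATURES: tuple[tuple[str, str, str, int, int], ...] = (
    ("Phe", "tRNA", "H", 577, 647),
    ("rrnS", "rRNA", "H", 648, 1601),
    ("Val", "tRNA", "H", 1602, 1670),
    ("rrnL", "rRNA", "H", 1671, 3228),
    ("Leu1", "tRNA", "H", 3229, 3303),
    ("ND1", "CDS", "H", 3306, 4261),
    ("Ile", "tRNA", "H", 4262, 4330),
    ("Gln", "tRNA", "L", 4328, 4399),
    ("Met", "tRNA", "H", 4401, 4468),
    ("ND2", "CDS", "H", 4469, 5510),
    ("Trp", "tRNA", "H", 5511, 5578),
    ("Ala", "tRNA", "L", 5586, 5654),
    ("Asn", "tRNA", "L", 5656, 5728),
    ("OL", "rep_origin_L", "H", 5720, 5797),
    ("Cys", "tRNA", "L", 5760, 5825),
    ("Tyr", "tRNA", "L", 5825, 5890),
    ("CO1", "CDS", "H", 5903, 7444),
    ("Ser1", "tRNA", "L", 7445, 7513),
    ("Asp", "tRNA", "H", 7517, 7584),
    ("CO2", "CDS", "H", 7585, 8268),
    ("Lys", "tRNA", "H", 8294, 8363),
    ("ATP8", "CDS", "H", 8365, 8571),
    ("ATP6", "CDS", "H", 8526, 9206),
    ("CO3", "CDS", "H", 9206, 9989),
    ("Gly", "tRNA", "H", 9990, 10057),
    ("ND3", "CDS", "H", 10058, 10403),
    ("Arg", "tRNA", "H", 10404, 10468),
    ("ND4L", "CDS", "H", 10469, 10765),
    ("ND4", "CDS", "H", 10759, 12136),
    ("His", "tRNA", "H", 12137, 12205),
    ("Ser2", "tRNA", "H", 12206, 12264),
    ("Leu2", "tRNA", "H", 12265, 12335),
    ("ND5", "CDS", "H", 12336, 14147),
    ("ND6", "CDS", "L", 14148, 14672),
    ("Glu", "tRNA", "L", 14673, 14741),
    ("CYTB", "CDS", "H", 14746, 15886),
    ("Thr", "tRNA", "H", 15887, 15952),
    ("Pro", "tRNA", "L", 15955, 16022),
)

#: Canonical human mt-tRNA anticodons, DNA, coding-strand 5'->3'
#: (structural positions 34-36; position 34 is the wobble base).
CANONICAL_ANTICODONS: dict[str, str] = {
    "Phe": "GAA", "Val": "TAC", "Leu1": "TAA", "Leu2": "TAG", "Ile": "GAT",
    "Met": "CAT", "Trp": "TCA", "Ala": "TGC", "Gly": "TCC", "Pro": "TGG",
    "Ser1": "TGA", "Ser2": "GCT", "Glu": "TTC", "Asp": "GTC", "Lys": "TTT",
    "Arg": "TCG", "Tyr": "GTA", "Cys": "GCA", "Asn": "GTT", "His": "GTG",
    "Gln": "TTG", "Thr": "TGT",
}

#: The typical vertebrate mitochondrial gene order, listed circularly
#: starting from the control region's 3' end on the H-strand (tRNA-Phe side).
TYPICAL_GENE_ORDER: tuple[str, ...] = (
    "Phe", "rrnS", "Val", "rrnL", "Leu1", "ND1", "Ile", "Gln", "Met", "ND2",
    "Trp", "Ala", "Asn", "Cys", "Tyr", "CO1", "Ser1", "Asp", "CO2", "Lys",
    "ATP8", "ATP6", "CO3", "Gly", "ND3", "Arg", "ND4L", "ND4", "His", "Ser2",
    "Leu2", "ND5", "ND6", "Glu", "CYTB", "Thr", "Pro",
)

CDS_LABELS: tuple[str, ...] = tuple(
    g for g in TYPICAL_GENE_ORDER
    if g.startswith(("ND", "CO", "ATP", "CYTB"))
)
assert len(CDS_LABELS) == 13


def human_record() -> MtGenomeRecord:
    """The built-in AF347015 annotation (coordinates only, no sequence)."""
    features = [
        GenomeFeature(
            kind="control_region",
            label="CR",
            strand="H",
            intervals=((16023, HUMAN_LENGTH_BP), (1, 576)),
        )
    ]
    for label, kind, strand, start, end in _HUMAN_FEATURES:
        features.append(
            GenomeFeature(
                kind=kind,
                label=label,
                strand=strand,
                intervals=((start, end),),
                anticodon=CANONICAL_ANTICODONS.get(label) if kind == "tRNA" else None,
            )
        )
    return MtGenomeRecord(
        accession=HUMAN_ACCESSION,
        taxon="Homo sapiens",
        length_bp=HUMAN_LENGTH_BP,
        sequence=None,
        features=features,
    )


#: Equilibrium amino-acid frequencies of the mtREV model (mitochondrially
#: encoded proteins) and the JTT model (a general nuclear proteome).
MTREV_FREQUENCIES: dict[str, float] = {
    "A": 0.072, "R": 0.019, "N": 0.039, "D": 0.019, "C": 0.006, "Q": 0.025,
    "E": 0.024, "G": 0.056, "H": 0.028, "I": 0.088, "L": 0.169, "K": 0.023,
    "M": 0.054, "F": 0.061, "P": 0.054, "S": 0.072, "T": 0.086, "W": 0.029,
    "Y": 0.033, "V": 0.043,
}

JTT_FREQUENCIES: dict[str, float] = {
    "A": 0.076748, "R": 0.051691, "N": 0.042645, "D": 0.051544, "C": 0.019803,
    "Q": 0.040752, "E": 0.061830, "G": 0.073152, "H": 0.022944, "I": 0.053761,
    "L": 0.091904, "K": 0.058676, "M": 0.023826, "F": 0.040126, "P": 0.050901,
    "S": 0.068765, "T": 0.058565, "W": 0.014261, "Y": 0.032102, "V": 0.066005,
}
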