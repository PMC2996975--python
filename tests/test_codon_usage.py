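"""Codon counting, tRNA-family usage, and hydropathy classification."""

import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from mitotrna.codon import (
    JTT,
    MTREV,
    AminoAcidFrequencySet,
    classify_trna,
    codons_of_cds,
    count_codons,
    hydrophobic_fraction,
    trna_usage,
)
from mitotrna.genetic_code import (
    CANONICAL_TRNAS,
    CODON_TO_TRNA,
    SENSE_CODONS,
    STOP_CODONS,
    TRNA_TO_CODONS,
    reverse_complement,
)
from mitotrna.model import GenomeFeature, MitoError, MtGenomeRecord


def _record_with_cds(segments, length=None, pad="A"):
    """Build a tiny record from (label, strand, start, seq) CDS segments."""
    length = length or max(s + len(seq) for _, _, s, seq in segments) + 10
    seq = [pad] * length
    feats = []
    for label, strand, start, cds_seq in segments:
        ins = cds_seq if strand == "H" else reverse_complement(cds_seq)
        seq[start - 1 : start - 1 + len(ins)] = list(ins)
        feats.append(GenomeFeature(
            "CDS", label, strand, ((start, start + len(cds_seq) - 1),)))
    return MtGenomeRecord("T1", "t", length, sequence="".join(seq),
                          features=feats)


def test_single_cds_counts_and_stop_exclusion():
    rec = _record_with_cds([("ND1", "H", 11, "ATGGCCTAA")])
    table = count_codons(rec)
    assert table.per_gene["ND1"] == {"ATG": 1, "GCC": 1}
    assert table.total_sense == 2


def test_l_strand_cds_read_as_reverse_complement():
    rec = _record_with_cds([("ND6", "L", 11, "ATGGCCCTT")])
    table = count_codons(rec)
    assert table.per_gene["ND6"] == {"ATG": 1, "GCC": 1, "CTT": 1}


def test_incomplete_terminal_codon_dropped():
    rec = _record_with_cds([("ND1", "H", 11, "ATGGCCTA")])  # 8 bp
    assert count_codons(rec).total_sense == 2


def test_overlapping_genes_counted_in_each_frame():
    """Overlap bases contribute to both genes, each in its own frame."""
    # ATP8 at 11..22 and ATP6 at 18..29: 5 shared bases, frames differ
    genome_len = 60
    seq = list("A" * genome_len)
    atp8 = "ATGAAACCCGGG"
    atp6 = "ATGTTTAAACCC"
    seq[10:22] = list(atp8)
    seq[17:29] = list(atp6)
    feats = [
        GenomeFeature("CDS", "ATP8", "H", ((11, 22),)),
        GenomeFeature("CDS", "ATP6", "H", ((18, 29),)),
    ]
    rec = MtGenomeRecord("T2", "t", genome_len, sequence="".join(seq),
                         features=feats)
    table = count_codons(rec)
    assert sum(table.per_gene["ATP8"].values()) == 4
    assert sum(table.per_gene["ATP6"].values()) == 4
    # the union region holds 19 bp (6 complete codons) but 8 codons counted
    assert table.total_sense == 8


def test_random_cds_matches_sliding_frame_oracle(rng):
    """Counts equal an independent 3-bp stepper over the coding sequence."""
    codons = [SENSE_CODONS[i]
              for i in rng.integers(0, len(SENSE_CODONS), size=300)]
    cds = "".join(codons)
    for strand in ("H", "L"):
        rec = _record_with_cds([("CYTB", strand, 21, cds)], length=1000)
        table = count_codons(rec)
        oracle: dict = {}
        for i in range(0, len(cds), 3):  # independent stepper
            c = cds[i : i + 3]
            if c not in STOP_CODONS:
                oracle[c] = oracle.get(c, 0) + 1
        assert table.per_gene["CYTB"] == oracle


def test_internal_stop_warns_but_continues():
    rec = _record_with_cds([("ND1", "H", 11, "ATGTAAGCC")])
    with pytest.warns(UserWarning, match="internal stop"):
        table = count_codons(rec)
    assert table.per_gene["ND1"] == {"ATG": 1, "GCC": 1}


def test_codon_family_partition_matches_genetic_code_oracle():
    """Independent dictionary built from translation table 2 agrees."""
    table2 = CodonTable.unambiguous_dna_by_id[2]
    oracle = {}
    for codon, aa in table2.forward_table.items():
        if aa == "L":
            oracle[codon] = "Leu1" if codon[0] == "T" else "Leu2"
        elif aa == "S":
            oracle[codon] = "Ser2" if codon[0] == "A" else "Ser1"
        else:
            oracle[codon] = aa
    from mitotrna.genetic_code import TRNA_TO_AA1
    for codon in SENSE_CODONS:
        got = CODON_TO_TRNA[codon]
        want = oracle[codon]
        assert got == want or TRNA_TO_AA1[got] == want
    # partition: 60 sense codons, 22 nonempty families, disjoint by construction
    assert sum(len(v) for v in TRNA_TO_CODONS.values()) == 60
    assert all(TRNA_TO_CODONS[t] for t in CANONICAL_TRNAS)


def test_trna_usage_sums_to_total(small_cohort):
    sp = sorted(small_cohort.records)[0]
    table = count_codons(small_cohort.records[sp])
    usage = trna_usage(table)
    assert sum(usage.counts.values()) == table.total_sense
    assert math.isclose(sum(usage.rel_freq.values()), 1.0, abs_tol=1e-12)


def test_aua_counts_as_met():
    rec = _record_with_cds([("ND1", "H", 11, "ATA" * 5 + "ATG" * 3)])
    usage = trna_usage(count_codons(rec))
    assert usage.counts["Met"] == 8


def test_strand_flip_invariance(small_cohort):
    """Reverse-complementing the genome and flipping strands keeps counts."""
    sp = sorted(small_cohort.records)[0]
    rec = small_cohort.records[sp]
    L = rec.length_bp
    import dataclasses
    flipped_feats = []
    for f in rec.features:
        ivals = tuple(sorted((L - e + 1, L - s + 1) for s, e in f.intervals))
        flipped_feats.append(dataclasses.replace(
            f, strand=("L" if f.strand == "H" else "H"), intervals=ivals))
    flipped = MtGenomeRecord(rec.accession, rec.taxon, L,
                             sequence=reverse_complement(rec.sequence),
                             features=flipped_feats)
    assert count_codons(flipped).aggregate == count_codons(rec).aggregate


@pytest.mark.parametrize("freqset,expected", [(MTREV, 0.624), (JTT, 0.490)])
def test_hydrophobic_fraction_embedded_matrices(freqset, expected):
    assert hydrophobic_fraction(freqset) == pytest.approx(expected, abs=0.005)


def test_hydrophobic_fraction_uniform():
    uniform = AminoAcidFrequencySet("uniform", {a: 0.05 for a in
                                                "ARNDCQEGHILKMFPSTWYV"})
    assert hydrophobic_fraction(uniform) == pytest.approx(0.45)


def test_hydrophobic_fraction_missing_residue_errors():
    partial = dict(MTREV.freq)
    del partial["F"]
    broken = AminoAcidFrequencySet.__new__(AminoAcidFrequencySet)
    object.__setattr__(broken, "name", "broken")
    object.__setattr__(broken, "freq", partial)
    with pytest.raises(MitoError):
        hydrophobic_fraction(broken)


def test_classify_trna_partition():
    hydro = {t for t in CANONICAL_TRNAS if classify_trna(t) == "hydrophobic"}
    philic = {t for t in CANONICAL_TRNAS if classify_trna(t) == "hydrophilic"}
    assert len(hydro) == 10 and len(philic) == 12
    assert hydro | philic == set(CANONICAL_TRNAS) and not hydro & philic
    assert classify_trna("Leu2") == "hydrophobic"
    assert classify_trna("Thr") == "hydrophilic"
    with pytest.raises(MitoError):
        classify_trna("Sec")
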