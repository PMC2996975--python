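"""Replication-exposure model and anticodon G+T scoring."""

import dataclasses

import pytest

from mitotrna.deamination import (
    anticodon_gt_count,
    build_replication_map,
    classify_replication_group,
    exposure_durations,
    exposure_gt_correlation,
    ReplicationMap,
)
from mitotrna.genetic_code import CANONICAL_TRNAS, TRNA_TO_CODONS, reverse_complement
from mitotrna.model import GenomeFeature, MitoError, MtGenomeRecord
from mitotrna.reference import CANONICAL_ANTICODONS

# Replication groups of the typical human arrangement.
BETWEEN_13 = {"Cys", "Tyr", "Ser1", "Asp", "Lys", "Gly", "Arg", "His",
              "Ser2", "Leu2", "Glu", "Thr", "Pro"}
OUTSIDE_9 = {"Asn", "Ala", "Trp", "Met", "Gln", "Ile", "Leu1", "Val", "Phe"}


def test_human_groups_match_typical_partition(human):
    rep_map = build_replication_map(human)
    groups = classify_replication_group(human, rep_map)
    assert {t for t, g in groups.items() if g == "between_origins"} == BETWEEN_13
    assert {t for t, g in groups.items() if g == "outside"} == OUTSIDE_9


def test_groups_partition_all_22(human, small_cohort):
    for rec in [human] + list(small_cohort.records.values()):
        groups = classify_replication_group(rec, build_replication_map(rec))
        assert len(groups) == 22
        assert set(groups.values()) <= {"between_origins", "outside"}


def test_alpha_plus_beta_is_genome_length(human, small_cohort):
    for rec in [human] + list(small_cohort.records.values()):
        rep_map = build_replication_map(rec)
        for e in exposure_durations(rec, rep_map):
            assert e.alpha + e.beta == rec.length_bp


def test_boundary_gene_just_past_ol_is_between():
    feats = [
        GenomeFeature("control_region", "CR", "H", ((1, 500),)),
        GenomeFeature("tRNA", "Cys", "H", ((2001, 2070),)),
        GenomeFeature("tRNA", "Phe", "H", ((900, 969),)),
    ]
    rec = MtGenomeRecord("B1", "t", 10000, features=feats)
    rep_map = ReplicationMap(o_l=2000, o_h=500, genome_length=10000)
    groups = classify_replication_group(rec, rep_map)
    assert groups["Cys"] == "between_origins"  # 5' at o_l + 1
    assert groups["Phe"] == "outside"


def test_exposure_formulas():
    feats = [
        GenomeFeature("control_region", "CR", "H", ((1, 500),)),
        GenomeFeature("tRNA", "Gly", "H", ((3001, 3070),)),  # between
        GenomeFeature("tRNA", "Phe", "H", ((7001, 7070),)),  # outside
    ]
    rec = MtGenomeRecord("E1", "t", 10000, features=feats)
    rep_map = ReplicationMap(o_l=2000, o_h=6000, genome_length=10000)
    ex = {e.trna: e for e in exposure_durations(rec, rep_map)}
    assert ex["Gly"].group == "between_origins"
    assert ex["Gly"].exposure == ex["Gly"].alpha == 1001
    assert ex["Phe"].group == "outside"
    assert ex["Phe"].alpha == 5001 and ex["Phe"].beta == 4999
    assert ex["Phe"].exposure == 5001 - 4999  # alpha - beta


def test_outside_gene_at_halfway_has_zero_exposure():
    feats = [
        GenomeFeature("control_region", "CR", "H", ((1, 500),)),
        GenomeFeature("tRNA", "Phe", "H", ((7000, 7069),)),
    ]
    rec = MtGenomeRecord("E2", "t", 10000, features=feats)
    rep_map = ReplicationMap(o_l=2000, o_h=6000, genome_length=10000)
    e = exposure_durations(rec, rep_map)[0]
    assert e.alpha == e.beta == 5000
    assert e.exposure == 0


def test_rotation_leaves_exposures_unchanged(human):
    rep_map = build_replication_map(human)
    base = {e.trna: (e.alpha, e.beta, e.exposure)
            for e in exposure_durations(human, rep_map)}
    rotated = human.rotated(4321)
    rep_rot = build_replication_map(rotated)
    got = {e.trna: (e.alpha, e.beta, e.exposure)
           for e in exposure_durations(rotated, rep_rot)}
    assert got == base


def test_ol_imputed_from_wancy_gap(human):
    without_ol = MtGenomeRecord(
        human.accession, human.taxon, human.length_bp,
        features=[f for f in human.features if f.kind != "rep_origin_L"])
    rep_map = build_replication_map(without_ol)
    # imputed midpoint of the Asn..Cys gap stays in the WANCY region
    assert 5728 < rep_map.o_l < 5760
    groups = classify_replication_group(without_ol, rep_map)
    assert {t for t, g in groups.items() if g == "between_origins"} == BETWEEN_13


@pytest.mark.parametrize("triplet,convention,expected", [
    ("GTA", "first_two_5to3", 2),
    ("CAA", "first_two_5to3", 0),
    ("CAA", "codon12_pairing", 0),
    ("GAT", "codon12_pairing", 1),   # scores T (pos 3) and A (pos 2)
    ("TAG", "codon12_pairing", 1),
])
def test_anticodon_gt_count(triplet, convention, expected):
    assert anticodon_gt_count(triplet, convention) == expected


def test_anticodon_unknown_raises():
    feat = GenomeFeature("tRNA", "Phe", "H", ((1, 70),))
    lone = dataclasses.replace(feat, label="Sec")
    with pytest.raises(MitoError, match="Sec"):
        anticodon_gt_count(dataclasses.replace(lone), "first_two_5to3")


def test_canonical_anticodons_consistent_with_genetic_code():
    """Reverse complement of each anticodon is a codon of its tRNA's family
    (the wobble-degenerate third position may mismatch)."""
    for label in CANONICAL_TRNAS:
        anticodon = CANONICAL_ANTICODONS[label]
        codon = reverse_complement(anticodon)
        family = TRNA_TO_CODONS[label]
        assert any(codon[:2] == f[:2] for f in family), label


def test_constant_gt_gives_degenerate_correlation_error(human):
    rep_map = build_replication_map(human)
    base = exposure_durations(human, rep_map)
    flat = [dataclasses.replace(e, gt_count=1) for e in base]
    with pytest.raises(MitoError):
        exposure_gt_correlation(flat, "all")


def test_human_subset_sizes(human):
    rep_map = build_replication_map(human)
    records = exposure_durations(human, rep_map)
    between = exposure_gt_correlation(records, "between_origins_only")
    allr = exposure_gt_correlation(records, "all")
    assert between.n == 13
    assert allr.n == 22
    assert allr.tail == "positive"
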