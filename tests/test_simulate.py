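"""Determinism and construction identities of the synthetic generator."""

import numpy as np
import pytest

from mitotrna.codon import count_codons, trna_usage
from mitotrna.deamination import (
    anticodon_gt_count,
    build_replication_map,
    exposure_durations,
)
from mitotrna.geometry import all_distances
from mitotrna.model import MitoError
from mitotrna.simulate import (
    SimulationConfig,
    simulate_anticodon_gradient,
    simulate_tree,
    simulate_usage_and_positions,
    write_fixture_genbank,
)


def test_tree_structure(rng):
    for n in (2, 7, 20):
        tree = simulate_tree(n, rng)
        leaves = list(tree.leaf_node_iter())
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert len(leaves) == n
        assert len(internal) == n - 1
        assert all(len(nd.child_nodes()) == 2 for nd in internal)


def test_tree_requires_two_species(rng):
    with pytest.raises(MitoError):
        simulate_tree(1, rng)


def test_same_seed_reproduces_newick_and_genomes():
    cfg = SimulationConfig(seed=99, n_species=4)
    sim1 = simulate_usage_and_positions(cfg)
    sim2 = simulate_usage_and_positions(SimulationConfig(seed=99, n_species=4))
    assert sim1.newick() == sim2.newick()
    for sp in sim1.records:
        assert sim1.records[sp].sequence == sim2.records[sp].sequence
        assert sim1.records[sp].features == sim2.records[sp].features


def test_different_seed_differs():
    a = simulate_usage_and_positions(SimulationConfig(seed=1, n_species=3))
    b = simulate_usage_and_positions(SimulationConfig(seed=2, n_species=3))
    sa = [r.sequence for r in a.records.values()]
    sb = [r.sequence for r in b.records.values()]
    assert sa != sb


def test_codon_counts_construction_identity(small_cohort):
    """count_codons recovers the generator's realized counts exactly."""
    for sp, record in small_cohort.records.items():
        table = count_codons(record)
        assert table.aggregate == small_cohort.realized_counts[sp]


def test_distances_construction_identity(small_cohort):
    for sp, record in small_cohort.records.items():
        got = {p.trna: p.distance_bp for p in all_distances(record)}
        assert got == small_cohort.distances[sp]


def test_usage_targets_close_to_realized(small_cohort):
    """Multinomial realization tracks the target family frequencies."""
    for sp, record in small_cohort.records.items():
        realized = trna_usage(count_codons(record)).rel_freq
        for trna, target in small_cohort.usage[sp].items():
            assert realized[trna] == pytest.approx(target, abs=0.03)


def test_permuted_gene_order_differs_from_typical():
    cfg_t = SimulationConfig(seed=5, n_species=2, gene_order="typical")
    cfg_p = SimulationConfig(seed=5, n_species=2, gene_order="permuted",
                             permutation_seed=3)
    sim_t = simulate_usage_and_positions(cfg_t, with_sequences=False)
    sim_p = simulate_usage_and_positions(cfg_p, with_sequences=False)
    assert sim_t.ground_truth["base_distances"] != sim_p.ground_truth[
        "base_distances"]


def test_fixture_batch_unique_accessions(tmp_path):
    cfg = SimulationConfig(seed=8, n_species=10)
    sim = simulate_usage_and_positions(cfg, with_sequences=False)
    paths = write_fixture_genbank(sim.records.values(), tmp_path / "fx")
    assert len(paths) == 10
    assert len({p.name for p in paths}) == 10


def test_fixture_empty_list(tmp_path):
    assert write_fixture_genbank([], tmp_path / "empty") == []
    assert (tmp_path / "empty").exists()


def test_gradient_zero_slope_keeps_gt_independent(small_cohort, rng):
    cfg = SimulationConfig(seed=1, n_species=2, deamination_slope=0.0,
                           deamination_intercept=0.0)
    record = list(small_cohort.records.values())[0]
    rep_map = build_replication_map(record)
    _, truth = simulate_anticodon_gradient(cfg, record, rep_map, rng)
    assert {round(v["p_gt"], 12) for v in truth.values()} == {0.5}


def test_gradient_saturation(small_cohort, rng):
    """Huge positive slope pins distal between-origin genes at gt = 2."""
    cfg = SimulationConfig(seed=1, n_species=2, deamination_slope=10.0,
                           deamination_intercept=0.0)
    record = list(small_cohort.records.values())[0]
    rep_map = build_replication_map(record)
    shaped, truth = simulate_anticodon_gradient(cfg, record, rep_map, rng)
    for e in exposure_durations(shaped, rep_map):
        if e.exposure > 0:
            assert e.gt_count == 2, e.trna


def test_gradient_written_into_sequence(small_cohort, rng):
    """The drawn anticodon is physically present in the genome sequence."""
    cfg = SimulationConfig(seed=1, n_species=2)
    record = list(small_cohort.records.values())[0]
    rep_map = build_replication_map(record)
    shaped, truth = simulate_anticodon_gradient(cfg, record, rep_map, rng)
    from mitotrna.genetic_code import reverse_complement
    from mitotrna.simulate import ANTICODON_OFFSET

    for label, feat in shaped.trnas.items():
        gene = shaped.subsequence(feat.intervals)
        coding = reverse_complement(gene) if feat.strand == "L" else gene
        triplet = coding[ANTICODON_OFFSET - 1 : ANTICODON_OFFSET + 2]
        assert triplet == truth[label]["anticodon"] == feat.anticodon
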