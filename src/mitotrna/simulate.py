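"""Synthetic annotated mt-genomes, trees, and tip data with known truth.

The generator emulates the statistical structure of a vertebrate
mt-genome cohort: a binary (Yule) phylogeny with unit branch lengths, a
bivariate Brownian process coupling log codon-family usage to log
CR-distance per tRNA with a chosen cross-correlation, genomes laid out on a
circle so that each tRNA sits at its realized distance (the typical
arrangement or a seeded permutation of it), protein-coding genes realized
as codon draws matching the target usage, and anticodon base composition
following a logistic single-strand-exposure gradient. Every output is a
deterministic function of the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .genetic_code import (
    CANONICAL_TRNAS,
    SENSE_CODONS,
    TRNA_TO_CODONS,
    reverse_complement,
)
from .model import GenomeFeature, LayoutError, MitoError, MtGenomeRecord
from .reference import CANONICAL_ANTICODONS, MTREV_FREQUENCIES, human_record
from .geometry import all_distances, cr_reference_points

__all__ = [
    "SimulationConfig",
    "CohortSimulation",
    "simulate_tree",
    "simulate_bivariate_bm",
    "simulate_usage_and_positions",
    "simulate_anticodon_gradient",
    "build_genome",
    "write_fixture_genbank",
]

#: Split of the Leu and Ser amino-acid budgets between their two isoacceptors
#: (CUN-box and UCN-box codons dominate in vertebrate mt coding sequences).
_TWO_TRNA_SPLIT = {"Leu1": 0.35, "Leu2": 0.65, "Ser1": 0.65, "Ser2": 0.35}


def _base_usage() -> dict[str, float]:
    from .genetic_code import TRNA_TO_AA1

    raw = {}
    for label in CANONICAL_TRNAS:
        aa_freq = MTREV_FREQUENCIES[TRNA_TO_AA1[label]]
        raw[label] = aa_freq * _TWO_TRNA_SPLIT.get(label, 1.0)
    total = sum(raw.values())
    return {t: v / total for t, v in raw.items()}


def _base_layout(genome_length: int) -> tuple[dict[str, int], dict[str, str]]:
    """Typical-arrangement tRNA distances and strands, scaled from human."""
    rec = human_record()
    scale = genome_length / rec.length_bp
    distances, strands = {}, {}
    for pos in all_distances(rec):
        distances[pos.trna] = max(1, int(round(pos.distance_bp * scale)))
        strands[pos.trna] = pos.strand
    return distances, strands


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated cohort.

    Defaults mirror the study conditions: 47 species, ~16.5 kb circular
    genomes in the typical arrangement, a modest negative usage-position
    correlation, Brownian dispersions of about 0.1 log10 units per unit
    branch, and a deamination gradient of 0.5 logit units per 10 kb of
    exposure centred so the per-position G/T probability stays near 1/2.
    """

    seed: int
    n_species: int = 47
    genome_length: int = 16500
    gene_order: str = "typical"  # "typical" | "permuted"
    permutation_seed: int = 0
    rho_usage_position: float = -0.15
    bm_sigma_usage: float = 0.10
    bm_sigma_position: float = 0.10
    deamination_slope: float = 0.5 / 10_000.0  # logit G/T probability per bp
    deamination_intercept: float = -0.40
    cr_length: int = 600
    trna_length: int = 70

    def __post_init__(self) -> None:
        if self.seed is None:
            raise MitoError("SimulationConfig requires an explicit seed")
        if not (-1.0 < self.rho_usage_position < 1.0):
            raise MitoError("rho_usage_position must lie in (-1, 1)")
        if self.bm_sigma_usage <= 0 or self.bm_sigma_position <= 0:
            raise MitoError("Brownian dispersions must be positive")
        if self.gene_order not in ("typical", "permuted"):
            raise MitoError(f"unknown gene_order {self.gene_order!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# trees and Brownian tip values
# ---------------------------------------------------------------------------

def simulate_tree(
    n_species: int, rng: np.random.Generator, branch_length: float = 1.0
) -> dendropy.Tree:
    """Yule (random-splitting) binary tree with constant branch lengths."""
    if n_species < 2:
        raise MitoError("need at least 2 species")
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:03d}" for i in range(n_species)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node]
    while len(leaves) < n_species:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = parent.new_child(edge_length=branch_length)
            leaves.append(child)
    # deterministic leaf labelling: preorder left-to-right
    idx = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = taxa[idx]
            idx += 1
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = branch_length
    return tree


def simulate_bivariate_bm(
    tree: dendropy.Tree,
    rho: float,
    sigma_x: float,
    sigma_y: float,
    rng: np.random.Generator,
    root_x: float = 0.0,
    root_y: float = 0.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Correlated Brownian evolution of two variables along a tree."""
    cov = np.array([
        [sigma_x**2, rho * sigma_x * sigma_y],
        [rho * sigma_x * sigma_y, sigma_y**2],
    ])
    chol = np.linalg.cholesky(cov)
    values: dict[int, np.ndarray] = {}
    x: dict[str, float] = {}
    y: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.array([root_x, root_y])
            continue
        b = node.edge.length if node.edge.length is not None else 1.0
        step = chol @ rng.standard_normal(2) * math.sqrt(b)
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            label = node.taxon.label
            x[label] = float(values[id(node)][0])
            y[label] = float(values[id(node)][1])
    return x, y


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

#: Fraction of the genome given to the small/large rRNA blocks and the
#: relative position of the L-strand replication origin, as in the typical
#: vertebrate arrangement.
_RRNS_FRAC, _RRNL_FRAC, _OL_FRAC = 0.058, 0.094, 0.313

_CDS_ORDER = ("ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3",
              "ND4L", "ND4", "ND5", "ND6", "CYTB")


def build_genome(
    accession: str,
    taxon: str,
    distances: dict[str, int],
    strands: dict[str, str],
    target_usage: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    with_sequence: bool = True,
) -> tuple[MtGenomeRecord, dict[str, int]]:
    """Lay one circular genome out and realize its coding sequences.

    tRNAs are placed at their requested distances (nudged forward by the
    minimum needed to stay non-overlapping, with a 1 bp spacer); free gaps
    receive the two rRNAs, a point O_L, and the 13 protein-coding genes,
    whose codons are drawn i.i.d. from the target usage. Returns the record
    and the realized aggregate codon counts (empty when ``with_sequence``
    is False).
    """
    L = config.genome_length
    cr = config.cr_length
    tlen = config.trna_length
    max_d = L - cr - tlen - 8
    blocks: list[tuple[int, int, str]] = []  # (low, high, label)
    for label in CANONICAL_TRNAS:
        d = min(max(1, distances[label]), max_d)
        if strands[label] == "H":
            low = cr + d
            high = low + tlen - 1
        else:
            five = L + 1 - d
            high = five
            low = high - tlen + 1
        blocks.append((low, high, label))
    blocks.sort()
    placed: list[tuple[int, int, str]] = []
    prev_high = cr  # CR occupies 1..cr
    for low, high, label in blocks:
        if low <= prev_high + 1:
            shift = prev_high + 2 - low
            low += shift
            high += shift
        placed.append((low, high, label))
        prev_high = high
    # backward relaxation: genes crowded past the end of the circle are
    # pushed back toward the CR while preserving order and 1 bp spacers
    allowed_high = L
    for i in range(len(placed) - 1, -1, -1):
        low, high, label = placed[i]
        if high > allowed_high:
            shift = high - allowed_high
            low -= shift
            high -= shift
            if low <= cr:
                raise LayoutError(
                    f"{accession}: cannot place tRNA {label}; total gene "
                    "length exceeds the genome"
                )
            placed[i] = (low, high, label)
        allowed_high = low - 2

    features = [GenomeFeature("control_region", "CR", "H", ((1, cr),))]
    for low, high, label in placed:
        features.append(GenomeFeature(
            "tRNA", label, strands[label], ((low, high),),
            anticodon=CANONICAL_ANTICODONS[label],
        ))

    # free gaps between placed blocks (and after the last block, before CR)
    gaps: list[tuple[int, int]] = []
    prev_high = cr
    for low, high, _ in placed:
        if low - prev_high > 2:
            gaps.append((prev_high + 1, low - 1))
        prev_high = high
    if L - prev_high > 1:
        gaps.append((prev_high + 1, L))

    def carve(n_bp: int, near: Optional[int] = None) -> tuple[int, int]:
        """Take n_bp from the largest gap (or the gap nearest ``near``)."""
        if not gaps:
            raise LayoutError(f"{accession}: no free gap left")
        if near is None:
            i = max(range(len(gaps)), key=lambda j: gaps[j][1] - gaps[j][0])
        else:
            usable = [j for j in range(len(gaps))
                      if gaps[j][1] - gaps[j][0] + 1 >= n_bp + 2]
            if not usable:
                raise LayoutError(f"{accession}: no gap fits {n_bp} bp")
            i = min(usable, key=lambda j: abs((gaps[j][0] + gaps[j][1]) // 2 - near))
        lo, hi = gaps.pop(i)
        n_bp = min(n_bp, hi - lo - 1)
        if n_bp < 1:
            raise LayoutError(f"{accession}: gap too small")
        seg = (lo + 1, lo + n_bp)
        if seg[1] + 1 < hi:
            gaps.append((seg[1] + 1, hi))
        return seg

    for label, frac in (("rrnS", _RRNS_FRAC), ("rrnL", _RRNL_FRAC)):
        seg = carve(int(frac * L))
        features.append(GenomeFeature("rRNA", label, "H", (seg,)))
    ol_seg = carve(24, near=cr + int(_OL_FRAC * L))
    features.append(GenomeFeature("rep_origin_L", "OL", "H", (ol_seg,)))

    # distribute the 13 CDS over the remaining gaps, largest first
    gap_order = sorted(range(len(gaps)),
                       key=lambda j: gaps[j][1] - gaps[j][0], reverse=True)
    capacities = [(gaps[j][1] - gaps[j][0] - 1) // 3 for j in gap_order]
    total_cap = sum(c for c in capacities if c >= 20)
    if total_cap < 13 * 20:
        raise LayoutError(f"{accession}: not enough free space for 13 CDS")
    quota: list[int] = []
    remaining = len(_CDS_ORDER)
    for rank, cap in enumerate(capacities):
        if cap < 20 or remaining == 0:
            quota.append(0)
            continue
        q = max(1, round(len(_CDS_ORDER) * cap / total_cap)) if rank < len(capacities) - 1 else remaining
        q = min(q, remaining, cap // 20)
        quota.append(q)
        remaining -= q
    if remaining:
        for rank, cap in enumerate(capacities):
            while remaining and quota[rank] < cap // 20:
                quota[rank] += 1
                remaining -= 1
    if remaining:
        raise LayoutError(f"{accession}: could not place all 13 CDS")

    probs = np.array([
        target_usage[_codon_family(c)] / len(TRNA_TO_CODONS[_codon_family(c)])
        for c in SENSE_CODONS
    ])
    probs = probs / probs.sum()

    cds_iter = iter(_CDS_ORDER)
    cds_segments: list[tuple[str, tuple[int, int], str]] = []
    realized = {c: 0 for c in SENSE_CODONS}
    for rank, j in enumerate(gap_order):
        if quota[rank] == 0:
            continue
        lo, hi = gaps[j]
        usable = hi - lo - 1
        per = usable // quota[rank]
        cursor = lo + 1
        for _ in range(quota[rank]):
            label = next(cds_iter)
            n_codons = (per - 1) // 3
            strand = "H"
            seg = (cursor, cursor + 3 * n_codons - 1)
            cursor = seg[1] + 2
            codon_seq = ""
            if with_sequence:
                draws = rng.choice(len(SENSE_CODONS), size=n_codons, p=probs)
                codon_seq = "".join(SENSE_CODONS[i] for i in draws)
                for i in draws:
                    realized[SENSE_CODONS[i]] += 1
            cds_segments.append((label, seg, codon_seq))
            features.append(GenomeFeature("CDS", label, strand, (seg,)))

    sequence = None
    if with_sequence:
        arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L)
        seq = np.char.decode(arr).tolist()
        for label, (lo, hi), codon_seq in cds_segments:
            seq[lo - 1 : hi] = list(codon_seq)
        for low, high, label in placed:
            gene = _random_trna_sequence(
                tlen, CANONICAL_ANTICODONS[label], rng)
            if strands[label] == "L":
                gene = reverse_complement(gene)
            seq[low - 1 : high] = list(gene)
        sequence = "".join(seq)

    record = MtGenomeRecord(
        accession=accession, taxon=taxon, length_bp=L,
        sequence=sequence, features=features,
    )
    return record, realized


def _codon_family(codon: str) -> str:
    from .genetic_code import CODON_TO_TRNA

    return CODON_TO_TRNA[codon]


#: 1-based offset of the anticodon triplet within a simulated tRNA gene
#: (coding orientation) -- roughly the anticodon loop position.
ANTICODON_OFFSET = 31


def _random_trna_sequence(
    tlen: int, anticodon: str, rng: np.random.Generator
) -> str:
    bases = rng.choice(list("ACGT"), size=tlen).tolist()
    bases[ANTICODON_OFFSET - 1 : ANTICODON_OFFSET + 2] = list(anticodon)
    return "".join(bases)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimulation:
    """A simulated cohort plus its generator-side ground truth."""

    config: SimulationConfig
    tree: dendropy.Tree
    records: dict[str, MtGenomeRecord]
    usage: dict[str, dict[str, float]]  # species -> trna -> target rel freq
    distances: dict[str, dict[str, int]]  # species -> trna -> realized bp
    realized_counts: dict[str, dict[str, int]]  # species -> codon -> count
    ground_truth: dict = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def simulate_usage_and_positions(
    config: SimulationConfig,
    tree: Optional[dendropy.Tree] = None,
    with_sequences: bool = True,
) -> CohortSimulation:
    """Evolve per-tRNA usage and distance on a tree and realize genomes.

    Each of the 22 tRNA families follows an independent bivariate Brownian
    process in (log10 usage, log10 distance) with cross-correlation
    ``rho_usage_position``; per species, usages are renormalized to sum to
    one and genomes are laid out at the realized distances. Realized codon
    counts are exactly what :func:`mitotrna.codon.count_codons` recovers
    from the emitted sequence.
    """
    rng = config.rng()
    if tree is None:
        tree = simulate_tree(config.n_species, rng)
    base_u = _base_usage()
    base_d, strands = _base_layout(config.genome_length)
    if config.gene_order == "permuted":
        perm_rng = np.random.default_rng(config.permutation_seed)
        labels = list(CANONICAL_TRNAS)
        geometry = [(base_d[t], strands[t]) for t in labels]
        perm_rng.shuffle(geometry)
        base_d = {t: g[0] for t, g in zip(labels, geometry)}
        strands = {t: g[1] for t, g in zip(labels, geometry)}

    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dev_u: dict[str, dict[str, float]] = {sp: {} for sp in species}
    dev_d: dict[str, dict[str, float]] = {sp: {} for sp in species}
    for trna in CANONICAL_TRNAS:
        du, dd = simulate_bivariate_bm(
            tree, config.rho_usage_position,
            config.bm_sigma_usage, config.bm_sigma_position, rng,
        )
        for sp in species:
            dev_u[sp][trna] = du[sp]
            dev_d[sp][trna] = dd[sp]

    records, usage, distances, realized_counts = {}, {}, {}, {}
    for i, sp in enumerate(species):
        raw = {t: base_u[t] * 10.0 ** dev_u[sp][t] for t in CANONICAL_TRNAS}
        tot = sum(raw.values())
        target = {t: v / tot for t, v in raw.items()}
        want = {t: int(round(base_d[t] * 10.0 ** dev_d[sp][t]))
                for t in CANONICAL_TRNAS}
        accession = f"SYN{i + 1:04d}"
        record, realized = build_genome(
            accession, sp, want, strands, target, config, rng,
            with_sequence=with_sequences,
        )
        records[sp] = record
        usage[sp] = target
        distances[sp] = {p.trna: p.distance_bp for p in all_distances(record)}
        realized_counts[sp] = realized
    truth = {
        "rho_usage_position": config.rho_usage_position,
        "gene_order": config.gene_order,
        "base_usage": base_u,
        "base_distances": base_d,
        "strands": strands,
    }
    return CohortSimulation(
        config=config, tree=tree, records=records, usage=usage,
        distances=distances, realized_counts=realized_counts,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# anticodon gradient
# ---------------------------------------------------------------------------

def simulate_anticodon_gradient(
    config: SimulationConfig,
    record: MtGenomeRecord,
    rep_map,
    rng: np.random.Generator,
    convention: str = "codon12_pairing",
) -> tuple[MtGenomeRecord, dict[str, dict]]:
    """Redraw anticodon composition under an exposure-dependent gradient.

    Each of the two scored anticodon positions is G or T independently with
    probability ``logistic(intercept + slope * exposure)``; the remaining
    (wobble-side) position is uniform. Returns a new record plus per-tRNA
    ground truth (exposure, probability, drawn triplet).
    """
    from .deamination import exposure_durations

    exposures = {e.trna: e.exposure
                 for e in exposure_durations(record, rep_map)}
    truth: dict[str, dict] = {}
    new_features = []
    seq = list(record.sequence) if record.sequence is not None else None
    for feat in record.features:
        if feat.kind != "tRNA":
            new_features.append(feat)
            continue
        expo = exposures[feat.label]
        p = 1.0 / (1.0 + math.exp(-(config.deamination_intercept
                                    + config.deamination_slope * expo)))
        scored = []
        for _ in range(2):
            if rng.random() < p:
                scored.append("G" if rng.random() < 0.5 else "T")
            else:
                scored.append("A" if rng.random() < 0.5 else "C")
        wobble = "ACGT"[int(rng.integers(4))]
        if convention == "codon12_pairing":
            # scored positions are the triplet's last two bases (36, 35)
            triplet = wobble + scored[1] + scored[0]
        elif convention == "first_two_5to3":
            triplet = scored[0] + scored[1] + wobble
        else:
            raise MitoError(f"unknown anticodon convention {convention!r}")
        new_feat = replace(feat, anticodon=triplet)
        new_features.append(new_feat)
        if seq is not None:
            lo = feat.intervals[0][0]
            gene_seq = record.subsequence(feat.intervals)
            if feat.strand == "L":
                coding = reverse_complement(gene_seq)
                coding = (coding[: ANTICODON_OFFSET - 1] + triplet
                          + coding[ANTICODON_OFFSET + 2 :])
                gene_seq = reverse_complement(coding)
            else:
                gene_seq = (gene_seq[: ANTICODON_OFFSET - 1] + triplet
                            + gene_seq[ANTICODON_OFFSET + 2 :])
            seq[lo - 1 : lo - 1 + len(gene_seq)] = list(gene_seq)
        truth[feat.label] = {"exposure": expo, "p_gt": p, "anticodon": triplet}
    new_record = MtGenomeRecord(
        accession=record.accession, taxon=record.taxon,
        length_bp=record.length_bp,
        sequence="".join(seq) if seq is not None else None,
        features=new_features,
    )
    return new_record, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixture_genbank(records, directory) -> list[Path]:
    """Write one GenBank flat file per record; round-trips through
    :func:`mitotrna.io.read_genbank`."""
    from .io import write_genbank

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for record in records:
        path = directory / f"{record.accession}.gb"
        write_genbank(record, path)
        paths.append(path)
    return paths


def write_ground_truth(sim: CohortSimulation, path) -> None:
    payload = {
        "config": {k: getattr(sim.config, k) for k in (
            "seed", "n_species", "genome_length", "gene_order",
            "permutation_seed", "rho_usage_position", "bm_sigma_usage",
            "bm_sigma_position", "deamination_slope", "deamination_intercept",
        )},
        "tree_newick": sim.newick(),
        "usage": sim.usage,
        "distances": sim.distances,
        "ground_truth": sim.ground_truth,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
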