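"""Single-strand exposure under strand-displacement mtDNA replication.

Heavy-strand synthesis starts at O_H (in the control region) and displaces
the parental H-strand as single-stranded DNA; light-strand synthesis starts
at O_L (in the WANCY tRNA cluster) once the fork passes it and proceeds in
the opposite direction. A locus between O_L and O_H along the L-synthesis
direction is therefore exposed for a time proportional to its distance
``alpha`` from O_L along that direction; the remaining loci are exposed in
proportion to ``alpha - beta``, where ``beta = genome_length - alpha`` is
the distance along the opposite direction. Long exposure enriches G and T
on the coding strand (deamination of A and C), which is scored here at the
two anticodon positions that pair with the non-degenerate codon positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import pandas as pd

from .geometry import cr_reference_points
from .model import GeometryError, GenomeFeature, MitoError, MtGenomeRecord
from .reference import CANONICAL_ANTICODONS
from .stats import CorrelationResult, pearson_one_tailed

__all__ = [
    "ReplicationMap",
    "ExposureRecord",
    "build_replication_map",
    "classify_replication_group",
    "exposure_durations",
    "anticodon_gt_count",
    "exposure_gt_correlation",
    "write_exposure_table",
]


@dataclass(frozen=True)
class ReplicationMap:
    """Point coordinates of the two replication origins on a circle.

    L-strand synthesis proceeds in increasing-coordinate direction (the
    orientation in which Cys..Pro lie downstream of O_L in the typical
    arrangement).
    """

    o_l: int
    o_h: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.o_l == self.o_h:
            raise GeometryError("O_L and O_H coincide")
        for p in (self.o_l, self.o_h):
            if not (1 <= p <= self.genome_length):
                raise GeometryError(f"origin coordinate {p} outside genome")

    @property
    def between_arc_length(self) -> int:
        return (self.o_h - self.o_l) % self.genome_length


@dataclass(frozen=True)
class ExposureRecord:
    """One tRNA's exposure geometry and anticodon G+T score."""

    trna: str
    group: str  # "between_origins" | "outside"
    alpha: int
    beta: int
    exposure: int
    anticodon: Optional[str]
    gt_count: int


def build_replication_map(record: MtGenomeRecord) -> ReplicationMap:
    """O_L from the rep_origin_L annotation (midpoint), else imputed at the
    midpoint of the tRNA-Asn..tRNA-Cys gap (the WANCY region); O_H from a
    rep_origin_H annotation, else the H-strand CR reference base."""
    L = record.length_bp
    origins_l = record.features_of_kind("rep_origin_L")
    if origins_l:
        o_l = origins_l[0].midpoint(L)
    else:
        trnas = record.trnas
        if "Asn" not in trnas or "Cys" not in trnas:
            raise GeometryError(
                f"{record.accession}: no rep_origin_L and no Asn/Cys tRNAs "
                "to impute O_L from; deamination analysis refused"
            )
        asn_end = trnas["Asn"].intervals[-1][1]
        cys_start = trnas["Cys"].intervals[0][0]
        gap = (cys_start - asn_end) % L
        o_l = (asn_end - 1 + gap // 2) % L + 1
    origins_h = record.features_of_kind("rep_origin_H")
    if origins_h:
        o_h = origins_h[0].midpoint(L)
    else:
        o_h = cr_reference_points(record).h_ref
    return ReplicationMap(o_l=o_l, o_h=o_h, genome_length=L)


def _reference_point(feat: GenomeFeature, length: int, reference_point: str) -> int:
    if reference_point == "five_prime":
        return feat.five_prime()
    if reference_point == "midpoint":
        return feat.midpoint(length)
    raise MitoError(f"unknown reference point {reference_point!r}")


def classify_replication_group(
    record: MtGenomeRecord,
    rep_map: ReplicationMap,
    reference_point: str = "five_prime",
) -> dict[str, str]:
    """Partition tRNAs into 'between_origins' and 'outside'.

    A tRNA is between the origins iff its reference point lies on the arc
    from O_L to O_H walked in the L-synthesis direction. Genes spanning an
    origin point are classified by their reference point, with a warning.
    """
    L = rep_map.genome_length
    arc = rep_map.between_arc_length
    groups: dict[str, str] = {}
    for label, feat in record.trnas.items():
        if feat.covers(rep_map.o_l) or feat.covers(rep_map.o_h):
            warnings.warn(
                f"{record.accession}: tRNA {label} spans a replication "
                "origin; classified by its reference point", stacklevel=2,
            )
        ref = _reference_point(feat, L, reference_point)
        alpha = (ref - rep_map.o_l) % L
        groups[label] = "between_origins" if 0 < alpha <= arc else "outside"
    return groups


def exposure_durations(
    record: MtGenomeRecord,
    rep_map: ReplicationMap,
    reference_point: str = "five_prime",
    convention: str = "codon12_pairing",
) -> list[ExposureRecord]:
    """Exposure duration (in bp of fork travel) for every annotated tRNA.

    ``alpha + beta = genome_length`` holds for every gene; exposure is
    ``alpha`` for the between-origins group and ``alpha - beta`` otherwise.
    """
    L = rep_map.genome_length
    groups = classify_replication_group(record, rep_map, reference_point)
    records = []
    for label in sorted(record.trnas):
        feat = record.trnas[label]
        ref = _reference_point(feat, L, reference_point)
        alpha = (ref - rep_map.o_l) % L
        beta = L - alpha
        group = groups[label]
        exposure = alpha if group == "between_origins" else alpha - beta
        anticodon = feat.anticodon or CANONICAL_ANTICODONS.get(label)
        gt = anticodon_gt_count(feat, convention) if anticodon else -1
        records.append(ExposureRecord(
            trna=label, group=group, alpha=alpha, beta=beta,
            exposure=exposure, anticodon=anticodon, gt_count=gt,
        ))
    return records


def anticodon_gt_count(
    feature: GenomeFeature | str, convention: str = "codon12_pairing"
) -> int:
    """G+T count at the two mutation-sensitive anticodon positions.

    ``first_two_5to3`` scores anticodon bases 1-2 reading 5'->3'
    (structural positions 34-35); ``codon12_pairing`` scores the bases that
    pair with codon positions 1-2 (structural positions 36 and 35, i.e. the
    triplet's last two bases). Bases are read on the tRNA gene's coding
    strand. The anticodon comes from the feature annotation or, failing
    that, the canonical vertebrate table.
    """
    if isinstance(feature, GenomeFeature):
        anticodon = feature.anticodon or CANONICAL_ANTICODONS.get(feature.label)
        name = feature.label
    else:
        anticodon = feature
        name = feature
    if not anticodon:
        raise MitoError(f"tRNA {name!r}: anticodon unknown")
    anticodon = anticodon.upper().replace("U", "T")
    if convention == "first_two_5to3":
        scored = anticodon[0:2]
    elif convention == "codon12_pairing":
        scored = anticodon[2] + anticodon[1]
    else:
        raise MitoError(f"unknown anticodon convention {convention!r}")
    return sum(1 for b in scored if b in "GT")


def exposure_gt_correlation(
    records: Sequence[ExposureRecord], subset: str = "all"
) -> CorrelationResult:
    """One-tailed (positive) Pearson correlation of exposure vs G+T count."""
    if subset == "between_origins_only":
        use = [r for r in records if r.group == "between_origins"]
    elif subset == "all":
        use = list(records)
    else:
        raise MitoError(f"unknown subset {subset!r}")
    use = [r for r in use if r.gt_count >= 0]
    if len(use) < 3:
        raise MitoError(f"need >= 3 exposure records, got {len(use)}")
    return pearson_one_tailed(
        [r.exposure for r in use], [r.gt_count for r in use], tail="positive"
    )


def write_exposure_table(records: Sequence[ExposureRecord], path) -> pd.DataFrame:
    """TSV output: trna, group, alpha, beta, exposure, anticodon, gt_count."""
    df = pd.DataFrame([{
        "trna": r.trna, "group": r.group, "alpha": r.alpha, "beta": r.beta,
        "exposure": r.exposure, "anticodon": r.anticodon or "",
        "gt_count": r.gt_count,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)
    return df
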