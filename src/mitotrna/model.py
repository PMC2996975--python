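"""Core data model for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive (GenBank convention). A feature that wraps
the origin of the circular coordinate system is represented as two intervals
``(a, length_bp), (1, b)`` -- never as ``start > end``. Strand ``H`` is the
strand whose coding sequence reads in increasing-coordinate direction (the
strand carrying tRNA-Phe next to the control region in the typical vertebrate
arrangement); ``L`` reads in decreasing coordinates (reverse complement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional


class MitoError(Exception):
    """Base class for all package errors."""


class ParseError(MitoError):
    """A GenBank record could not be parsed."""


class ValidationError(MitoError):
    """A record violates a structural invariant."""


class GeometryError(MitoError):
    """A geometric computation was requested on an incapable record."""


class AmbiguousLabelError(MitoError):
    """A tRNA product name could not be resolved to a canonical label."""


class LayoutError(MitoError):
    """A simulated genome layout is infeasible."""


class CorrelationError(MitoError):
    """A correlation is undefined (degenerate input)."""


class ContrastError(MitoError):
    """Independent contrasts cannot be computed (polytomy, label mismatch)."""


FEATURE_KINDS = (
    "CDS",
    "tRNA",
    "rRNA",
    "control_region",
    "rep_origin_L",
    "rep_origin_H",
)


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature on a circular mitochondrial genome.

    ``intervals`` are ordered in the genomic (increasing-coordinate) reading
    of the feature's arc; for a wrapped feature the terminal interval restarts
    at 1. The coding 5' end is the first base of the arc for H-strand
    features and the last base of the arc for L-strand features.
    """

    kind: str
    label: str
    strand: str  # "H" or "L"
    intervals: tuple[tuple[int, int], ...]
    anticodon: Optional[str] = None  # triplet, coding-strand 5'->3' (tRNA only)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ValidationError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if not self.intervals:
            raise ValidationError(f"feature {self.label!r} has no intervals")
        for start, end in self.intervals:
            if start < 1 or end < start:
                raise ValidationError(
                    f"feature {self.label!r}: bad interval ({start}, {end}); "
                    "wrap-around must be encoded as two intervals"
                )
        if self.anticodon is not None:
            ac = self.anticodon.upper()
            if len(ac) != 3 or any(b not in "ACGT" for b in ac):
                raise ValidationError(
                    f"feature {self.label!r}: anticodon {self.anticodon!r} is not "
                    "a DNA triplet"
                )
            object.__setattr__(self, "anticodon", ac)

    @property
    def wraps(self) -> bool:
        return len(self.intervals) > 1 and self.intervals[-1][0] == 1

    def span_bp(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def five_prime(self) -> int:
        """Genomic coordinate of the coding-strand 5' base."""
        if self.strand == "H":
            return self.intervals[0][0]
        return self.intervals[-1][1]

    def three_prime(self) -> int:
        if self.strand == "H":
            return self.intervals[-1][1]
        return self.intervals[0][0]

    def midpoint(self, length_bp: int) -> int:
        """Circular midpoint of the feature's arc (1-based)."""
        start = self.intervals[0][0]
        offset = (self.span_bp() - 1) // 2
        return (start - 1 + offset) % length_bp + 1

    def covers(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.intervals)


@dataclass
class MtGenomeRecord:
    """An annotated circular mitochondrial genome."""

    accession: str
    taxon: str
    length_bp: int
    circular: bool = True
    sequence: Optional[str] = None
    features: list[GenomeFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"{self.accession}: length_bp must be positive")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length_bp:
                raise ValidationError(
                    f"{self.accession}: sequence length {len(self.sequence)} != "
                    f"length_bp {self.length_bp}"
                )
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"{self.accession}: sequence contains non-ACGTN symbols {bad}"
                )
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        seen_trna: set[str] = set()
        for feat in self.features:
            for start, end in feat.intervals:
                if end > self.length_bp:
                    raise ValidationError(
                        f"{self.accession}: feature {feat.label!r} interval "
                        f"({start}, {end}) exceeds genome length {self.length_bp}"
                    )
            if feat.kind == "tRNA":
                if feat.label in seen_trna:
                    raise ValidationError(
                        f"{self.accession}: duplicate canonical tRNA label "
                        f"{feat.label!r}"
                    )
                seen_trna.add(feat.label)
        n_cr = len(self.features_of_kind("control_region"))
        if n_cr > 1:
            raise ValidationError(
                f"{self.accession}: {n_cr} control_region features; designate one"
            )
        if len(self.features_of_kind("rep_origin_L")) > 1:
            raise ValidationError(f"{self.accession}: multiple rep_origin_L features")

    @property
    def geometry_capable(self) -> bool:
        """True when CR-anchored distance analyses are possible."""
        return len(self.features_of_kind("control_region")) == 1

    # -- accessors ---------------------------------------------------------

    def features_of_kind(self, kind: str) -> list[GenomeFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def control_region(self) -> GenomeFeature:
        crs = self.features_of_kind("control_region")
        if len(crs) != 1:
            raise GeometryError(
                f"{self.accession}: record is geometry-incapable "
                f"({len(crs)} control_region features)"
            )
        return crs[0]

    @property
    def trnas(self) -> dict[str, GenomeFeature]:
        return {f.label: f for f in self.features_of_kind("tRNA")}

    def trna(self, label: str) -> GenomeFeature:
        try:
            return self.trnas[label]
        except KeyError:
            raise MitoError(
                f"{self.accession}: tRNA {label!r} not annotated"
            ) from None

    def subsequence(self, intervals: Iterable[tuple[int, int]]) -> str:
        """Concatenated genomic (H-strand sense) sequence over intervals."""
        if self.sequence is None:
            raise MitoError(f"{self.accession}: record has no sequence")
        return "".join(self.sequence[s - 1 : e] for s, e in intervals)

    def rotated(self, shift: int) -> "MtGenomeRecord":
        """Record with the coordinate origin rotated by ``shift`` bp.

        Base at old coordinate p moves to ``((p - 1 + shift) mod L) + 1``.
        Used by rotation-invariance checks; annotation-only records rotate
        their features alone.
        """
        L = self.length_bp

        def move(p: int) -> int:
            return (p - 1 + shift) % L + 1

        def rot_feature(feat: GenomeFeature) -> GenomeFeature:
            # Re-derive the arc from its genomic start and span, then re-split
            # at the origin if needed.
            start = move(feat.intervals[0][0])
            span = feat.span_bp()
            end = start + span - 1
            if end <= L:
                ivals: tuple[tuple[int, int], ...] = ((start, end),)
            else:
                ivals = ((start, L), (1, end - L))
            return replace(feat, intervals=ivals)

        seq = None
        if self.sequence is not None:
            k = shift % L
            seq = self.sequence[L - k :] + self.sequence[: L - k] if k else self.sequence
        return MtGenomeRecord(
            accession=self.accession,
            taxon=self.taxon,
            length_bp=L,
            circular=self.circular,
            sequence=seq,
            features=[rot_feature(f) for f in self.features],
        )
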