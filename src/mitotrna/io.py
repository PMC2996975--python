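"""Reading and writing annotated mitochondrial genome records.

GenBank flat files are read with Biopython and normalized into
:class:`~mitotrna.model.MtGenomeRecord`: D-loop / control-region misc
features become ``control_region``, replication origins outside the control
region become ``rep_origin_L``, and tRNA product names plus anticodon
qualifiers are canonicalized to the 22-name vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genetic_code import AA1_TO_AA3
from .model import (
    AmbiguousLabelError,
    GenomeFeature,
    MtGenomeRecord,
    ParseError,
    ValidationError,
)
from .reference import TYPICAL_GENE_ORDER

__all__ = [
    "read_genbank",
    "write_genbank",
    "canonical_trna_label",
    "check_typical_order",
    "write_feature_table",
    "OrderReport",
]

_AA3_SET = set(AA1_TO_AA3.values())

#: Anticodon -> canonical label for the two-tRNA amino acids.
LEU_SER_BY_ANTICODON = {"TAA": "Leu1", "TAG": "Leu2", "TGA": "Ser1", "GCT": "Ser2"}

_FAMILY_NOTES = {
    "UUR": "Leu1", "TTR": "Leu1", "CUN": "Leu2", "CTN": "Leu2",
    "UCN": "Ser1", "TCN": "Ser1", "AGY": "Ser2", "AGC": "Ser2",
    "1": None, "2": None,  # resolved below with the amino acid
}

_CDS_SYNONYMS = {
    "ND1": "ND1", "ND2": "ND2", "ND3": "ND3", "ND4": "ND4", "ND4L": "ND4L",
    "ND5": "ND5", "ND6": "ND6", "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3",
    "NAD4": "ND4", "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "COX1": "CO1", "COX2": "CO2", "COX3": "CO3", "COI": "CO1", "COII": "CO2",
    "COIII": "CO3", "CO1": "CO1", "CO2": "CO2", "CO3": "CO3",
    "ATP6": "ATP6", "ATP8": "ATP8", "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "ATPASE 6": "ATP6", "ATPASE 8": "ATP8",
    "CYTB": "CYTB", "COB": "CYTB", "CYB": "CYTB",
}


def canonical_trna_label(product_text: str, anticodon: Optional[str] = None) -> str:
    """Resolve a tRNA product name to one of the 22 canonical labels.

    Leu and Ser are disambiguated by the anticodon (TAA -> Leu1/UUR,
    TAG -> Leu2/CUN, TGA -> Ser1/UCN, GCT -> Ser2/AGY) or by a codon-family
    note embedded in the product text, e.g. ``tRNA-Leu (CUN)``.
    """
    text = product_text.strip()
    m = re.search(r"t?RNA[-_ ]?([A-Za-z]{3})", text, flags=re.IGNORECASE)
    if not m:
        raise AmbiguousLabelError(f"cannot parse tRNA product {product_text!r}")
    aa3 = m.group(1).capitalize()
    if aa3 not in _AA3_SET:
        raise AmbiguousLabelError(
            f"unknown amino acid {aa3!r} in product {product_text!r}"
        )
    if aa3 not in ("Leu", "Ser"):
        return aa3
    # Two-tRNA amino acids: try the anticodon first, then a family note.
    if anticodon is not None:
        ac = anticodon.upper().replace("U", "T")
        if ac in LEU_SER_BY_ANTICODON:
            label = LEU_SER_BY_ANTICODON[ac]
            if label.startswith(aa3):
                return label
            raise AmbiguousLabelError(
                f"anticodon {anticodon!r} conflicts with product {product_text!r}"
            )
    tail = text[m.end():].upper()
    for token, label in _FAMILY_NOTES.items():
        if label and token in tail and label.startswith(aa3):
            return label
    m2 = re.search(r"\b([12])\b", tail)
    if m2:
        return f"{aa3}{m2.group(1)}"
    raise AmbiguousLabelError(
        f"tRNA-{aa3} needs an anticodon or codon-family note to resolve "
        f"({product_text!r})"
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_ANTICODON_SEQ_RE = re.compile(r"seq\s*:\s*([acgtuACGTU]{3})")
_ANTICODON_NOTE_RE = re.compile(r"anticodon[:\s]+([ACGTUacgtu]{3})\b")


def _feature_anticodon(feat: SeqFeature) -> Optional[str]:
    for q in feat.qualifiers.get("anticodon", []):
        m = _ANTICODON_SEQ_RE.search(q)
        if m:
            return m.group(1).upper().replace("U", "T")
        if len(q.strip()) == 3:
            return q.strip().upper().replace("U", "T")
    for q in feat.qualifiers.get("note", []):
        m = _ANTICODON_NOTE_RE.search(q)
        if m:
            return m.group(1).upper().replace("U", "T")
    return None


def _intervals_from_location(loc, length_bp: int) -> tuple[tuple[int, int], ...]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    ivals = [(int(p.start) + 1, int(p.end)) for p in parts]
    # Normalize to genomic arc order: a wrapped feature is (.., L), (1, ..).
    if len(ivals) > 1:
        ivals.sort(key=lambda se: se[0])
        if ivals[-1][1] == length_bp and ivals[0][0] == 1:
            ivals = ivals[1:] + ivals[:1]
        else:
            # contiguous split intervals (e.g. writer artifacts): merge
            merged = [ivals[0]]
            for s, e in ivals[1:]:
                if s == merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            ivals = merged
    return tuple(ivals)


def _cds_label(feat: SeqFeature) -> str:
    for key in ("gene", "product"):
        for q in feat.qualifiers.get(key, []):
            token = q.strip().upper().replace("SUBUNIT ", "").replace("-", "")
            if token in _CDS_SYNONYMS:
                return _CDS_SYNONYMS[token]
            # fall back: compress e.g. "NADH dehydrogenase subunit 4L"
            m = re.search(r"NADH.*?(\d+L?)", q, flags=re.IGNORECASE)
            if m:
                return f"ND{m.group(1).upper()}"
            m = re.search(r"cytochrome c oxidase.*?(I{1,3}|\d)", q, flags=re.IGNORECASE)
            if m:
                sub = m.group(1).upper()
                return f"CO{len(sub) if 'I' in sub else sub}"
            m = re.search(r"ATP(?:ase)?\s*(?:synthase)?.*?([68])", q, flags=re.IGNORECASE)
            if m:
                return f"ATP{m.group(1)}"
            if re.search(r"cytochrome b", q, flags=re.IGNORECASE):
                return "CYTB"
    return (feat.qualifiers.get("gene") or feat.qualifiers.get("product") or ["CDS"])[0]


def _rrna_label(feat: SeqFeature) -> str:
    text = " ".join(feat.qualifiers.get("product", []) +
                    feat.qualifiers.get("gene", [])).lower()
    if "12" in text or "s-rrna" in text or "small" in text or "rrns" in text:
        return "rrnS"
    if "16" in text or "l-rrna" in text or "large" in text or "rrnl" in text:
        return "rrnL"
    return "rRNA"


def _is_control_region(feat: SeqFeature) -> bool:
    if feat.type in ("D-loop", "D_loop"):
        return True
    text = " ".join(sum(feat.qualifiers.values(), [])).lower()
    return feat.type == "misc_feature" and ("control region" in text or "d-loop" in text)


def _convert_record(rec: SeqRecord) -> MtGenomeRecord:
    length = len(rec.seq)
    if length == 0:
        raise ParseError(f"{rec.id}: record has no LOCUS length / sequence")
    seq = str(rec.seq).upper()
    has_sequence = bool(seq) and set(seq) != {"N"}
    features: list[GenomeFeature] = []
    cr_feature = None
    for feat in rec.features:
        if feat.type == "source":
            continue
        strand = "L" if feat.location.strand == -1 else "H"
        ivals = _intervals_from_location(feat.location, length)
        if _is_control_region(feat):
            cr_feature = GenomeFeature("control_region", "CR", strand, ivals)
            continue
        if feat.type == "rep_origin":
            text = " ".join(sum(feat.qualifiers.values(), [])).lower()
            if "h-strand" in text or "heavy" in text:
                kind = "rep_origin_H"
            else:
                kind = "rep_origin_L"
            features.append(GenomeFeature(kind, "OH" if kind == "rep_origin_H" else "OL",
                                          strand, ivals))
            continue
        if feat.type == "tRNA":
            product = (feat.qualifiers.get("product") or feat.qualifiers.get("gene")
                       or [""])[0]
            anticodon = _feature_anticodon(feat)
            label = canonical_trna_label(product, anticodon)
            features.append(GenomeFeature("tRNA", label, strand, ivals, anticodon))
            continue
        if feat.type == "rRNA":
            features.append(GenomeFeature("rRNA", _rrna_label(feat), strand, ivals))
            continue
        if feat.type == "CDS":
            features.append(GenomeFeature("CDS", _cds_label(feat), strand, ivals))
            continue
        # other feature types (gene, misc) are ignored
    if cr_feature is not None:
        features.insert(0, cr_feature)
    taxon = rec.annotations.get("organism") or rec.description or rec.id
    return MtGenomeRecord(
        accession=rec.id.split(".")[0],
        taxon=taxon,
        length_bp=length,
        circular=rec.annotations.get("topology", "circular") == "circular",
        sequence=seq if has_sequence else None,
        features=features,
    )


def read_genbank(path) -> list[MtGenomeRecord]:
    """Read a (single- or multi-record) GenBank flat file.

    Records without a control-region annotation load but are flagged
    geometry-incapable; a duplicate canonical tRNA label raises
    :class:`ValidationError`.
    """
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not seq_records:
        raise ParseError(f"{path}: no GenBank records found")
    return [_convert_record(r) for r in seq_records]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _location_for(feature: GenomeFeature, length_bp: int):
    strand = 1 if feature.strand == "H" else -1
    parts = [SimpleLocation(s - 1, e, strand) for s, e in feature.intervals]
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


_KIND_TO_GB = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D-loop",
    "rep_origin_L": "rep_origin",
    "rep_origin_H": "rep_origin",
}

_TRNA_PRODUCT = {
    "Leu1": "tRNA-Leu (UUR)", "Leu2": "tRNA-Leu (CUN)",
    "Ser1": "tRNA-Ser (UCN)", "Ser2": "tRNA-Ser (AGY)",
}


def write_genbank(record: MtGenomeRecord, path) -> None:
    """Write one record as a GenBank flat file readable by :func:`read_genbank`."""
    seq = Seq(record.sequence if record.sequence is not None
              else "N" * record.length_bp)
    rec = SeqRecord(
        seq,
        id=record.accession,
        name=record.accession[:16],
        description=record.taxon,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.taxon,
            "date": "01-JAN-2000",
            "data_file_division": "VRT",
            "accessions": [record.accession],
        },
    )
    for feat in record.features:
        qualifiers: dict[str, list[str]] = {}
        if feat.kind == "tRNA":
            aa3 = feat.label[:3]
            qualifiers["product"] = [_TRNA_PRODUCT.get(feat.label, f"tRNA-{aa3}")]
            if feat.anticodon:
                qualifiers["note"] = [f"anticodon:{feat.anticodon}"]
        elif feat.kind == "CDS":
            qualifiers["gene"] = [feat.label]
            qualifiers["codon_start"] = ["1"]
            qualifiers["transl_table"] = ["2"]
        elif feat.kind == "rRNA":
            qualifiers["product"] = [
                "12S ribosomal RNA" if feat.label == "rrnS" else "16S ribosomal RNA"
            ]
        elif feat.kind == "control_region":
            qualifiers["note"] = ["control region"]
        elif feat.kind == "rep_origin_L":
            qualifiers["note"] = ["origin of L-strand replication"]
        elif feat.kind == "rep_origin_H":
            qualifiers["note"] = ["origin of H-strand replication"]
        rec.features.append(
            SeqFeature(_location_for(feat, record.length_bp),
                       type=_KIND_TO_GB[feat.kind], qualifiers=qualifiers)
        )
    SeqIO.write([rec], str(path), "genbank")


def write_feature_table(records: Sequence[MtGenomeRecord], path) -> pd.DataFrame:
    """Normalized feature table as TSV: one row per feature interval set."""
    rows = []
    for record in records:
        for feat in record.features:
            rows.append({
                "accession": record.accession,
                "label": feat.label,
                "kind": feat.kind,
                "strand": feat.strand,
                "start": feat.intervals[0][0],
                "end": feat.intervals[-1][1],
                "anticodon": feat.anticodon or "",
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# typical-order report
# ---------------------------------------------------------------------------

@dataclass
class OrderReport:
    """Diagnostic comparison of a record's gene order with the typical one."""

    observed: tuple[str, ...]
    expected: tuple[str, ...]
    matches: bool
    mismatches: tuple[tuple[int, str, str], ...]  # (index, expected, observed)

    def __str__(self) -> str:
        if self.matches:
            return "match"
        parts = ", ".join(f"position {i}: expected {e}, found {o}"
                          for i, e, o in self.mismatches[:10])
        return f"mismatch ({len(self.mismatches)} positions: {parts})"


def check_typical_order(record: MtGenomeRecord) -> OrderReport:
    """Compare a record's circular gene order with the typical arrangement.

    Genes are listed in circular order starting from the control region's 3'
    end on the H-strand (falling back to coordinate 1 when no control region
    is annotated). Purely diagnostic; never raises.
    """
    genes = [f for f in record.features if f.kind in ("CDS", "tRNA", "rRNA")]
    if record.geometry_capable:
        from .geometry import cr_reference_points

        anchor = cr_reference_points(record).h_ref
    else:
        anchor = 0
    L = record.length_bp
    genes.sort(key=lambda f: (f.intervals[0][0] - anchor - 1) % L)
    observed = tuple(f.label for f in genes)
    expected = TYPICAL_GENE_ORDER
    if len(observed) != len(expected) or set(observed) != set(expected):
        mism = tuple(
            (i, e, o)
            for i, (e, o) in enumerate(zip(expected, observed))
            if e != o
        )
        return OrderReport(observed, expected, False, mism or ((0, "<set>", "<set>"),))
    mism = tuple((i, e, o) for i, (e, o) in enumerate(zip(expected, observed)) if e != o)
    return OrderReport(observed, expected, not mism, mism)
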