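"""End-to-end orchestration of the analysis stages.

Given a cohort of annotated genomes, a rooted composite tree, and an
analysis configuration (group labels, exclusion lists, offsets, anticodon
convention), the pipeline reproduces each analysis stage: the per-genome
hydropathy rank test, the pooled and per-group contrast correlations with
and without the outlier tRNAs, the per-tRNA cross-taxon mean correlation,
the per-tRNA meta-analysis, and the replication-exposure anticodon
analysis. All stages write TSV tables plus one JSON summary and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .codon import count_codons, trna_usage
from .contrasts import (
    ContrastPair,
    contrast_correlation,
    independent_contrasts,
    log_transform,
    read_tree,
)
from .deamination import (
    build_replication_map,
    exposure_durations,
    exposure_gt_correlation,
    write_exposure_table,
)
from .genetic_code import CANONICAL_TRNAS, HYDROPHOBIC_TRNAS
from .geometry import all_distances, cr_reference_points, trna_distance
from .io import read_genbank
from .model import MitoError, MtGenomeRecord
from .stats import (
    MetaResult,
    RankTestResult,
    combine_correlations,
    mann_whitney_u,
    pearson_one_tailed,
)

log = logging.getLogger("mitotrna")

__all__ = [
    "AnalysisConfig",
    "CohortData",
    "load_cohort",
    "run_hydropathy_test",
    "run_contrast_correlations",
    "run_meta",
    "run_deamination",
    "run_all",
]


@dataclass
class AnalysisConfig:
    """Structured configuration of one full pipeline run."""

    genome_paths: list[str] = field(default_factory=list)
    tree_path: Optional[str] = None
    groups: dict[str, str] = field(default_factory=dict)  # accession -> group
    exclude_taxa: list[str] = field(default_factory=list)
    exclude_trnas: list[str] = field(default_factory=list)  # e.g. Leu2, Thr
    offsets: list[int] = field(default_factory=lambda: [0, 150, -150, 500, -500])
    anticodon_convention: str = "codon12_pairing"
    output_dir: str = "mitotrna_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self, accessions: Sequence[str]) -> None:
        for acc in accessions:
            if self.groups and acc not in self.groups:
                raise MitoError(f"accession {acc} has no group label")
        for g in set(self.groups.values()):
            if g not in ("stable", "rearranged"):
                raise MitoError(f"unknown group label {g!r}")
        for t in self.exclude_trnas:
            if t not in CANONICAL_TRNAS:
                raise MitoError(f"excluded tRNA {t!r} is not a canonical label")


@dataclass
class CohortData:
    """Per-species usage and distance tables plus the tree."""

    records: dict[str, MtGenomeRecord]  # keyed by taxon (tree tip label)
    tree: Optional[dendropy.Tree]
    usage: dict[str, dict[str, float]]  # taxon -> trna -> rel freq
    distances: dict[str, dict[str, int]]  # taxon -> trna -> bp
    groups: dict[str, str]  # taxon -> "stable" | "rearranged"


def load_cohort(
    config: AnalysisConfig,
    records: Optional[Sequence[MtGenomeRecord]] = None,
    tree: Optional[dendropy.Tree] = None,
    usage: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> CohortData:
    """Assemble cohort tables from GenBank files or in-memory records.

    Usage comes from codon counting when sequences are present; a
    pre-computed usage table may be supplied for annotation-only records.
    """
    if records is None:
        records = []
        for path in config.genome_paths:
            records.extend(read_genbank(path))
    if tree is None and config.tree_path:
        tree = read_tree(config.tree_path)
    by_taxon: dict[str, MtGenomeRecord] = {}
    usage_out: dict[str, dict[str, float]] = {}
    dist_out: dict[str, dict[str, int]] = {}
    groups: dict[str, str] = {}
    for record in records:
        taxon = record.taxon
        by_taxon[taxon] = record
        if usage is not None and taxon in usage:
            usage_out[taxon] = dict(usage[taxon])
        elif record.sequence is not None:
            usage_out[taxon] = trna_usage(count_codons(record)).rel_freq
        if record.geometry_capable:
            dist_out[taxon] = {
                p.trna: p.distance_bp for p in all_distances(record)
            }
        else:
            log.warning("%s: geometry-incapable record skipped for distances",
                        record.accession)
        if config.groups:
            groups[taxon] = config.groups.get(record.accession, "stable")
        else:
            groups[taxon] = "stable"
    return CohortData(records=by_taxon, tree=tree, usage=usage_out,
                      distances=dist_out, groups=groups)


# ---------------------------------------------------------------------------
# stage 1: hydropathy rank test
# ---------------------------------------------------------------------------

def run_hydropathy_test(
    cohort: CohortData,
) -> tuple[dict[str, RankTestResult], pd.DataFrame]:
    """Per-genome Mann-Whitney U of hydrophobic vs hydrophilic distances."""
    results: dict[str, RankTestResult] = {}
    rows = []
    for taxon, dists in cohort.distances.items():
        missing = set(CANONICAL_TRNAS) - set(dists)
        if missing:
            log.warning("%s: missing tRNAs %s; genome skipped",
                        taxon, sorted(missing))
            continue
        hydro = [dists[t] for t in sorted(HYDROPHOBIC_TRNAS)]
        philic = [dists[t] for t in sorted(set(CANONICAL_TRNAS) - HYDROPHOBIC_TRNAS)]
        res = mann_whitney_u(hydro, philic)
        results[taxon] = res
        for t in sorted(dists):
            rows.append({
                "taxon": taxon,
                "trna": t,
                "group": "hydrophobic" if t in HYDROPHOBIC_TRNAS else "hydrophilic",
                "distance_bp": dists[t],
                "U": res.U,
                "p_two_tailed": res.p_two_tailed,
            })
    return results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 2: contrast correlations
# ---------------------------------------------------------------------------

def _pruned_tree(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    sub = tree.extract_tree_with_taxa_labels(labels=set(keep))
    sub.suppress_unifurcations()
    return sub

def _contrasts_per_trna(
    cohort: CohortData,
    taxa: Sequence[str],
    trnas: Sequence[str],
    pseudocount_rel: float = 1e-4,
) -> dict[str, list[ContrastPair]]:
    """Per-tRNA standardized contrasts of (log10 usage, log10 distance)."""
    if cohort.tree is None:
        raise MitoError("contrast analyses need a tree")
    taxa = [t for t in taxa if t in cohort.usage and t in cohort.distances]
    if len(taxa) < 3:
        raise MitoError(f"need >= 3 usable taxa, got {len(taxa)}")
    tree = _pruned_tree(cohort.tree, taxa)
    out: dict[str, list[ContrastPair]] = {}
    for trna in trnas:
        x = log_transform({t: cohort.usage[t][trna] for t in taxa},
                          pseudocount=pseudocount_rel)
        y = log_transform({t: float(cohort.distances[t][trna]) for t in taxa})
        out[trna] = independent_contrasts(tree, x, y)
    return out


_GRID = (
    ("all", None),
    ("stable", "stable"),
    ("rearranged", "rearranged"),
)


def run_contrast_correlations(
    config: AnalysisConfig, cohort: CohortData
) -> dict[str, dict]:
    """The full grid of pooled and per-tRNA-mean correlation analyses.

    For each genome group (all / stable / rearranged), pooled contrasts are
    correlated with and without the configured outlier tRNAs and excluded
    taxa; cross-taxon per-tRNA means give the 22-point (and 20-point)
    ancient-adaptation analysis.
    """
    results: dict[str, dict] = {}
    all_taxa = sorted(cohort.usage)
    excl_taxa = set(config.exclude_taxa)
    excl_trnas = set(config.exclude_trnas)
    for group_name, group in _GRID:
        taxa = [t for t in all_taxa
                if group is None or cohort.groups.get(t) == group]
        if len(taxa) < 3:
            continue
        variants = {
            "full": (taxa, list(CANONICAL_TRNAS)),
            "excl_outlier_trnas": (
                taxa, [t for t in CANONICAL_TRNAS if t not in excl_trnas]),
        }
        if excl_taxa:
            variants["excl_taxa"] = (
                [t for t in taxa if t not in excl_taxa], list(CANONICAL_TRNAS))
        for vname, (vtaxa, vtrnas) in variants.items():
            if len(vtaxa) < 3:
                continue
            per_trna = _contrasts_per_trna(cohort, vtaxa, vtrnas)
            pooled = [p for pairs in per_trna.values() for p in pairs]
            key = f"pooled_{group_name}_{vname}"
            entry = {
                "pearson": contrast_correlation(pooled, "pearson").to_dict(),
                "spearman": contrast_correlation(pooled, "spearman").to_dict(),
                "n_taxa": len(vtaxa),
                "n_trnas": len(vtrnas),
            }
            results[key] = entry
        # per-tRNA cross-taxon means (ancient-adaptation analysis)
        mean_u = [float(np.mean([np.log10(cohort.usage[t][trna])
                                 for t in taxa])) for trna in CANONICAL_TRNAS]
        mean_d = [float(np.mean([np.log10(cohort.distances[t][trna])
                                 for t in taxa])) for trna in CANONICAL_TRNAS]
        results[f"trna_means_{group_name}"] = pearson_one_tailed(
            mean_u, mean_d, tail="negative").to_dict()
        if excl_trnas:
            keep = [i for i, t in enumerate(CANONICAL_TRNAS)
                    if t not in excl_trnas]
            results[f"trna_means_{group_name}_excl_outliers"] = (
                pearson_one_tailed([mean_u[i] for i in keep],
                                   [mean_d[i] for i in keep],
                                   tail="negative").to_dict())
    return results


# ---------------------------------------------------------------------------
# stage 3: per-tRNA meta-analysis
# ---------------------------------------------------------------------------

def run_meta(config: AnalysisConfig, cohort: CohortData) -> MetaResult:
    """Per-tRNA contrast correlations combined across the 22 gene sets."""
    taxa = sorted(set(cohort.usage) & set(cohort.distances))
    per_trna = _contrasts_per_trna(cohort, taxa, CANONICAL_TRNAS)
    studies = []
    for trna, pairs in per_trna.items():
        if len(pairs) < 3:
            continue
        try:
            res = contrast_correlation(pairs, "pearson", tail="negative")
        except MitoError:
            # e.g. a tRNA adjacent to the CR whose distance never varies
            log.warning("tRNA %s: degenerate contrasts, dropped from meta",
                        trna)
            continue
        studies.append((trna, res.r, res.n, res.p_one_tailed))
    if len(studies) < 2:
        raise MitoError("fewer than 2 usable tRNA families for meta-analysis")
    return combine_correlations(studies)


# ---------------------------------------------------------------------------
# stage 4: deamination / exposure analysis
# ---------------------------------------------------------------------------

def run_deamination(
    config: AnalysisConfig, record: MtGenomeRecord
) -> dict[str, object]:
    """Exposure table and 13-gene / 22-gene correlations, both conventions."""
    rep_map = build_replication_map(record)
    out: dict[str, object] = {"o_l": rep_map.o_l, "o_h": rep_map.o_h}
    for convention in ("codon12_pairing", "first_two_5to3"):
        records = exposure_durations(record, rep_map, convention=convention)
        entry: dict[str, object] = {
            "records": records,
            "n_between": sum(r.group == "between_origins" for r in records),
            "n_total": len(records),
        }
        for subset in ("between_origins_only", "all"):
            try:
                entry[subset] = exposure_gt_correlation(records, subset).to_dict()
            except MitoError as exc:
                entry[subset] = {"error": str(exc)}
        out[convention] = entry
    return out


# ---------------------------------------------------------------------------
# run everything
# ---------------------------------------------------------------------------

def run_all(
    config: AnalysisConfig,
    records: Optional[Sequence[MtGenomeRecord]] = None,
    tree: Optional[dendropy.Tree] = None,
    usage: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> dict:
    """Run every stage and write TSV tables plus one JSON summary."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config, records=records, tree=tree, usage=usage)
    config.validate([r.accession for r in cohort.records.values()])
    summary: dict = {"n_genomes": len(cohort.records)}

    utests, table = run_hydropathy_test(cohort)
    if not table.empty:
        table.to_csv(outdir / "hydropathy.tsv", sep="\t", index=False)
    summary["hydropathy"] = {t: r.to_dict() for t, r in sorted(utests.items())}
    log.info("hydropathy stage done (%.2fs)", time.time() - t0)

    if cohort.tree is not None and len(cohort.usage) >= 3:
        summary["contrast_correlations"] = run_contrast_correlations(
            config, cohort)
        meta = run_meta(config, cohort)
        summary["meta"] = meta.to_dict()
        log.info("contrast stages done (%.2fs)", time.time() - t0)

    deamination: dict[str, dict] = {}
    for taxon, record in sorted(cohort.records.items()):
        try:
            res = run_deamination(config, record)
        except MitoError as exc:
            log.warning("%s: deamination skipped (%s)", taxon, exc)
            continue
        conv = res[config.anticodon_convention]
        write_exposure_table(conv["records"],
                             outdir / f"exposure_{record.accession}.tsv")
        deamination[taxon] = {
            "o_l": res["o_l"], "o_h": res["o_h"],
            **{c: {k: v for k, v in res[c].items() if k != "records"}
               for c in ("codon12_pairing", "first_two_5to3")},
        }
    summary["deamination"] = deamination

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline finished in %.2fs", time.time() - t0)
    return summary
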