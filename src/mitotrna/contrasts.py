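"""Felsenstein-style phylogenetically independent contrasts.

For a rooted, strictly binary tree with branch lengths, tip values evolving
by Brownian motion yield n-1 independent standardized contrasts, one per
internal node: ``(x_i - x_j) / sqrt(b_i + b_j)`` with the nodal value set to
the branch-length-weighted average and the parent branch extended by
``b_i b_j / (b_i + b_j)``. Contrast pairs are sign-oriented so that the
x-contrast is non-negative (the usual positive orientation); correlations between
contrasts are computed through the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .model import ContrastError, MitoError
from .stats import (
    CorrelationResult,
    pearson_through_origin,
    spearman_one_tailed,
)

__all__ = [
    "ContrastPair",
    "read_tree",
    "tree_from_newick",
    "log_transform",
    "independent_contrasts",
    "contrast_correlation",
    "write_contrast_table",
]


@dataclass(frozen=True)
class ContrastPair:
    """One internal node's standardized contrast in two variables."""

    node_id: str
    contrast_x: float
    contrast_y: float
    sd: float  # sqrt of the summed (adjusted) branch lengths


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    return tree


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def log_transform(
    values: Mapping[str, float], base: float = 10.0,
    pseudocount: Optional[float] = None,
) -> dict[str, float]:
    """Elementwise logarithm of a species -> value map.

    Zero values are replaced by ``pseudocount`` when one is given (the
    pipeline uses 0.5 / total_sense for codon usage); nonpositive values
    without a pseudocount raise.
    """
    out = {}
    for key, v in values.items():
        if v <= 0:
            if pseudocount is None or v < 0:
                raise MitoError(
                    f"log_transform: nonpositive value {v} for {key!r} "
                    "(supply a pseudocount for zero usage)"
                )
            v = pseudocount
        out[key] = math.log(v, base)
    return out


def _tip_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else str(id(node))


def independent_contrasts(
    tree: dendropy.Tree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    default_branch_length: float = 1.0,
) -> list[ContrastPair]:
    """Standardized contrasts of two variables on a rooted binary tree.

    Branch lengths missing from the newick default to
    ``default_branch_length`` (the composite literature tree carries no rate
    estimates). Polytomies are rejected: resolve them before calling.
    Exactly ``n_tips - 1`` pairs are returned.
    """
    tips = {_tip_label(leaf) for leaf in tree.leaf_node_iter()}
    missing = tips - set(x) | tips - set(y)
    extra = (set(x) | set(y)) - tips
    if missing or extra:
        raise ContrastError(
            f"tip/value label mismatch: missing values for {sorted(missing)}, "
            f"values without tips for {sorted(extra)}"
        )
    pairs: list[ContrastPair] = []
    state: dict[int, tuple[float, float, float]] = {}  # node -> (x, y, extra_b)
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _tip_label(node)
            state[id(node)] = (float(x[label]), float(y[label]), 0.0)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ContrastError(
                f"node with {len(children)} children: resolve polytomies "
                "before computing contrasts"
            )
        ci, cj = children
        xi, yi, exi = state[id(ci)]
        xj, yj, exj = state[id(cj)]
        bi = (ci.edge.length if ci.edge.length is not None
              else default_branch_length) + exi
        bj = (cj.edge.length if cj.edge.length is not None
              else default_branch_length) + exj
        if bi <= 0 or bj <= 0:
            raise ContrastError("branch lengths must be positive")
        sd = math.sqrt(bi + bj)
        cx = (xi - xj) / sd
        cy = (yi - yj) / sd
        if cx < 0 or (cx == 0 and cy < 0):
            cx, cy = -cx, -cy
        counter += 1
        pairs.append(ContrastPair(node_id=f"node{counter}", contrast_x=cx,
                                  contrast_y=cy, sd=sd))
        node_x = (xi / bi + xj / bj) / (1.0 / bi + 1.0 / bj)
        node_y = (yi / bi + yj / bj) / (1.0 / bi + 1.0 / bj)
        state[id(node)] = (node_x, node_y, bi * bj / (bi + bj))
    n_tips = len(tips)
    assert len(pairs) == n_tips - 1
    return pairs


def contrast_correlation(
    pairs: Sequence[ContrastPair],
    method: str = "pearson",
    tail: str = "negative",
) -> CorrelationResult:
    """Correlation of contrast pairs.

    Pearson mode runs through the origin (df = n - 1), since contrasts have
    zero expectation and arbitrary sign. Spearman mode uses the ordinary
    rank correlation with df = n - 2, mirroring how rank correlations of
    contrast data are conventionally reported.
    """
    if len(pairs) < 3:
        raise MitoError(f"need at least 3 contrast pairs, got {len(pairs)}")
    cx = [p.contrast_x for p in pairs]
    cy = [p.contrast_y for p in pairs]
    if method == "pearson":
        return pearson_through_origin(cx, cy, tail=tail)
    if method == "spearman":
        return spearman_one_tailed(cx, cy, tail=tail)
    raise MitoError(f"unknown method {method!r}")


def write_contrast_table(
    pairs_by_trna: Mapping[str, Sequence[ContrastPair]], path
) -> pd.DataFrame:
    """TSV output: node, trna, contrast_usage, contrast_distance."""
    rows = [{
        "node": p.node_id, "trna": trna,
        "contrast_usage": p.contrast_x, "contrast_distance": p.contrast_y,
        "sd": p.sd,
    } for trna, pairs in pairs_by_trna.items() for p in pairs]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
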