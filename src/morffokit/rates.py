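"""Relative and absolute substitution rates by internode tip-to-root sums.

For every internal node (internode) of a single-gene phylogram, the branch
lengths from each descendant tip up to that node are summed.  Dividing by the
corresponding sum in a reference plastome phylogram gives a dimensionless
relative rate; dividing by the sum in the matching ultrametric chronogram
(branch lengths in Myr) gives an absolute rate in substitutions/site/Myr.
Only internodes whose descendant taxa form a monophyletic group in both
references are included, which keeps the "root" placement of each comparison
consistent.  Tips flagged as pseudogene-like (frameshift mutations) can be
excluded before estimation.

Conventions: the internode's own stem branch is not part of a tip-to-root
sum (paths start at the internode); internodes need at least two tips; both
references are restricted to the gene tree's taxa before any comparison so
"corresponding sums" are defined even when genes differ in taxon coverage;
gene trees are used as rooted exactly as provided.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PhyloTree

__all__ = [
    "RateEstimate",
    "normalize_label",
    "prune_taxa",
    "enumerate_internodes",
    "tip_to_root_sum",
    "monophyly_consistent",
    "gene_rates",
    "summarize_rates",
    "estimates_to_frame",
]


@dataclass
class RateEstimate:
    """Rates at one internode of a gene tree.

    ``internode_id`` is the canonical sorted descendant-leaf-set key.  When
    ``included`` is False, ``reason`` names the exclusion and the rate fields
    are NaN.
    """

    gene_id: str
    internode_id: str
    n_tips: int
    rel_rate: float
    abs_rate: float
    included: bool
    reason: str = ""


def normalize_label(label: str) -> str:
    """Harmonize taxon labels: trim, collapse whitespace runs to underscores."""
    return re.sub(r"\s+", "_", label.strip())


def _normalized_tree(tree: PhyloTree) -> PhyloTree:
    # deep copy: label normalization must not leak into the caller's namespace
    out = PhyloTree(copy.deepcopy(tree.dendropy_tree))
    for taxon in out.dendropy_tree.taxon_namespace:
        taxon.label = normalize_label(taxon.label)
    return out


def prune_taxa(tree: PhyloTree, drop: set[str]) -> PhyloTree:
    """Remove leaves in ``drop``; unbranched internal nodes are suppressed
    with their incident branch lengths summed, so the path-length matrix among
    survivors is unchanged."""
    if not drop:
        return tree.copy()
    leaves = set(tree.leaf_labels())
    unknown = set(drop) - leaves
    if unknown:
        raise ValueError(f"cannot drop taxa absent from tree: {sorted(unknown)}")
    keep = leaves - set(drop)
    if len(keep) < 2:
        raise ValueError("fewer than 2 leaves would remain after pruning")
    out = tree.copy().dendropy_tree
    out.retain_taxa_with_labels(list(keep))
    return PhyloTree(out)


def _leafset_below(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def internode_key(leafset: frozenset[str] | set[str]) -> str:
    return "|".join(sorted(leafset))


def enumerate_internodes(tree: PhyloTree) -> list[tuple[str, frozenset[str]]]:
    """All internal nodes (including the root) with >= 2 descendant leaves,
    keyed by their sorted descendant-leaf sets."""
    out = []
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        ls = _leafset_below(node)
        if len(ls) >= 2:
            out.append((internode_key(ls), ls))
    return out


def _find_clade_node(tree: PhyloTree, leafset: frozenset[str] | set[str]):
    """The node whose descendant leaf set equals ``leafset``, or None."""
    target = frozenset(leafset)
    tree_leaves = set(tree.leaf_labels())
    if not target.issubset(tree_leaves):
        raise ValueError(f"leaf set contains taxa absent from tree: {sorted(target - tree_leaves)}")
    mrca = tree.dendropy_tree.mrca(taxon_labels=list(target))
    if mrca is None:
        return None
    return mrca if _leafset_below(mrca) == target else None


def tip_to_root_sum(tree: PhyloTree, internode: frozenset[str] | set[str]) -> float:
    """Sum of path lengths from each leaf of the clade to the clade's root.

    The clade root's own stem branch is not included.  Raises if the leaf set
    is not a clade of ``tree``.
    """
    node = _find_clade_node(tree, internode)
    if node is None:
        raise ValueError(f"leaf set is not a clade: {internode_key(internode)}")
    total = 0.0
    for leaf in node.leaf_iter():
        cur = leaf
        while cur is not node:
            total += cur.edge.length or 0.0
            cur = cur.parent_node
    return total


def monophyly_consistent(leafset: frozenset[str] | set[str], reference: PhyloTree) -> bool:
    """True iff ``leafset`` equals the descendant set of some reference node."""
    return _find_clade_node(reference, leafset) is not None


def gene_rates(
    gene_tree: PhyloTree,
    ref_phylogram: PhyloTree,
    ref_chronogram: PhyloTree,
    gene_id: str = "gene",
    flags: dict[str, int] | None = None,
    exclude_pseudogenes: bool = False,
    drop: set[str] | None = None,
) -> list[RateEstimate]:
    """Per-internode relative and absolute rates for one gene tree.

    Pipeline: optionally drop pseudogene-flagged tips (``flags[taxon] > 0``),
    prune ``drop``, restrict both references to the surviving gene taxa, then
    for every gene-tree internode that is monophyletic in both references
    report rel_rate (gene sum / phylogram sum) and abs_rate (gene sum /
    chronogram sum).  Non-monophyletic or degenerate internodes come back
    with ``included=False`` and a reason.
    """
    gene = _normalized_tree(gene_tree)
    phylo = _normalized_tree(ref_phylogram)
    chrono = _normalized_tree(ref_chronogram)

    gene_leaves = set(gene.leaf_labels())
    missing = gene_leaves - set(phylo.leaf_labels())
    if missing:
        raise ValueError(f"gene-tree taxa absent from reference phylogram: {sorted(missing)}")
    missing = gene_leaves - set(chrono.leaf_labels())
    if missing:
        raise ValueError(f"gene-tree taxa absent from reference chronogram: {sorted(missing)}")

    to_drop: set[str] = set(normalize_label(t) for t in (drop or set()))
    if exclude_pseudogenes and flags:
        to_drop |= {normalize_label(t) for t, c in flags.items() if c > 0}
    if flags:
        unknown = {normalize_label(t) for t in flags} - gene_leaves
        if unknown:
            raise ValueError(f"frameshift flags reference taxa absent from gene tree: {sorted(unknown)}")
    to_drop &= gene_leaves
    if to_drop:
        gene = prune_taxa(gene, to_drop)
        gene_leaves = set(gene.leaf_labels())
    if len(gene_leaves) < 2:
        raise ValueError("gene tree has fewer than 2 leaves after exclusions")

    # Restrict references to the gene's taxon coverage.
    phylo_r = prune_taxa(phylo, set(phylo.leaf_labels()) - gene_leaves)
    chrono_r = prune_taxa(chrono, set(chrono.leaf_labels()) - gene_leaves)

    out: list[RateEstimate] = []
    for key, leafset in enumerate_internodes(gene):
        n_tips = len(leafset)
        if not (monophyly_consistent(leafset, phylo_r) and monophyly_consistent(leafset, chrono_r)):
            out.append(RateEstimate(gene_id, key, n_tips, math.nan, math.nan, False, "not_monophyletic_in_reference"))
            continue
        gene_sum = tip_to_root_sum(gene, leafset)
        phylo_sum = tip_to_root_sum(phylo_r, leafset)
        chrono_sum = tip_to_root_sum(chrono_r, leafset)
        if phylo_sum <= 0 or chrono_sum <= 0:
            out.append(RateEstimate(gene_id, key, n_tips, math.nan, math.nan, False, "zero_reference_sum"))
            continue
        out.append(RateEstimate(gene_id, key, n_tips, gene_sum / phylo_sum, gene_sum / chrono_sum, True))
    return out


def summarize_rates(estimates: list[RateEstimate], value: str = "rel_rate") -> pd.DataFrame:
    """Per-gene five-number summaries of included internode rates.

    Quartiles by linear interpolation (numpy's default, R type 7); whiskers at
    the most extreme values within 1.5 x IQR of the quartiles; points beyond
    reported as outliers.  Genes with no included estimate are flagged empty.
    """
    rows = []
    by_gene: dict[str, list[float]] = {}
    for est in estimates:
        by_gene.setdefault(est.gene_id, [])
        if est.included:
            by_gene[est.gene_id].append(getattr(est, value))
    for gene_id, vals in by_gene.items():
        if not vals:
            rows.append(
                {"gene_id": gene_id, "n": 0, "median": math.nan, "q1": math.nan, "q3": math.nan,
                 "whisker_low": math.nan, "whisker_high": math.nan, "outliers": "", "flag": "empty"}
            )
            continue
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
        rows.append(
            {
                "gene_id": gene_id,
                "n": len(arr),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "outliers": ";".join(f"{v:.6g}" for v in sorted(outliers)),
                "flag": "ok",
            }
        )
    return pd.DataFrame(rows)


def estimates_to_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "internode_id": e.internode_id,
                "n_tips": e.n_tips,
                "rel_rate": e.rel_rate,
                "abs_rate": e.abs_rate,
                "included": e.included,
                "reason": e.reason or ".",
            }
            for e in estimates
        ]
    )
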