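"""Grafting extension trees onto the foundation tree.

Each foundation tip is labeled with a genus; each extension tree carries a
genus at its root and accessions at its tips.  Grafting replaces every
foundation tip that matches an extension genus with that extension tree's
root, producing one hybrid tree spanning both markers.  Branch lengths are
copied unscaled from both sources — the two markers evolve at different
rates and no rate calibration between them is attempted — and the junction
edge (the edge that carried the replaced tip) keeps the foundation tip's
branch length, preserving the foundation's depth structure.

Every edge of the result is tagged with its provenance (``foundation``,
``extension`` or ``junction``), which supports the branch-zeroing ablation:
zeroing one part shows how much that marker's branch-length information
contributes to downstream phylogenetic diversity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from skbio import TreeNode

from .io_formats import FeatureTable

__all__ = [
    "GraftOptions",
    "GraftResult",
    "graft",
    "zero_branch_lengths",
    "filter_table_to_tree",
]

FOUNDATION = "foundation"
EXTENSION = "extension"
JUNCTION = "junction"


@dataclass(frozen=True)
class GraftOptions:
    """Options for :func:`graft`.

    ``prune_ungrafted`` removes foundation tips that received no extension
    tree (suppressing the resulting one-child nodes and summing their
    branch lengths).  The junction-edge policy is fixed to "inherit": the
    extension root takes over the replaced tip's branch length.
    """

    prune_ungrafted: bool = False


@dataclass
class GraftResult:
    """A grafted hybrid tree plus its audit trail.

    Edge provenance lives on the tree itself: every non-root node carries a
    ``part`` attribute naming the origin of the edge above it.
    """

    tree: TreeNode
    grafted_genera: list[str] = field(default_factory=list)
    ungrafted_foundation_tips: list[str] = field(default_factory=list)
    unmatched_extension_genera: list[str] = field(default_factory=list)

    def edge_provenance(self) -> dict[str, int]:
        """Count of edges per provenance tag."""
        counts: dict[str, int] = {}
        for node in self.tree.traverse(include_self=False):
            counts[node.part] = counts.get(node.part, 0) + 1
        return counts


def _tag(tree: TreeNode, part: str) -> None:
    for node in tree.traverse(include_self=True):
        node.part = part


def graft(
    foundation: TreeNode,
    extensions: Mapping[str, TreeNode],
    opts: GraftOptions | None = None,
) -> GraftResult:
    """Replace matching foundation tips by their extension trees.

    For each foundation tip whose genus label matches an extension tree,
    the tip node is replaced by a copy of the extension tree's root; the
    junction edge keeps the tip's branch length and extension branch
    lengths are copied without scaling.  A single-tip extension simply
    relabels the tip to its accession.  Unmatched foundation tips stay as
    genus tips (or are pruned per ``opts``); extension genera with no
    matching foundation tip are reported and left out of the tree.  The
    inputs are not mutated.
    """
    opts = opts or GraftOptions()
    tree = foundation.copy()
    _tag(tree, FOUNDATION)

    tips = list(tree.tips())
    tip_names = [t.name for t in tips]
    if len(set(tip_names)) != len(tip_names):
        dup = sorted({n for n in tip_names if tip_names.count(n) > 1})[0]
        raise ValueError(f"foundation tip label {dup!r} is not unique")

    result = GraftResult(tree=tree)
    foundation_tipset = set(tip_names)
    result.unmatched_extension_genera = sorted(set(extensions) - foundation_tipset)

    for tip in tips:
        genus = tip.name
        if genus not in extensions:
            result.ungrafted_foundation_tips.append(genus)
            continue
        ext = extensions[genus].copy()
        _tag(ext, EXTENSION)
        ext.part = JUNCTION
        ext.length = tip.length  # inherit the junction edge, unscaled subtree below
        parent = tip.parent
        if parent is None:  # single-tip foundation
            result.tree = ext
            tree = ext
        else:
            idx = parent.children.index(tip)
            parent.children[idx] = ext
            ext.parent = parent
            tip.parent = None
        result.grafted_genera.append(genus)

    labels = [t.name for t in result.tree.tips()]
    dups = sorted({n for n in labels if labels.count(n) > 1})
    if dups:
        raise ValueError(f"duplicate tip label {dups[0]!r} in grafted tree")

    if opts.prune_ungrafted and result.ungrafted_foundation_tips:
        remaining = set(labels) - set(result.ungrafted_foundation_tips)
        if not remaining:
            raise ValueError("pruning ungrafted tips would empty the tree")
        for tip in list(result.tree.tips()):
            if tip.name in result.ungrafted_foundation_tips:
                tip.parent.remove(tip)
        result.tree.prune()

    return result


def zero_branch_lengths(result: GraftResult | TreeNode, part: str) -> TreeNode:
    """Copy the tree with one marker's branch lengths set to zero.

    ``part`` is ``"foundation"`` or ``"extension"``; junction edges count
    as foundation.  Other edges are untouched.  Used to ablate the
    phylogenetic signal contributed by one of the two markers.
    """
    if part not in (FOUNDATION, EXTENSION):
        raise ValueError(f"part must be {FOUNDATION!r} or {EXTENSION!r}")
    tree = result.tree if isinstance(result, GraftResult) else result
    out = tree.copy()
    for node in out.traverse(include_self=False):
        tag = getattr(node, "part", FOUNDATION)
        if tag == JUNCTION:
            tag = FOUNDATION
        if tag == part:
            node.length = 0.0
    return out


def filter_table_to_tree(
    table: FeatureTable, tree: TreeNode
) -> tuple[FeatureTable, list[str], list[str]]:
    """Keep only table OTUs that are tree tips.

    Returns the filtered table, the removed OTU ids, and the samples whose
    counts became all-zero (kept in the table, but flagged so downstream
    weighted metrics can exclude them).
    """
    tipset = {t.name for t in tree.tips()}
    kept = [o for o in table.otu_ids if o in tipset]
    removed = [o for o in table.otu_ids if o not in tipset]
    if not kept:
        raise ValueError("no table OTUs are present in the tree")
    filtered = table.filter_otus(kept)
    zero_samples = [s for s, tot in filtered.data.sum(axis=1).items() if tot == 0]
    return filtered, removed, zero_samples
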