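"""Shared test utilities: topology comparison and brute-force oracles."""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from treegraft.io_formats import FeatureTable


def unrooted_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the tip set, ignoring the root position."""
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            splits.add(frozenset({side, tips - side}))
    return splits


def brute_force_unifrac(
    table: FeatureTable,
    tree: TreeNode,
    sample_a: str,
    sample_b: str,
    weighted: bool,
    normalized: bool = False,
) -> float:
    """Edge-by-edge UniFrac enumeration in plain Python (test oracle).

    Walks every non-root edge, collects its descendant tip set recursively
    and applies the metric definition directly, independent of the
    incidence-matrix implementation under test.
    """
    counts_a = dict(zip(table.otu_ids, table.data.loc[sample_a]))
    counts_b = dict(zip(table.otu_ids, table.data.loc[sample_b]))
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())

    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        ca = sum(counts_a.get(t, 0) for t in below)
        cb = sum(counts_b.get(t, 0) for t in below)
        if weighted:
            pa, pb = ca / total_a, cb / total_b
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        else:
            in_a, in_b = ca > 0, cb > 0
            if in_a != in_b:
                num += length
            if in_a or in_b:
                den += length
    if weighted:
        if not normalized:
            return num
        return num / den if den > 0 else 0.0
    return num / den if den > 0 else 0.0


def random_table(
    rng: np.random.Generator,
    sample_ids: list[str],
    otu_ids: list[str],
    density: float = 0.6,
    max_count: int = 50,
) -> FeatureTable:
    """Random sparse count table with no all-zero samples."""
    import pandas as pd

    n, m = len(sample_ids), len(otu_ids)
    counts = rng.integers(1, max_count + 1, size=(n, m))
    mask = rng.random((n, m)) < density
    counts = counts * mask
    for i in range(n):  # guarantee every sample observes something
        if counts[i].sum() == 0:
            counts[i, rng.integers(m)] = 1
    return FeatureTable(pd.DataFrame(counts.astype(np.int64), index=sample_ids, columns=otu_ids))
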