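"""Beta-diversity metrics, ordination and ANOSIM.

This is the evaluation layer: sample-by-sample distances (non-phylogenetic
Jaccard / Bray-Curtis, and phylogenetic unweighted / weighted UniFrac over
a supplied tree), principal coordinates analysis of a distance matrix, and
the rank-based ANOSIM permutation test for group separation.

UniFrac is computed from a tip-to-edge incidence accumulation: each edge's
descendant-tip counts per sample are obtained in one matrix product, after
which the unweighted and weighted forms are edge-weighted sums.  Weighted
UniFrac defaults to the raw (non-normalized) variant; ``normalized=True``
divides by the abundance-weighted total branch length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .io_formats import FeatureTable

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "jaccard_dm",
    "bray_curtis_dm",
    "unifrac_dm",
    "pcoa",
    "anosim",
]


def jaccard_dm(table: FeatureTable) -> DistanceMatrix:
    """Binary Jaccard distance: 1 - |intersection| / |union| of presence sets.

    Two samples with no observed OTUs at all are at distance 0 by
    convention.
    """
    pres = (table.counts > 0)
    inter = (pres[:, None, :] & pres[None, :, :]).sum(axis=2).astype(float)
    union = (pres[:, None, :] | pres[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, table.sample_ids)


def bray_curtis_dm(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x - y| / sum(x + y); both-zero pairs -> 0."""
    x = table.counts.astype(float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = num / den
    d[den == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, table.sample_ids)


def _edge_incidence(tree: TreeNode, tip_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Edge lengths and edge x tip incidence (1 iff tip descends from edge)."""
    tip_idx = {name: i for i, name in enumerate(tip_order)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder(include_self=False):
        mask = np.zeros(len(tip_order), dtype=bool)
        if node.is_tip():
            if node.name in tip_idx:  # tree tips absent from the table carry no counts
                mask[tip_idx[node.name]] = True
            node._tipmask = mask
        else:
            for child in node.children:
                mask |= child._tipmask
            node._tipmask = mask
        lengths.append(float(node.length) if node.length is not None else 0.0)
        rows.append(mask)
    # root aggregates children masks for completeness but carries no edge
    for node in tree.postorder(include_self=True):
        if hasattr(node, "_tipmask"):
            del node._tipmask
    return np.array(lengths), np.array(rows)


def unifrac_dm(
    table: FeatureTable,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = False,
) -> DistanceMatrix:
    """Unweighted or weighted UniFrac over all sample pairs.

    Every table OTU must be a tree tip (apply
    :func:`~treegraft.grafting.filter_table_to_tree` first).  Unweighted
    UniFrac is the fraction of union branch length unique to one of the two
    samples; with an all-zero-length tree every distance is 0.  Weighted
    UniFrac sums ``l_b * |p_A - p_B|`` over edges, with p the proportion of
    a sample's reads descending from the edge (raw variant); the normalized
    variant divides by ``sum l_b * (p_A + p_B)``.
    """
    tipset = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tipset]
    if missing:
        raise ValueError(f"table OTU {missing[0]!r} is not a tip of the tree")
    lengths, incidence = _edge_incidence(tree, table.otu_ids)
    counts = table.counts.astype(float)
    n = counts.shape[0]
    edge_counts = counts @ incidence.T  # samples x edges

    d = np.zeros((n, n))
    if weighted:
        totals = counts.sum(axis=1)
        for s, tot in zip(table.sample_ids, totals):
            if tot == 0:
                raise ValueError(f"sample {s!r} has zero total count (weighted UniFrac)")
        p = edge_counts / totals[:, None]
        for i in range(n):
            for j in range(i + 1, n):
                raw = float((lengths * np.abs(p[i] - p[j])).sum())
                if normalized:
                    den = float((lengths * (p[i] + p[j])).sum())
                    raw = raw / den if den > 0 else 0.0
                d[i, j] = d[j, i] = raw
    else:
        present = edge_counts > 0
        for i in range(n):
            for j in range(i + 1, n):
                union = present[i] | present[j]
                uniq = present[i] ^ present[j]
                den = float(lengths[union].sum())
                d[i, j] = d[j, i] = float(lengths[uniq].sum()) / den if den > 0 else 0.0
    return DistanceMatrix(d, table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA output: coordinates plus eigenvalue bookkeeping.

    ``percent_explained`` shares out the sum of positive eigenvalues (in
    percent, summing to 100 over the retained axes); negative eigenvalues
    are reported but excluded from that denominator (no Cailliez-style
    correction).
    """

    samples: pd.DataFrame  # samples x axes, columns "PC1", "PC2", ...
    eigenvalues: np.ndarray
    percent_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    ``B = -1/2 J D^2 J`` with ``J = I - 11'/n`` is eigendecomposed;
    coordinates are eigenvectors scaled by the square root of the positive
    eigenvalues, ordered by decreasing eigenvalue.  Axis signs are fixed so
    each axis's largest-magnitude loading is positive.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_vals = eigvals[pos]
    percent = 100.0 * pos_vals / pos_vals.sum() if pos_vals.size else np.array([])
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
    )
    return OrdinationResult(
        samples=frame,
        eigenvalues=pos_vals,
        percent_explained=percent,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM test statistic and permutation p-value."""

    r: float
    p_value: float
    permutations: int
    seed: int


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray, m: int) -> float:
    rb = ranks[~same_group].mean()
    rw = ranks[same_group].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities.

    All pairwise distances are ranked (average ranks on ties) and
    ``R = (mean between-group rank - mean within-group rank) / (M/2)`` with
    ``M = n(n-1)/2`` pairwise distances, so R lies in [-1, 1] and perfectly
    separated groups reach R = 1.  The p-value permutes group labels with the given
    seed and uses the ``(1 + hits) / (1 + permutations)`` estimator, so it
    is never exactly zero and is deterministic for a fixed seed.
    """
    ids = list(dm.ids)
    missing = [s for s in ids if s not in groups]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no group label")
    labels = np.array([groups[s] for s in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    condensed = squareform(dm.data, checks=False)
    ranks = rankdata(condensed)
    n = len(ids)
    m = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, same, m)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        same_p = perm[iu] == perm[ju]
        if _anosim_r(ranks, same_p, m) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return AnosimResult(r=r_obs, p_value=p, permutations=permutations, seed=seed)
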