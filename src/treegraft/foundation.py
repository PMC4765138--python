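"""Foundation-tree construction from a conserved-marker alignment.

The foundation marker (e.g., 18S rRNA) aligns across distant taxa, so a
single tree spanning all genera can be built from it: the alignment is
filtered by per-column gap fraction and entropy, one representative sequence
is kept per genus, pairwise Jukes-Cantor (JC69) distances are computed, and
a neighbor-joining tree is built and relabeled to genus names.

The reference tree engine is the package's own neighbor joining over JC69
distances, which keeps the whole pipeline deterministic and testable;
``external_tree_cmd`` plugs in any program that reads aligned FASTA on stdin
and writes Newick on stdout (FastTree-compatible).
"""

from __future__ import annotations

import math
import shlex
import subprocess
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .io_formats import (
    Alignment,
    GAP_CHARS,
    SequenceRecord,
    TaxonomyMap,
    UNIDENTIFIED,
    parse_newick,
    write_fasta,
)

__all__ = [
    "ColumnStats",
    "FilterParams",
    "FoundationBuildReport",
    "column_stats",
    "filter_alignment",
    "jc69_distance",
    "jc69_distance_matrix",
    "neighbor_joining",
    "build_foundation_tree",
]

_BASES = ("A", "C", "G", "T")

#: Distance assigned when observed divergence saturates the JC69 model.
DEFAULT_SATURATION_CEILING = 5.0


@dataclass(frozen=True)
class ColumnStats:
    index: int
    gap_fraction: float
    entropy_bits: float


@dataclass(frozen=True)
class FilterParams:
    """Column-filter thresholds.

    Exactly one entropy criterion is active: an absolute cutoff in bits
    (``max_entropy``) or a quantile (``entropy_quantile`` keeps columns at
    or below that quantile of the observed entropy distribution).
    """

    max_gap_fraction: float = 0.90
    max_entropy: float | None = None
    entropy_quantile: float | None = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must be in [0, 1]")
        if (self.max_entropy is None) == (self.entropy_quantile is None):
            raise ValueError("exactly one of max_entropy / entropy_quantile must be set")
        if self.entropy_quantile is not None and not 0.0 < self.entropy_quantile <= 1.0:
            raise ValueError("entropy_quantile must be in (0, 1]")
        if self.max_entropy is not None and self.max_entropy < 0:
            raise ValueError("max_entropy must be >= 0")


@dataclass
class FoundationBuildReport:
    """Audit trail of a foundation-tree build."""

    columns_in: int = 0
    columns_kept: int = 0
    representatives: dict[str, str] = field(default_factory=dict)
    dropped_unidentified: list[str] = field(default_factory=list)
    dropped_all_gap_rows: list[str] = field(default_factory=list)
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)


def column_stats(aln: Alignment) -> list[ColumnStats]:
    """Per-column gap fraction and base entropy.

    Gap fraction counts ``-`` and ``.`` over all rows.  Entropy (bits) is
    computed from the A/C/G/T frequencies among unambiguous, non-gap
    characters; ambiguity codes are excluded from the tally and a column
    with no countable base has entropy 0 by convention.
    """
    mat = aln.to_char_matrix()
    n_rows = mat.shape[0]
    stats = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        gaps = int(np.isin(col, list(GAP_CHARS)).sum())
        counts = np.array([(col == b).sum() for b in _BASES], dtype=float)
        total = counts.sum()
        if total > 0:
            p = counts[counts > 0] / total
            entropy = float(-(p * np.log2(p)).sum())
        else:
            entropy = 0.0
        stats.append(ColumnStats(j, gaps / n_rows, entropy))
    return stats


def filter_alignment(
    aln: Alignment, params: FilterParams
) -> tuple[Alignment, FoundationBuildReport]:
    """Drop highly gapped and high-entropy columns.

    Keeps exactly the columns with ``gap_fraction <= max_gap_fraction`` and
    entropy within the active criterion; row and column order is preserved.
    Rows left with only gaps are removed and reported.
    """
    stats = column_stats(aln)
    entropies = np.array([s.entropy_bits for s in stats])
    if params.max_entropy is not None:
        h_max = params.max_entropy
    else:
        h_max = float(np.quantile(entropies, params.entropy_quantile))
    keep = [
        s.index
        for s in stats
        if s.gap_fraction <= params.max_gap_fraction and s.entropy_bits <= h_max
    ]
    if not keep:
        raise ValueError(
            "no columns survive filtering; relax max_gap_fraction or the entropy criterion"
        )
    report = FoundationBuildReport(columns_in=aln.n_cols, columns_kept=len(keep))
    records = []
    for rec in aln.records:
        seq = "".join(rec.seq[j] for j in keep)
        if set(seq) <= GAP_CHARS:
            report.dropped_all_gap_rows.append(rec.id)
        else:
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError("all rows became gap-only after column filtering")
    return Alignment(tuple(records)), report


def _valid_mask(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.isin(arr, [b"A", b"C", b"G", b"T"])


def jc69_distance(
    a: str,
    b: str,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
) -> float:
    """Jukes-Cantor distance between two aligned sequences.

    Sites where either sequence has a gap or ambiguity code are excluded
    (pairwise deletion); ``d = -(3/4) ln(1 - (4/3) p)`` with p the mismatch
    fraction over the remaining sites.  At saturation (p >= 3/4) the model
    distance diverges and the configurable ceiling is returned instead.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    valid = _valid_mask(a) & _valid_mask(b)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid overlapping sites between sequences")
    p = float((aa[valid] != bb[valid]).sum()) / n
    if p >= 0.75:
        return saturation_ceiling
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc69_distance_matrix(
    aln: Alignment,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
    report: FoundationBuildReport | None = None,
) -> DistanceMatrix:
    ids = aln.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = jc69_distance(aln.records[i].seq, aln.records[j].seq, saturation_ceiling)
            if dij == saturation_ceiling and report is not None:
                report.saturated_pairs.append((ids[i], ids[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``
    is joined; ties go to the lexicographically smallest pair of cluster
    labels, where a cluster is labeled by the smallest tip id it contains.
    Negative branch-length estimates are clamped to 0.  The final edge is
    split at its midpoint to yield a rooted binary tree, so on an additive
    matrix the unrooted topology is recovered exactly.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("neighbor joining needs at least 2 ids")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    labels: list[str] = list(ids)  # smallest tip id per cluster, for tie-breaks
    d = dm.data.astype(float).copy()

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if i >= j:
                continue
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # Root at the midpoint of the last remaining edge.
    half = max(d[0, 1], 0.0) / 2.0
    root = TreeNode()
    a, b = nodes
    a.length = float(half)
    b.length = float(half)
    root.extend([a, b])
    return root


def _run_external_tree_cmd(cmd: str, aln: Alignment) -> TreeNode:
    fasta = write_fasta(aln.records)
    proc = subprocess.run(
        shlex.split(cmd), input=fasta, capture_output=True, text=True, check=True
    )
    return parse_newick(proc.stdout)


def build_foundation_tree(
    aln: Alignment,
    tax: TaxonomyMap,
    params: FilterParams | None = None,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
    external_tree_cmd: str | None = None,
) -> tuple[TreeNode, FoundationBuildReport]:
    """Build the genus-labeled foundation tree.

    Steps: drop sequences with unidentified genus; keep one representative
    per genus (longest ungapped sequence, ties to the smallest accession);
    filter columns; all-pairs JC69 distances; neighbor joining; relabel tips
    from accession to genus.
    """
    params = params or FilterParams()
    for rec in aln.records:
        if rec.id not in tax:
            raise KeyError(f"alignment id {rec.id!r} missing from taxonomy map")

    dropped = [r.id for r in aln.records if tax.genus_of(r.id) == UNIDENTIFIED]
    by_genus: dict[str, SequenceRecord] = {}
    for rec in aln.records:
        genus = tax.genus_of(rec.id)
        if genus == UNIDENTIFIED:
            continue
        cur = by_genus.get(genus)
        if (
            cur is None
            or len(rec.degapped()) > len(cur.degapped())
            or (len(rec.degapped()) == len(cur.degapped()) and rec.id < cur.id)
        ):
            by_genus[genus] = rec
    if len(by_genus) < 2:
        raise ValueError(f"only {len(by_genus)} genera survive; need at least 2")

    # Preserve the input row order among the chosen representatives.
    chosen_ids = {r.id for r in by_genus.values()}
    reps = Alignment(tuple(r for r in aln.records if r.id in chosen_ids))

    filtered, report = filter_alignment(reps, params)
    report.dropped_unidentified = dropped
    report.representatives = {tax.genus_of(r.id): r.id for r in filtered.records}

    if external_tree_cmd is not None:
        tree = _run_external_tree_cmd(external_tree_cmd, filtered)
    else:
        dm = jc69_distance_matrix(filtered, saturation_ceiling, report)
        tree = neighbor_joining(dm)
    acc_to_genus = {acc: genus for genus, acc in report.representatives.items()}
    for tip in tree.tips():
        tip.name = acc_to_genus.get(tip.name, tip.name)
    return tree, report
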