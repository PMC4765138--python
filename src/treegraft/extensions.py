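"""Extension-tree construction from a fast-evolving marker.

Extension sequences (e.g., fungal ITS) cannot be aligned reliably across
distant taxa, so they are first clustered into OTUs by percent identity,
each OTU is assigned a consensus genus from the taxonomy map, OTUs sharing
a genus are merged, and each genus group is aligned on its own and turned
into a small tree.  The genus name at the root of each extension tree is
the handle used later to graft it onto the foundation tree.

Greedy seed clustering and center-star alignment are the package's own
reference engines (both deterministic); ``external_otu_map`` and
``external_align_cmd`` accept the output of dedicated tools (SUMACLUST- or
MUSCLE-style) verbatim.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from skbio import TreeNode

from .foundation import jc69_distance_matrix, neighbor_joining
from .io_formats import (
    Alignment,
    SequenceRecord,
    TaxonomyMap,
    UNIDENTIFIED,
    parse_fasta,
    write_fasta,
)

__all__ = [
    "ClusterParams",
    "ConsensusParams",
    "GenusGroup",
    "pairwise_identity",
    "greedy_cluster",
    "consensus_genus",
    "merge_otus_by_consensus",
    "center_star_align",
    "build_extension_trees",
]


@dataclass(frozen=True)
class ClusterParams:
    """Percent-identity clustering parameters.

    Identity is computed from a global (Needleman-Wunsch) alignment with
    match +1, mismatch -1, gap open -2, gap extend -1.  By default the
    denominator is the full alignment length (gap columns included);
    ``gap_excluded_identity`` switches to matches / (matches + mismatches).
    """

    identity_threshold: float = 0.97
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    gap_excluded_identity: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ConsensusParams:
    """Majority-rule consensus at genus rank.

    ``min_fraction`` > 0.5 guarantees at most one genus can qualify.  The
    fraction is taken over ALL members of an OTU, so unidentified members
    count against the majority.
    """

    min_fraction: float = 0.51

    def __post_init__(self) -> None:
        if not 0.5 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in (0.5, 1]")


@dataclass
class GenusGroup:
    """All extension sequences resolved to one genus."""

    genus: str
    members: list[str]
    source_otus: list[str] = field(default_factory=list)


def _make_aligner(params: ClusterParams) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap_open,
        extend_gap_score=params.gap_extend,
    )


def _align_pair(a: str, b: str, params: ClusterParams) -> tuple[str, str]:
    """Globally align two ungapped sequences; returns the two gapped rows."""
    aln = _make_aligner(params).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: SequenceRecord, b: SequenceRecord, params: ClusterParams) -> float:
    """Fraction of identical positions in the optimal global alignment."""
    aln = _make_aligner(params).align(a.degapped(), b.degapped())[0]
    counts = aln.counts()
    if params.gap_excluded_identity:
        denom = counts.identities + counts.mismatches
    else:
        denom = aln.length
    return counts.identities / denom if denom else 0.0


def greedy_cluster(
    seqs: Sequence[SequenceRecord], params: ClusterParams | None = None
) -> dict[str, list[str]]:
    """Deterministic greedy seed clustering by percent identity.

    Sequences are visited in decreasing length (ties by ascending id); each
    sequence joins the first seed, in seed-creation order, with identity at
    or above the threshold, else founds a new cluster.  OTU ids are the seed
    accessions, so the result is invariant to input order.
    """
    params = params or ClusterParams()
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda r: (-len(r.degapped()), r.id))
    seeds: list[SequenceRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        for seed in seeds:
            if pairwise_identity(rec, seed, params) >= params.identity_threshold:
                clusters[seed.id].append(rec.id)
                break
        else:
            seeds.append(rec)
            clusters[rec.id] = [rec.id]
    return clusters


def consensus_genus(
    members: Sequence[str], tax: TaxonomyMap, params: ConsensusParams | None = None
) -> str | None:
    """Majority genus of an OTU, or None when no genus reaches the cutoff.

    Unidentified members are excluded from the candidate tally but kept in
    the denominator, so an OTU dominated by unannotated sequences resolves
    to None rather than to a minority label.
    """
    params = params or ConsensusParams()
    if not members:
        raise ValueError("empty member list")
    counts: dict[str, int] = {}
    for acc in members:
        genus = tax.genus_of(acc)  # raises KeyError if missing
        if genus != UNIDENTIFIED:
            counts[genus] = counts.get(genus, 0) + 1
    if not counts:
        return None
    best = min(sorted(counts), key=lambda g: -counts[g])
    if counts[best] / len(members) >= params.min_fraction:
        return best
    return None


def merge_otus_by_consensus(
    otus: Mapping[str, Sequence[str]],
    tax: TaxonomyMap,
    params: ConsensusParams | None = None,
) -> tuple[list[GenusGroup], dict[str, list[str]]]:
    """Assign each OTU a consensus genus and union same-genus OTUs.

    Returns the genus groups (sorted by genus, members de-duplicated) and a
    report of OTUs that failed to reach consensus, keyed by OTU id.
    """
    params = params or ConsensusParams()
    groups: dict[str, GenusGroup] = {}
    dropped: dict[str, list[str]] = {}
    for otu_id in otus:
        members = list(otus[otu_id])
        genus = consensus_genus(members, tax, params)
        if genus is None:
            dropped[otu_id] = members
            continue
        if genus not in groups:
            groups[genus] = GenusGroup(genus=genus, members=[], source_otus=[])
        grp = groups[genus]
        grp.source_otus.append(otu_id)
        for m in members:
            if m not in grp.members:
                grp.members.append(m)
    return [groups[g] for g in sorted(groups)], dropped


def _merge_into_master(
    master_center: str, rows: list[str], pair_center: str, pair_other: str
) -> tuple[str, list[str], str]:
    """Merge one center/other pairwise alignment into the running master.

    "Once a gap, always a gap": gaps present in either version of the
    center are propagated to all rows.
    """
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_other: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(pair_center):
        mc = master_center[i] if i < len(master_center) else None
        pc = pair_center[j] if j < len(pair_center) else None
        if mc is not None and mc == "-" and (pc is None or pc != "-"):
            out_master.append("-")
            for k, row in enumerate(rows):
                out_rows[k].append(row[i])
            out_other.append("-")
            i += 1
        elif pc is not None and pc == "-" and (mc is None or mc != "-"):
            out_master.append("-")
            for k in range(len(rows)):
                out_rows[k].append("-")
            out_other.append(pair_other[j])
            j += 1
        else:
            # Both gap, or both the same residue of the center.
            out_master.append(mc)
            for k, row in enumerate(rows):
                out_rows[k].append(row[i])
            out_other.append(pair_other[j])
            i += 1
            j += 1
    return "".join(out_master), ["".join(r) for r in out_rows], "".join(out_other)


def center_star_align(
    seqs: Sequence[SequenceRecord], params: ClusterParams | None = None
) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence maximizing summed pairwise identity to the
    others (ties to the smallest id); every other sequence is aligned to the
    center pairwise and the alignments are merged under "once a gap, always
    a gap".  Adequate for the closely related sequences found within one
    OTU / genus group.
    """
    params = params or ClusterParams()
    if len(seqs) < 2:
        raise ValueError("center-star alignment needs at least 2 sequences")
    ident = {}
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i < j:
                ident[(i, j)] = pairwise_identity(a, b, params)
    scores = [
        sum(ident[tuple(sorted((i, j)))] for j in range(len(seqs)) if j != i)
        for i in range(len(seqs))
    ]
    center_idx = min(range(len(seqs)), key=lambda i: (-scores[i], seqs[i].id))
    center = seqs[center_idx]
    others = [s for k, s in enumerate(seqs) if k != center_idx]

    master = center.degapped()
    rows: list[str] = []
    for other in others:
        pc, po = _align_pair(center.degapped(), other.degapped(), params)
        master, rows, aligned_other = _merge_into_master(master, rows, pc, po)
        rows.append(aligned_other)

    records = [SequenceRecord(center.id, master)] + [
        SequenceRecord(o.id, row) for o, row in zip(others, rows)
    ]
    order = {r.id: k for k, r in enumerate(seqs)}
    records.sort(key=lambda r: order[r.id])
    return Alignment(tuple(records))


def _run_external_align_cmd(cmd: str, seqs: Sequence[SequenceRecord]) -> Alignment:
    fasta = write_fasta(seqs)
    proc = subprocess.run(
        shlex.split(cmd), input=fasta, capture_output=True, text=True, check=True
    )
    return Alignment(tuple(parse_fasta(proc.stdout)))


def build_extension_trees(
    groups: Sequence[GenusGroup],
    seqs: Mapping[str, SequenceRecord],
    params: ClusterParams | None = None,
    external_align_cmd: str | None = None,
) -> dict[str, TreeNode]:
    """One tree per genus group, tips labeled by accession.

    Singleton groups become single-tip trees; larger groups are aligned
    (center-star, or the external aligner when given), JC69 distances are
    computed and a neighbor-joining tree is built.  The group's genus is
    stored on the root (``root.genus``), mirroring the grafting handle.
    """
    params = params or ClusterParams()
    trees: dict[str, TreeNode] = {}
    for group in groups:
        missing = [m for m in group.members if m not in seqs]
        if missing:
            raise KeyError(f"genus {group.genus!r}: no sequence for accession {missing[0]!r}")
        members = [seqs[m] for m in group.members]
        if len(members) == 1:
            tree = TreeNode(name=members[0].id)
        else:
            if external_align_cmd is not None:
                aln = _run_external_align_cmd(external_align_cmd, members)
            else:
                aln = center_star_align(members, params)
            tree = neighbor_joining(jc69_distance_matrix(aln))
        tree.genus = group.genus
        trees[group.genus] = tree
    return trees
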