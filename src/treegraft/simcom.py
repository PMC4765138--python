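"""Synthetic data: sequence evolution on known trees and community simulation.

Two generators live here.  ``make_fixture`` fabricates a complete input set
for the grafting pipeline — a foundation alignment evolved on a known genus
tree, per-genus extension sequences evolved on known species trees, and a
matching taxonomy map — together with the generating trees, so topology
recovery can be tested end to end without downloading any reference
database.  ``simsam`` fabricates community replicates: phylogenetically
perturbed copies of each source sample, built by moving counts to nearby
tips on a supplied tree, which creates a small, tree-shaped effect size
(replicates of one source resemble each other more than replicates of
different sources).

Sequence evolution follows the Jukes-Cantor model with no indels, so the
foundation "alignment" is gap-free by construction; rate variation across
sites and sequencing error are not modeled.  All randomness derives from a
single integer seed through numpy ``SeedSequence`` spawning, so any
sub-result is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (
    Alignment,
    FeatureTable,
    Lineage,
    SequenceRecord,
    TaxonomyMap,
    UNIDENTIFIED,
    serialize_newick,
    write_fasta,
    write_taxonomy_map,
)

__all__ = [
    "FixtureParams",
    "SimsamParams",
    "Fixture",
    "random_tree",
    "evolve_sequences",
    "make_fixture",
    "simsam",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureParams:
    """Shape and divergence of the synthetic input set.

    Divergences are mean root-to-tip path lengths in expected
    substitutions per site; the extension marker evolves faster than the
    foundation marker, as a fast spacer region does relative to a
    conserved rRNA gene.  ``unidentified_fraction`` marks that share of
    extension sequences as taxonomically unidentified at genus rank, to
    exercise the consensus and drop paths.
    """

    n_genera: int = 6
    species_per_genus: int = 4
    foundation_seq_len: int = 600
    extension_seq_len: int = 300
    foundation_divergence: float = 0.05
    extension_divergence: float = 0.15
    unidentified_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 2:
            raise ValueError("need at least 2 genera")
        if self.species_per_genus < 1:
            raise ValueError("need at least 1 species per genus")
        if not 0.0 <= self.unidentified_fraction < 1.0:
            raise ValueError("unidentified_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimsamParams:
    """Community-replicate simulation parameters.

    ``n_replicates`` phylogenetically similar samples are generated per
    source sample; ``dissimilarity`` is the patristic radius within which
    counts may be reassigned to a neighboring tip (0 reproduces the source
    exactly).
    """

    n_replicates: int = 10
    dissimilarity: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dissimilarity < 0:
            raise ValueError("dissimilarity must be >= 0")


@dataclass
class Fixture:
    """A synthetic pipeline input set plus its generating ground truth."""

    foundation_alignment: Alignment
    extension_seqs: list[SequenceRecord]
    taxonomy: TaxonomyMap
    genus_tree: TreeNode  # tips labeled by genus
    species_trees: dict[str, TreeNode]  # genus -> tree with accession tips

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the fixture as the pipeline's file inputs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "foundation_alignment": outdir / "foundation_alignment.fasta",
            "extension_seqs": outdir / "extension_seqs.fasta",
            "taxonomy": outdir / "taxonomy.tsv",
            "genus_tree": outdir / "truth_genus_tree.nwk",
        }
        paths["foundation_alignment"].write_text(
            write_fasta(self.foundation_alignment.records)
        )
        paths["extension_seqs"].write_text(write_fasta(self.extension_seqs))
        paths["taxonomy"].write_text(write_taxonomy_map(self.taxonomy))
        paths["genus_tree"].write_text(serialize_newick(self.genus_tree))
        for genus, tree in self.species_trees.items():
            p = outdir / f"truth_species_tree_{genus}.nwk"
            p.write_text(serialize_newick(tree))
            paths[f"species_tree_{genus}"] = p
        return paths


def random_tree(labels: list[str], rng: np.random.Generator, mean_depth: float) -> TreeNode:
    """Random rooted binary tree over ``labels``.

    Topology by successive random joins; edge lengths uniform on
    [0.5, 1.5) — bounded away from zero so every internal edge carries
    recoverable signal — then rescaled so the mean root-to-tip path length
    equals ``mean_depth``.
    """
    if not labels:
        raise ValueError("no labels")
    nodes = [TreeNode(name=l) for l in labels]
    if len(nodes) == 1:
        nodes[0].length = float(mean_depth)
        return nodes[0]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.5, 1.5))
        b.length = float(rng.uniform(0.5, 1.5))
        parent = TreeNode()
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    depths = [sum(n.length for n in tip.ancestors() if n.length) + (tip.length or 0.0)
              for tip in root.tips()]
    mean = float(np.mean(depths))
    if mean > 0:
        scale = mean_depth / mean
        for node in root.traverse(include_self=False):
            node.length = float(node.length * scale)
    return root


def evolve_sequences(tree: TreeNode, root_seq: str, seed: int) -> dict[str, str]:
    """Evolve a root sequence down a tree under the Jukes-Cantor model.

    Along an edge of length l (expected substitutions per site) each site
    independently differs from its parent with probability
    ``(3/4)(1 - exp(-4l/3))``, and a differing site takes one of the three
    alternative bases uniformly.  No indels.  Returns tip name -> sequence;
    deterministic for a fixed seed.
    """
    if not root_seq:
        raise ValueError("root sequence is empty")
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    root_arr = np.array([base_idx[c] for c in root_seq.upper()], dtype=np.int64)
    seqs: dict[int, np.ndarray] = {id(tree): root_arr}
    out: dict[str, str] = {}
    if tree.is_tip():
        out[tree.name] = "".join(_BASES[root_arr])
        return out
    for node in tree.preorder(include_self=False):
        parent_arr = seqs[id(node.parent)]
        ell = float(node.length) if node.length else 0.0
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * ell / 3.0))
        arr = parent_arr.copy()
        if p_diff > 0:
            mask = rng.random(arr.size) < p_diff
            n_sub = int(mask.sum())
            if n_sub:
                arr[mask] = (arr[mask] + rng.integers(1, 4, size=n_sub)) % 4
        seqs[id(node)] = arr
        if node.is_tip():
            out[node.name] = "".join(_BASES[arr])
    return out


def _lineage_for(genus: str, g_index: int, species: str | None) -> Lineage:
    return Lineage((
        "Fungi",
        f"Phylum{g_index % 3 + 1:02d}",
        f"Class{g_index % 4 + 1:02d}",
        f"Order{g_index % 5 + 1:02d}",
        f"Family{g_index + 1:02d}",
        genus,
        species if species is not None else UNIDENTIFIED,
    ))


def make_fixture(params: FixtureParams | None = None) -> Fixture:
    """Fabricate foundation, extension and taxonomy inputs with known truth.

    A random genus tree is drawn and a foundation sequence evolved on it per
    genus; an independent extension root sequence is drawn per genus and
    evolved on a per-genus random species tree, so congeneric extension
    sequences are similar while genera are unrelated.  The taxonomy map
    covers every accession with a full seven-rank lineage.
    """
    params = params or FixtureParams()
    ss = np.random.SeedSequence(params.seed)
    subseeds = ss.spawn(4 + 2 * params.n_genera)
    rng_topo = np.random.default_rng(subseeds[0])
    rng_roots = np.random.default_rng(subseeds[1])
    rng_unid = np.random.default_rng(subseeds[2])

    genera = [f"Genus{i + 1:02d}" for i in range(params.n_genera)]
    genus_tree = random_tree(genera, rng_topo, params.foundation_divergence)

    root_seq = "".join(rng_roots.choice(_BASES, size=params.foundation_seq_len))
    foundation_seqs = evolve_sequences(
        genus_tree, root_seq, int(subseeds[3].generate_state(1)[0] % (2**31))
    )

    taxonomy: dict[str, Lineage] = {}
    foundation_records = []
    for i, genus in enumerate(genera):
        acc = f"F{i + 1:04d}"
        foundation_records.append(SequenceRecord(acc, foundation_seqs[genus]))
        taxonomy[acc] = _lineage_for(genus, i, f"{genus} foundation")

    extension_records: list[SequenceRecord] = []
    species_trees: dict[str, TreeNode] = {}
    acc_counter = 0
    for i, genus in enumerate(genera):
        rng_g = np.random.default_rng(subseeds[4 + 2 * i])
        accs = [f"X{acc_counter + j + 1:04d}" for j in range(params.species_per_genus)]
        acc_counter += params.species_per_genus
        sp_tree = random_tree(accs, rng_g, params.extension_divergence)
        species_trees[genus] = sp_tree
        ext_root = "".join(rng_g.choice(_BASES, size=params.extension_seq_len))
        ext_seed = int(subseeds[4 + 2 * i + 1].generate_state(1)[0] % (2**31))
        tip_seqs = evolve_sequences(sp_tree, ext_root, ext_seed)
        for j, acc in enumerate(accs):
            extension_records.append(SequenceRecord(acc, tip_seqs[acc]))
            taxonomy[acc] = _lineage_for(genus, i, f"{genus} sp{j + 1}")

    n_unid = int(round(params.unidentified_fraction * len(extension_records)))
    if n_unid:
        chosen = rng_unid.choice(len(extension_records), size=n_unid, replace=False)
        for k in chosen:
            acc = extension_records[k].id
            taxa = list(taxonomy[acc].taxa)
            taxa[5] = UNIDENTIFIED
            taxa[6] = UNIDENTIFIED
            taxonomy[acc] = Lineage(tuple(taxa))

    return Fixture(
        foundation_alignment=Alignment(tuple(foundation_records)),
        extension_seqs=extension_records,
        taxonomy=TaxonomyMap(taxonomy),
        genus_tree=genus_tree,
        species_trees=species_trees,
    )


def simsam(
    table: FeatureTable,
    tree: TreeNode,
    params: SimsamParams | None = None,
    environments: Mapping[str, str] | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate phylogenetically similar replicates of each source sample.

    For each source sample and replicate, every nonzero count is moved, in
    full, to a tip drawn uniformly from the tips within patristic distance
    ``dissimilarity`` of its OTU (the OTU itself included); counts landing
    on the same tip are summed, so per-sample totals are conserved exactly.
    Replicate ids are ``<source>.<r>``.  The metadata records each
    replicate's source sample and environment label (the source id itself
    when no environment mapping is given).
    """
    params = params or SimsamParams()
    tipset = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tipset]
    if missing:
        raise ValueError(f"table OTU {missing[0]!r} is not a tip of the tree")

    tipdm = tree.tip_tip_distances()
    tip_ids = list(tipdm.ids)
    tip_pos = {t: i for i, t in enumerate(tip_ids)}
    neighbors: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        row = tipdm.data[tip_pos[otu]]
        neighbors[otu] = [tip_ids[k] for k in np.flatnonzero(row <= params.dissimilarity)]

    ss = np.random.SeedSequence(params.seed)
    subseeds = ss.spawn(len(table.sample_ids) * params.n_replicates)

    new_counts: dict[str, dict[str, int]] = {}
    meta_rows = []
    k = 0
    for source in table.sample_ids:
        src_row = table.data.loc[source]
        for r in range(1, params.n_replicates + 1):
            rng = np.random.default_rng(subseeds[k])
            k += 1
            sid = f"{source}.{r}"
            acc: dict[str, int] = {}
            for otu, count in src_row.items():
                if count == 0:
                    continue
                targets = neighbors[otu]
                target = targets[int(rng.integers(len(targets)))]
                acc[target] = acc.get(target, 0) + int(count)
            new_counts[sid] = acc
            env = environments[source] if environments is not None else source
            meta_rows.append({"#SampleID": sid, "Source": source, "Environment": env})

    all_otus = sorted({o for row in new_counts.values() for o in row})
    frame = pd.DataFrame(0, index=list(new_counts), columns=all_otus, dtype=np.int64)
    for sid, row in new_counts.items():
        for otu, count in row.items():
            frame.at[sid, otu] = count
    metadata = pd.DataFrame(meta_rows).set_index("#SampleID")
    return FeatureTable(frame), metadata
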