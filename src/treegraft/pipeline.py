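"""End-to-end orchestration of the grafting workflow.

``run_scaffold`` executes the whole chain — filter the foundation
alignment, build the foundation tree, cluster the extension sequences,
resolve consensus genera, build extension trees, graft — and writes every
artifact plus a run manifest to an output directory.  The run is fully
deterministic: the manifest records resolved parameters, input digests and
per-stage record counts, and two runs from the same inputs produce
byte-identical trees and manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .extensions import (
    ClusterParams,
    ConsensusParams,
    build_extension_trees,
    greedy_cluster,
    merge_otus_by_consensus,
)
from .foundation import FilterParams, build_foundation_tree
from .grafting import GraftOptions, GraftResult, graft
from .io_formats import (
    parse_alignment_fasta,
    parse_fasta,
    parse_taxonomy_map,
    read_otu_map,
    serialize_newick,
    write_otu_map,
)

__all__ = ["ScaffoldParams", "PipelineError", "run_scaffold"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass(frozen=True)
class ScaffoldParams:
    """Resolved parameters of a scaffold run."""

    filter: FilterParams = field(default_factory=FilterParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    graft: GraftOptions = field(default_factory=GraftOptions)
    taxonomy_dialect: str = "prefixed"
    external_tree_cmd: str | None = None
    external_align_cmd: str | None = None
    external_otu_map: str | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def run_scaffold(
    foundation_aln_path: str | Path,
    extension_fasta_path: str | Path,
    taxonomy_path: str | Path,
    params: ScaffoldParams | None = None,
    out_dir: str | Path = "treegraft_out",
) -> GraftResult:
    """Run the full workflow and write all artifacts to ``out_dir``.

    Returns the :class:`~treegraft.grafting.GraftResult`; the grafted tree
    is written as ``grafted_tree.nwk`` and the audit trail as TSV files
    alongside a ``manifest.json``.
    """
    params = params or ScaffoldParams()
    foundation_aln_path = Path(foundation_aln_path)
    extension_fasta_path = Path(extension_fasta_path)
    taxonomy_path = Path(taxonomy_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aln = _stage("read-foundation", lambda: parse_alignment_fasta(foundation_aln_path.read_text()))
    ext_seqs = _stage("read-extensions", lambda: parse_fasta(extension_fasta_path.read_text()))
    tax = _stage(
        "read-taxonomy",
        lambda: parse_taxonomy_map(taxonomy_path.read_text(), params.taxonomy_dialect),
    )

    for rec in ext_seqs:
        if rec.id not in tax:
            raise PipelineError(
                "read-taxonomy", KeyError(f"extension accession {rec.id!r} missing from taxonomy map")
            )

    foundation_tree, report = _stage(
        "build-foundation",
        build_foundation_tree,
        aln,
        tax,
        params.filter,
        external_tree_cmd=params.external_tree_cmd,
    )

    if params.external_otu_map is not None:
        otus = _stage("cluster", lambda: read_otu_map(Path(params.external_otu_map).read_text()))
    else:
        otus = _stage("cluster", greedy_cluster, ext_seqs, params.cluster)

    groups, dropped = _stage("consensus-merge", merge_otus_by_consensus, otus, tax, params.consensus)

    seq_lookup = {r.id: r for r in ext_seqs}
    ext_trees = _stage(
        "build-extensions",
        build_extension_trees,
        groups,
        seq_lookup,
        params.cluster,
        external_align_cmd=params.external_align_cmd,
    )

    result = _stage("graft", graft, foundation_tree, ext_trees, params.graft)

    (out / "foundation_tree.nwk").write_text(serialize_newick(foundation_tree))
    (out / "grafted_tree.nwk").write_text(serialize_newick(result.tree))
    (out / "otu_map.tsv").write_text(write_otu_map(otus))
    (out / "genus_groups.tsv").write_text(
        write_otu_map({g.genus: g.members for g in groups})
    )
    (out / "dropped_otus.tsv").write_text(
        write_otu_map(dropped) if dropped else ""
    )
    audit_lines = (
        [f"grafted\t{g}" for g in result.grafted_genera]
        + [f"ungrafted_foundation_tip\t{g}" for g in result.ungrafted_foundation_tips]
        + [f"unmatched_extension_genus\t{g}" for g in result.unmatched_extension_genera]
    )
    (out / "graft_audit.tsv").write_text("\n".join(audit_lines) + "\n")

    manifest = {
        "tool": "treegraft",
        "version": __version__,
        "parameters": {
            "filter": asdict(params.filter),
            "cluster": asdict(params.cluster),
            "consensus": asdict(params.consensus),
            "graft": asdict(params.graft),
            "taxonomy_dialect": params.taxonomy_dialect,
            "external_tree_cmd": params.external_tree_cmd,
            "external_align_cmd": params.external_align_cmd,
            "external_otu_map": params.external_otu_map,
        },
        "inputs": {
            "foundation_alignment": {
                "path": str(foundation_aln_path),
                "sha256": _sha256(foundation_aln_path),
            },
            "extension_seqs": {
                "path": str(extension_fasta_path),
                "sha256": _sha256(extension_fasta_path),
            },
            "taxonomy": {"path": str(taxonomy_path), "sha256": _sha256(taxonomy_path)},
        },
        "stages": {
            "foundation_sequences_in": len(aln.records),
            "foundation_columns_in": report.columns_in,
            "foundation_columns_kept": report.columns_kept,
            "foundation_dropped_unidentified": sorted(report.dropped_unidentified),
            "foundation_genera": len(report.representatives),
            "extension_sequences_in": len(ext_seqs),
            "otus_formed": len(otus),
            "otus_dropped_no_consensus": sorted(dropped),
            "genus_groups": len(groups),
            "genera_grafted": sorted(result.grafted_genera),
            "foundation_tips_ungrafted": sorted(result.ungrafted_foundation_tips),
            "extension_genera_unmatched": sorted(result.unmatched_extension_genera),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result
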