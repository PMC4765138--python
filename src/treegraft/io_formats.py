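"""Readers and writers for the file formats the pipeline touches.

Sequence collections travel as FASTA, trees as Newick, taxonomy maps and
feature tables as TSV.  All parsers normalize aggressively at the boundary
(uppercase, U->T, ``.`` gaps to ``-``) so downstream distance and identity
code can assume uppercase DNA, and every parser/serializer pair round-trips
exactly on the in-memory model.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "SequenceRecord",
    "Alignment",
    "Lineage",
    "TaxonomyMap",
    "FeatureTable",
    "UNIDENTIFIED",
    "RANKS",
    "GAP_CHARS",
    "FormatError",
    "parse_fasta",
    "write_fasta",
    "parse_taxonomy_map",
    "write_taxonomy_map",
    "parse_newick",
    "serialize_newick",
    "read_feature_table",
    "write_feature_table",
    "read_otu_map",
    "write_otu_map",
    "read_sample_metadata",
    "write_sample_metadata",
]

#: Sentinel taxon for a rank that is missing, "unidentified" or "unclassified".
UNIDENTIFIED = "unidentified"

#: The fixed seven-rank model, kingdom through species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Characters treated as alignment gaps.
GAP_CHARS = frozenset("-.")


class FormatError(ValueError):
    """Raised when an input file violates its dialect rules."""


_SEQ_TRANS = str.maketrans({"u": "T", "U": "T", ".": "-"})


def _normalize_seq(seq: str) -> str:
    return seq.upper().translate(_SEQ_TRANS)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (uppercase DNA; ``-`` marks gaps)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")

    def degapped(self) -> str:
        return self.seq.replace("-", "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_char_matrix(self) -> np.ndarray:
        """Rows x columns matrix of single characters."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")


@dataclass(frozen=True)
class Lineage:
    """A ranked lineage, kingdom through species.

    Unknown ranks hold the :data:`UNIDENTIFIED` sentinel.
    """

    taxa: tuple[str, ...] = field(default=(UNIDENTIFIED,) * 7)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(RANKS):
            raise FormatError(f"lineage must have {len(RANKS)} ranks, got {len(self.taxa)}")

    @property
    def genus(self) -> str:
        return self.taxa[RANKS.index("genus")]

    @property
    def species(self) -> str:
        return self.taxa[RANKS.index("species")]

    def __getitem__(self, rank: str) -> str:
        return self.taxa[RANKS.index(rank)]


class TaxonomyMap:
    """Mapping accession -> :class:`Lineage`; the join key for grafting."""

    def __init__(self, entries: Mapping[str, Lineage]):
        self.entries = dict(entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, accession: str) -> Lineage:
        try:
            return self.entries[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} missing from taxonomy map") from None

    def genus_of(self, accession: str) -> str:
        return self[accession].genus


@dataclass
class FeatureTable:
    """Sample x OTU counts backed by a pandas DataFrame (rows = samples)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids in feature table")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate OTU ids in feature table")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("feature table counts must be integers")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at OTU {self.data.columns[c]!r}, sample {self.data.index[r]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def filter_otus(self, keep: Iterable[str]) -> "FeatureTable":
        keep = [o for o in self.otu_ids if o in set(keep)]
        return FeatureTable(self.data[keep])


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text into normalized records.

    The id is the first whitespace-delimited header token.  Sequences are
    uppercased with U->T and ``.``->``-``.  Duplicate ids, empty sequences
    and empty input are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_seq(str(rec.seq))
        if not seq:
            raise FormatError(f"sequence {rec.id!r} is empty")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 80) -> str:
    out = []
    for r in records:
        out.append(f">{r.id}")
        for i in range(0, len(r.seq), width):
            out.append(r.seq[i : i + width])
    return "\n".join(out) + "\n"


def parse_alignment_fasta(text: str) -> Alignment:
    return Alignment(tuple(parse_fasta(text)))


# ---------------------------------------------------------------------------
# Taxonomy maps


def _parse_prefixed_lineage(lineage: str, lineno: int) -> Lineage:
    taxa = [UNIDENTIFIED] * len(RANKS)
    for part in lineage.split(";"):
        part = part.strip()
        if not part:
            continue
        prefix = part[:3]
        if prefix not in _RANK_PREFIXES:
            raise FormatError(f"line {lineno}: unknown rank prefix in field {part!r}")
        name = part[3:].strip()
        if name and name.lower() not in ("unidentified", "unclassified"):
            taxa[_RANK_PREFIXES.index(prefix)] = name
    return Lineage(tuple(taxa))


def _parse_plain_lineage(lineage: str) -> Lineage:
    # Positional: fields map to kingdom..species in order; extra depth ignored.
    taxa = [UNIDENTIFIED] * len(RANKS)
    fields = [f.strip() for f in lineage.split(";")]
    for i, name in enumerate(fields[: len(RANKS)]):
        if name and name.lower() not in ("unidentified", "unclassified"):
            taxa[i] = name
    return Lineage(tuple(taxa))


def parse_taxonomy_map(text: str, dialect: str = "prefixed") -> TaxonomyMap:
    """Parse a two-column ``accession<TAB>lineage`` file.

    ``dialect="prefixed"`` expects ``k__X;p__X;...;s__X`` fields (UNITE
    style); ``dialect="plain"`` expects bare semicolon-separated names in
    kingdom..species order (Silva style).  Empty fields and the literal
    tokens "unidentified"/"unclassified" collapse to one sentinel.
    """
    if dialect not in ("prefixed", "plain"):
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    entries: dict[str, Lineage] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise FormatError(f"line {lineno}: expected tab-separated accession and lineage")
        accession, lineage = line.split("\t", 1)
        accession = accession.strip()
        if accession in entries:
            raise FormatError(f"line {lineno}: accession {accession!r} repeated")
        if dialect == "prefixed":
            entries[accession] = _parse_prefixed_lineage(lineage.strip(), lineno)
        else:
            entries[accession] = _parse_plain_lineage(lineage.strip())
    if not entries:
        raise FormatError("taxonomy map is empty")
    return TaxonomyMap(entries)


def write_taxonomy_map(tax: TaxonomyMap) -> str:
    lines = []
    for accession, lin in tax.entries.items():
        fields = [
            f"{p}{'' if t == UNIDENTIFIED else t}"
            for p, t in zip(_RANK_PREFIXES, lin.taxa)
        ]
        lines.append(f"{accession}\t{';'.join(fields)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick

_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,']")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a scikit-bio TreeNode.

    Underscores in labels are preserved verbatim (no conversion to spaces).
    Unbalanced parentheses are reported with a character offset.
    """
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise FormatError(f"unbalanced '(' ({depth} unclosed) in Newick input")
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio NewickFormatError
        raise FormatError(f"Newick parse error: {exc}") from exc
    return tree


def _format_label(label: str | None) -> str:
    if label is None:
        return ""
    if _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _serialize_node(node: TreeNode) -> str:
    if node.children:
        inner = ",".join(_serialize_node(c) for c in node.children)
        s = f"({inner}){_format_label(node.name)}"
    else:
        s = _format_label(node.name)
    if node.length is not None:
        s += f":{node.length!r}"
    return s


def serialize_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick, byte-reproducibly.

    Branch lengths use Python's shortest round-trip float representation, so
    serialize -> parse -> serialize is bit-stable.
    """
    return _serialize_node(tree) + ";\n"


# ---------------------------------------------------------------------------
# Feature tables, OTU maps, sample metadata


def read_feature_table(text: str) -> FeatureTable:
    """Read an OTU x sample TSV (first column OTU id, header row sample ids)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str, comment=None)
    if df.empty:
        raise FormatError("feature table has no rows")
    counts = np.empty(df.shape, dtype=np.int64)
    for i, otu in enumerate(df.index):
        for j, sample in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                val = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at OTU {otu!r}, sample {sample!r}"
                ) from None
            if val < 0:
                raise FormatError(f"negative count at OTU {otu!r}, sample {sample!r}")
            counts[i, j] = val
    frame = pd.DataFrame(counts.T, index=list(df.columns), columns=list(df.index))
    return FeatureTable(frame)


def write_feature_table(table: FeatureTable) -> str:
    df = table.data.T  # back to OTU x sample for the file layout
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index_label="#OTU ID")
    return buf.getvalue()


def read_otu_map(text: str) -> dict[str, list[str]]:
    """Read a QIIME-1 style OTU map: ``otu-id<TAB>member1<TAB>member2...``."""
    clusters: dict[str, list[str]] = {}
    seen_members: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        otu_id, members = fields[0], fields[1:]
        if otu_id in clusters:
            raise FormatError(f"line {lineno}: OTU id {otu_id!r} repeated")
        if not members:
            raise FormatError(f"line {lineno}: OTU {otu_id!r} has no members")
        for m in members:
            if m in seen_members:
                raise FormatError(f"line {lineno}: accession {m!r} in more than one OTU")
            seen_members.add(m)
        clusters[otu_id] = members
    if not clusters:
        raise FormatError("OTU map is empty")
    return clusters


def write_otu_map(clusters: Mapping[str, Sequence[str]]) -> str:
    return "\n".join(f"{otu}\t" + "\t".join(members) for otu, members in clusters.items()) + "\n"


def read_distance_matrix(text: str):
    """Read a labeled square distance matrix TSV."""
    from skbio import DistanceMatrix

    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row and column labels differ")
    return DistanceMatrix(df.to_numpy(dtype=float), list(df.index))


def write_distance_matrix(dm) -> str:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    buf = io.StringIO()
    df.to_csv(buf, sep="\t")
    return buf.getvalue()


def read_sample_metadata(text: str) -> pd.DataFrame:
    """Read a sample metadata TSV whose first column header is ``#SampleID``."""
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    if df.columns[0] != "#SampleID":
        raise FormatError("sample metadata must start with a '#SampleID' column")
    df = df.set_index("#SampleID")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in metadata")
    return df


def write_sample_metadata(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index_label="#SampleID")
    return buf.getvalue()
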