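"""Shared domain types and readers/writers for the standard formats.

Sequence data is kept as plain Python strings with original case preserved
(lowercase marks soft-masked residues).  Trees are represented with
:mod:`dendropy` and interpreted as unrooted throughout.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReadPair",
    "LocusAlignment",
    "TaxonGroups",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_phylip_relaxed",
    "write_phylip_relaxed",
    "read_newick",
    "write_newick",
    "revcomp",
]

#: characters considered unambiguous nucleotides by downstream statistics
UNAMBIGUOUS_NT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; non-IUPAC characters pass through."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence with case preserved."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence for record {self.id!r} must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """A mate pair of sequencing reads."""

    id: str
    mate1: str
    mate2: str

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise ValueError(f"read pair {self.id!r} has an empty mate")


class LocusAlignment:
    """Per-locus multiple alignment: a map taxon -> aligned row.

    Rows must all have the same length and taxon names must be unique.
    '.' and '?' are treated as undetermined (N) by analyses; '-' is a gap.
    """

    def __init__(self, locus_id: str, rows: Mapping[str, str]):
        rows = dict(rows)
        if not rows:
            raise ValueError(f"alignment {locus_id!r} has no rows")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {locus_id!r} rows have unequal lengths {sorted(lengths)}"
            )
        self.locus_id = locus_id
        self.rows = rows
        self._encoded: dict[str, np.ndarray] | None = None

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values())))

    def encoded(self) -> dict[str, np.ndarray]:
        """Uppercased rows as uint8 arrays, cached; used by distance code."""
        if self._encoded is None:
            self._encoded = {
                t: np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
                for t, s in self.rows.items()
            }
        return self._encoded

    def __repr__(self) -> str:
        return (
            f"LocusAlignment({self.locus_id!r}, {self.n_taxa} taxa x "
            f"{self.n_sites} sites)"
        )


@dataclass
class TaxonGroups:
    """Assignment of each taxon to a presumed closely-related group."""

    assignment: dict[str, str] = field(default_factory=dict)

    @property
    def groups(self) -> set[str]:
        return set(self.assignment.values())

    def group_of(self, taxon: str) -> str:
        return self.assignment[taxon]

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TaxonGroups":
        """Read a two-column TSV (taxon, group); a header line is skipped
        when its first field is literally 'taxon'."""
        assignment: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed groups line: {line!r}")
                taxon, group = fields[0], fields[1]
                if taxon == "taxon":
                    continue
                if taxon in assignment:
                    raise ValueError(f"taxon {taxon!r} listed twice in groups table")
                assignment[taxon] = group
        return cls(assignment)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tgroup\n")
            for taxon, group in self.assignment.items():
                fh.write(f"{taxon}\t{group}\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read FASTA preserving record order and case.

    Raises ``ValueError`` for duplicate ids or an empty file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def alignment_from_fasta(path: str | os.PathLike,
                         locus_id: str | None = None) -> LocusAlignment:
    """Read a per-locus alignment from FASTA; locus id defaults to the
    file stem."""
    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    records = read_fasta(path)
    return LocusAlignment(locus_id, {r.id: r.seq for r in records})


def alignment_to_fasta(aln: LocusAlignment, path: str | os.PathLike) -> None:
    write_fasta(
        (SequenceRecord(t, s) for t, s in aln.rows.items()), path
    )


def read_fastq_pairs(r1_path: str | os.PathLike,
                     r2_path: str | os.PathLike) -> list[ReadPair]:
    """Read paired FASTQ files in lock-step; qualities are parsed but
    discarded (quality trimming is out of scope)."""
    pairs = []
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        pair_id = rec1.id.removesuffix("/1")
        pairs.append(ReadPair(pair_id, str(rec1.seq), str(rec2.seq)))
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str | os.PathLike,
                      r2_path: str | os.PathLike) -> None:
    """Write mate pairs as two FASTQ files with constant dummy qualities."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.id}/1\n{pair.mate1}\n+\n{'I' * len(pair.mate1)}\n")
            f2.write(f"@{pair.id}/2\n{pair.mate2}\n+\n{'I' * len(pair.mate2)}\n")


# ---------------------------------------------------------------------------
# relaxed PHYLIP


def write_phylip_relaxed(alignment, path: str | os.PathLike) -> None:
    """Write a relaxed-PHYLIP alignment (``LocusAlignment`` or any object
    with a ``rows``-like taxon->string mapping)."""
    rows = alignment.rows if hasattr(alignment, "rows") else alignment.matrix
    n_taxa = len(rows)
    n_sites = len(next(iter(rows.values())))
    for name in rows:
        if any(ch.isspace() for ch in name):
            raise ValueError(f"taxon name {name!r} contains whitespace")
    name_w = max(len(n) for n in rows) + 2
    with open(path, "w") as fh:
        fh.write(f"{n_taxa} {n_sites}\n")
        for name, seq in rows.items():
            fh.write(f"{name.ljust(name_w)}{seq}\n")


def read_phylip_relaxed(path: str | os.PathLike,
                        locus_id: str | None = None) -> LocusAlignment:
    if locus_id is None:
        locus_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"bad PHYLIP header in {path}")
        n_taxa, n_sites = int(header[0]), int(header[1])
        rows: dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            rows[name] = seq.strip()
    if len(rows) != n_taxa or any(len(s) != n_sites for s in rows.values()):
        raise ValueError(f"PHYLIP body of {path} disagrees with header")
    return LocusAlignment(locus_id, rows)


# ---------------------------------------------------------------------------
# Newick


def read_newick(source: str | os.PathLike) -> list[dendropy.Tree]:
    """Read one Newick tree per line; trees are interpreted as unrooted."""
    trees = []
    with open(source) as fh:
        text = fh.read()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        tree = parse_newick(line)
        trees.append(tree)
    if not trees:
        raise ValueError(f"no trees in {source}")
    return trees


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a single Newick string into an unrooted dendropy tree."""
    if newick.count("(") != newick.count(")"):
        raise ValueError(
            f"unbalanced parentheses in newick (open={newick.count('(')}, "
            f"close={newick.count(')')})"
        )
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in newick tree")
    return tree


def write_newick(trees, path: str | os.PathLike) -> None:
    """Write one or more trees, one Newick string per line."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(
                tree.as_string(
                    schema="newick", suppress_rooting=True,
                    unquoted_underscores=True,
                ).strip()
                + "\n"
            )


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}
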