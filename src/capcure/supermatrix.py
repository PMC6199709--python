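"""Supermatrix concatenation, alignment statistics and partition files."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio_core import LocusAlignment

__all__ = ["Supermatrix", "MatrixStats", "concatenate", "matrix_stats",
           "write_partition_file"]


@dataclass
class Supermatrix:
    """Concatenated alignment with 1-based inclusive partition ranges."""

    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def rows(self) -> dict[str, str]:  # alias so PHYLIP writer accepts it
        return self.matrix

    @property
    def n_sites(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def slice_partition(self, locus_id: str) -> LocusAlignment:
        """Recover one locus block (taxa restricted to non-all-gap rows)."""
        for name, start, end in self.partitions:
            if name == locus_id:
                rows = {
                    t: self.matrix[t][start - 1:end] for t in self.taxa
                }
                rows = {t: s for t, s in rows.items() if set(s) != {"-"}}
                return LocusAlignment(locus_id, rows)
        raise KeyError(f"no partition {locus_id!r}")


@dataclass(frozen=True)
class MatrixStats:
    n_taxa: int
    n_sites: int
    n_distinct_patterns: int
    prop_gap_undetermined: float


def concatenate(loci: Iterable[LocusAlignment]) -> Supermatrix:
    """Concatenate loci in input order; taxa missing from a locus are
    filled with gaps for that block."""
    loci = list(loci)
    if not loci:
        raise ValueError("no loci to concatenate")
    ids = [aln.locus_id for aln in loci]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate locus id(s): {', '.join(dup)}")
    taxa = sorted(set().union(*(aln.rows.keys() for aln in loci)))
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for aln in loci:
        length = aln.n_sites
        for taxon in taxa:
            parts[taxon].append(aln.rows.get(taxon, "-" * length))
        partitions.append((aln.locus_id, pos + 1, pos + length))
        pos += length
    matrix = {t: "".join(chunks) for t, chunks in parts.items()}
    return Supermatrix(taxa, matrix, partitions)


def matrix_stats(sm: Supermatrix) -> MatrixStats:
    """Distinct-column count and gap/undetermined proportion.

    Characters are uppercased and {N, ?, .} unified to N before counting;
    a pattern is the full column over the fixed taxon order.
    """
    unify = str.maketrans("?.", "NN")
    rows = [sm.matrix[t].upper().translate(unify) for t in sm.taxa]
    n_taxa = len(rows)
    n_sites = sm.n_sites
    patterns = set(zip(*rows))
    n_missing = sum(row.count("-") + row.count("N") for row in rows)
    prop = n_missing / (n_taxa * n_sites) if n_taxa and n_sites else 0.0
    return MatrixStats(n_taxa, n_sites, len(patterns), prop)


def write_partition_file(sm: Supermatrix, datatype: str, path) -> None:
    """One line per partition: ``DNA, locus = start-end`` (1-based
    inclusive), RAxML style."""
    if datatype not in ("DNA", "AA"):
        raise ValueError("datatype must be 'DNA' or 'AA'")
    with open(path, "w") as fh:
        for name, start, end in sm.partitions:
            fh.write(f"{datatype}, {name} = {start}-{end}\n")
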