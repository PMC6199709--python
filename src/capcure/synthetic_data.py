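"""Seeded generator of capture-like datasets with planted artifacts.

Loci are evolved along a pure-birth species tree under a uniform
(JC-like) substitution process; from the per-locus sequences the
generator derives exon references, contigs with inserted introns,
paired reads with planted prefix-duplicates, paralogous contigs from a
deep duplication, and cross-contamination events — each recorded in a
truth table so every pipeline stage can be checked against it.
"""

from __future__ import annotations

import json
import math
import os
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .seqio_core import (
    LocusAlignment,
    ReadPair,
    SequenceRecord,
    TaxonGroups,
    revcomp,
    write_fasta,
    write_fastq_pairs,
    write_newick,
)

__all__ = [
    "ContaminationEvent",
    "SimConfig",
    "TruthTables",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_dataset",
    "random_orf",
    "random_orf_record",
    "evolve_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class ContaminationEvent:
    donor: str
    recipient: str
    fraction_of_loci: float
    residual_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("contamination donor must differ from recipient")
        if not 0.0 <= self.fraction_of_loci <= 1.0:
            raise ValueError("fraction_of_loci must be in [0, 1]")
        if not 0.0 <= self.residual_noise <= 0.001:
            raise ValueError("residual_noise must be in [0, 0.001]")


@dataclass
class SimConfig:
    n_taxa: int = 12
    n_loci: int = 20
    locus_length_range: tuple[int, int] = (300, 600)
    birth_tree_seed: int = 1
    subs_rate_range: tuple[float, float] = (0.05, 0.20)
    dup_read_fraction: float = 0.0
    n_paralog_loci: int = 0
    paralog_divergence: float = 0.30
    contamination_events: list[ContaminationEvent] = field(default_factory=list)
    intron_rate: float = 0.0
    intron_length_range: tuple[int, int] = (60, 200)
    missing_taxon_fraction: float = 0.0
    rng_seed: int = 0
    read_length: int = 100
    pairs_per_contig: int = 3


@dataclass
class TruthTables:
    species_tree: str = ""
    # contig id -> dict(locus, taxon, strand, introns=[(start, end), ...])
    contigs: dict[str, dict] = field(default_factory=dict)
    # kept read-pair id -> ids of its planted duplicates
    duplicate_classes: dict[str, list[str]] = field(default_factory=dict)
    # (locus, donor, recipient) triples actually planted
    contaminated: list[tuple[str, str, str]] = field(default_factory=list)
    paralog_contigs: list[str] = field(default_factory=list)
    # locus -> taxa present in the locus alignment
    presence: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: dendropy.Tree
    loci: list[LocusAlignment]
    exons: list[SequenceRecord]  # per-locus reference (ancestral) sequences
    contigs: list[SequenceRecord]
    read_pairs: dict[str, list[ReadPair]]  # per taxon
    groups: TaxonGroups
    truth: TruthTables

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        (out / "loci").mkdir(parents=True, exist_ok=True)
        (out / "reads").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        write_newick(self.tree, out / "species_tree.nwk")
        for aln in self.loci:
            write_fasta(
                (SequenceRecord(t, s) for t, s in aln.rows.items()),
                out / "loci" / f"{aln.locus_id}.fasta",
            )
        write_fasta(self.exons, out / "exons.fasta")
        write_fasta(self.contigs, out / "contigs.fasta")
        for taxon, pairs in self.read_pairs.items():
            if pairs:
                write_fastq_pairs(
                    pairs,
                    out / "reads" / f"{taxon}_R1.fastq",
                    out / "reads" / f"{taxon}_R2.fastq",
                )
        self.groups.to_tsv(out / "groups.tsv")
        truth = asdict(self.truth)
        truth["config"] = asdict(self.config)
        with open(out / "truth" / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# primitive generators


def random_orf(n_codons: int, rng: random.Random) -> str:
    """An open reading frame of stop-free codons, ending in a stop codon."""
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons))
    return body + rng.choice(sorted(_STOPS))


def random_orf_record(
    rec_id: str,
    n_codons: int,
    rng: random.Random,
    max_overhang: int = 30,
) -> tuple[SequenceRecord, str, int]:
    """An intact ORF embedded with random overhangs on a random strand.

    Returns ``(record, true_strand, true_offset)`` where the offset is the
    reading-frame offset on the called strand.
    """
    orf = random_orf(n_codons, rng)
    over5 = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, max_overhang)))
    over3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, max_overhang)))
    nt = over5 + orf + over3
    offset = len(over5) % 3
    strand = rng.choice("+-")
    if strand == "-":
        nt = revcomp(nt)
    return SequenceRecord(rec_id, nt), strand, offset


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.zeros(arr.size, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        codes[arr == base] = i
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _jc_prob(expected_subs: float) -> float:
    """Per-site substitution probability for an expected number of
    substitutions per site (Jukes-Cantor saturation)."""
    return 0.75 * (1.0 - math.exp(-4.0 / 3.0 * expected_subs))


def _mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def evolve_sequence(seq: str, expected_subs: float,
                    rng: np.random.Generator) -> str:
    """One JC-like substitution round at the given expected distance."""
    return _decode(_mutate(_encode(seq), _jc_prob(expected_subs), rng))


def simulate_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree over taxa t01..tNN, scaled to unit height."""
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:02d}"
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if height > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= height
    return tree


def _evolve_alignment(
    tree: dendropy.Tree,
    root_codes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Propagate the root sequence down the tree; per-branch substitution
    probability follows the branch length times the locus rate."""
    states: dict = {tree.seed_node: root_codes}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[node.parent_node]
        bl = node.edge.length or 0.0
        states[node] = _mutate(parent, _jc_prob(bl * rate), rng)
        if node.is_leaf():
            leaves[node.taxon.label] = states[node]
    return leaves


def _root_groups(tree: dendropy.Tree) -> TaxonGroups:
    """Two (or more) groups given by the root's child clades."""
    assignment: dict[str, str] = {}
    for i, child in enumerate(tree.seed_node.child_nodes()):
        for leaf in child.leaf_iter():
            assignment[leaf.taxon.label] = f"G{i + 1}"
    return TaxonGroups(assignment)


# ---------------------------------------------------------------------------
# the full dataset


def simulate_dataset(cfg: SimConfig,
                     out_dir: str | os.PathLike | None = None) -> SimulatedDataset:
    """Generate the whole dataset; identical seeds give identical output."""
    rng = np.random.default_rng(cfg.rng_seed)
    pyrng = random.Random(cfg.rng_seed)
    tree = simulate_species_tree(cfg.n_taxa, cfg.birth_tree_seed)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    groups = _root_groups(tree)
    truth = TruthTables(species_tree=tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip())

    loci: list[LocusAlignment] = []
    exons: list[SequenceRecord] = []
    roots: dict[str, str] = {}
    locus_ids = [f"L{i + 1:04d}" for i in range(cfg.n_loci)]
    for locus_id in locus_ids:
        n_codons = int(rng.integers(
            cfg.locus_length_range[0] // 3, cfg.locus_length_range[1] // 3 + 1
        ))
        root = random_orf(n_codons, pyrng)[:-3]  # body only, stop-free
        roots[locus_id] = root
        rate = float(rng.uniform(*cfg.subs_rate_range))
        leaves = _evolve_alignment(tree, _encode(root), rate, rng)
        rows = {t: _decode(leaves[t]) for t in taxa}
        if cfg.missing_taxon_fraction > 0:
            present = [
                t for t in taxa if rng.random() >= cfg.missing_taxon_fraction
            ]
            if len(present) >= 4:
                rows = {t: rows[t] for t in present}
        loci.append(LocusAlignment(locus_id, rows))
        exons.append(SequenceRecord(locus_id, root))

    # cross-contamination: overwrite the recipient with the donor (+noise)
    for event in cfg.contamination_events:
        n_events = round(event.fraction_of_loci * cfg.n_loci)
        eligible = [
            aln for aln in loci
            if event.donor in aln.rows and event.recipient in aln.rows
        ]
        order = rng.permutation(len(eligible))[:n_events]
        for idx in sorted(order):
            aln = eligible[idx]
            donor_seq = aln.rows[event.donor]
            if event.residual_noise > 0:
                donor_seq = _decode(
                    _mutate(_encode(donor_seq), event.residual_noise, rng)
                )
            aln.rows[event.recipient] = donor_seq
            aln._encoded = None
            truth.contaminated.append((aln.locus_id, event.donor, event.recipient))

    for aln in loci:
        truth.presence[aln.locus_id] = sorted(aln.rows)

    # contigs: per locus x present taxon, optional intron, random strand
    contigs: list[SequenceRecord] = []
    for aln in loci:
        for taxon in sorted(aln.rows):
            seq = aln.rows[taxon]
            introns: list[tuple[int, int]] = []
            if cfg.intron_rate > 0 and rng.random() < cfg.intron_rate:
                ilen = int(rng.integers(*cfg.intron_length_range))
                pos = int(rng.integers(30, max(31, len(seq) - 30)))
                intron = _decode(rng.integers(0, 4, size=ilen).astype(np.uint8))
                seq = seq[:pos] + intron + seq[pos:]
                introns.append((pos, pos + ilen))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            contig_id = f"{taxon}@{aln.locus_id}"
            contigs.append(SequenceRecord(contig_id, seq))
            truth.contigs[contig_id] = {
                "locus": aln.locus_id, "taxon": taxon,
                "strand": strand, "introns": introns,
            }

    # paralogs: duplicate loci diverged deeply; contigs from the duplicate
    # are claimed for the original locus and should fail the RBH screen
    dup_idx = rng.permutation(cfg.n_loci)[:cfg.n_paralog_loci]
    for idx in sorted(dup_idx):
        locus_id = locus_ids[idx]
        dup_id = f"{locus_id}dup"
        dup_root = evolve_sequence(roots[locus_id], cfg.paralog_divergence, rng)
        exons.append(SequenceRecord(dup_id, dup_root))
        taxon = taxa[int(rng.integers(0, len(taxa)))]
        contig_seq = evolve_sequence(dup_root, 0.05, rng)
        contig_id = f"{taxon}@{locus_id}#paralog"
        contigs.append(SequenceRecord(contig_id, contig_seq))
        truth.contigs[contig_id] = {
            "locus": locus_id, "taxon": taxon, "strand": "+", "introns": [],
            "paralog_of": dup_id,
        }
        truth.paralog_contigs.append(contig_id)

    # paired reads cut from contigs, with planted prefix-duplicates
    read_pairs: dict[str, list[ReadPair]] = {t: [] for t in taxa}
    all_pairs: list[tuple[str, ReadPair]] = []
    rl = cfg.read_length
    for contig in contigs:
        taxon = truth.contigs[contig.id]["taxon"]
        flen = min(len(contig.seq), 2 * rl + 50)
        n_starts = max(1, len(contig.seq) - flen + 1)
        n_pairs = min(cfg.pairs_per_contig, n_starts)
        # distinct starts so only PLANTED duplicates share both prefixes
        starts = rng.choice(n_starts, size=n_pairs, replace=False)
        for i, start in enumerate(sorted(int(s) for s in starts)):
            frag = contig.seq[start:start + flen]
            pair = ReadPair(f"{contig.id}:r{i}", frag[:rl], revcomp(frag)[:rl])
            all_pairs.append((taxon, pair))
    n_dups = round(cfg.dup_read_fraction * len(all_pairs))
    dup_sources = rng.permutation(len(all_pairs))[:n_dups]
    for j, src in enumerate(sorted(dup_sources)):
        taxon, pair = all_pairs[src]
        m1, m2 = pair.mate1, pair.mate2
        # change one base past the compared prefix so only prefixes match
        if len(m1) > 25:
            repl = "ACGT"[(("ACGT".index(m1[25].upper()) + 1) % 4)]
            m1 = m1[:25] + repl + m1[26:]
        dup = ReadPair(f"{pair.id}:dup{j}", m1, m2)
        all_pairs.append((taxon, dup))
        truth.duplicate_classes.setdefault(pair.id, []).append(dup.id)
    for taxon, pair in all_pairs:
        read_pairs[taxon].append(pair)

    dataset = SimulatedDataset(
        cfg, tree, loci, exons, contigs, read_pairs, groups, truth
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
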