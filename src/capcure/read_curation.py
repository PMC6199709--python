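"""Replicate read-pair removal and per-locus binning of reads/contigs.

Binning is done with a self-contained seeded ungapped matcher (exact k-mer
seeding, full-diagonal ungapped scoring with +1/-1, both strands) so the
pipeline needs no external aligner binary.  The same matcher backs the
reciprocal-best-hit screen and the intron splicer in :mod:`.orthology`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .seqio_core import ReadPair, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "DedupParams",
    "MatchParams",
    "GeneBin",
    "BaitIndex",
    "Hsp",
    "deduplicate_pairs",
    "assign_to_bins",
]


@dataclass(frozen=True)
class DedupParams:
    prefix_len: int = 20

    def __post_init__(self) -> None:
        if self.prefix_len < 1:
            raise ValueError("prefix_len must be >= 1")


@dataclass(frozen=True)
class MatchParams:
    """Parameters of the seeded ungapped matcher.

    ``min_score`` is on the +1 match / -1 mismatch scale, so an exact match
    of length L scores L.  Ties across loci resolve to the lexicographically
    smallest locus id.
    """

    seed_k: int = 11
    min_score: int = 50

    def __post_init__(self) -> None:
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")


@dataclass
class GeneBin:
    locus_id: str
    members: list[SequenceRecord] = field(default_factory=list)
    scores: dict[str, int] = field(default_factory=dict)


def deduplicate_pairs(
    pairs: list[ReadPair], params: DedupParams = DedupParams()
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Remove pairs whose mate1 AND mate2 prefixes both match an earlier
    kept pair (case-insensitive); the first occurrence is always kept.

    Pairs with either mate shorter than the prefix length are never removed.
    """
    n = params.prefix_len
    kept: list[ReadPair] = []
    removed: list[ReadPair] = []
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        if len(pair.mate1) < n or len(pair.mate2) < n:
            kept.append(pair)
            continue
        key = (pair.mate1[:n].upper(), pair.mate2[:n].upper())
        if key in seen:
            removed.append(pair)
        else:
            seen.add(key)
            kept.append(pair)
    return kept, removed


# ---------------------------------------------------------------------------
# seeded ungapped matching


@dataclass(frozen=True)
class Hsp:
    """An ungapped high-scoring segment: query/target half-open ranges on
    one diagonal, +1/-1 score."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return index


def _diagonal_hsp(query: str, target: str, diag: int) -> Hsp | None:
    """Best-scoring segment on one diagonal (maximum subarray of the
    +1/-1 per-position scores along the overlap)."""
    q0 = max(0, diag)
    q1 = min(len(query), len(target) + diag)
    if q1 <= q0:
        return None
    best = None
    run_score = 0
    run_start = q0
    for q in range(q0, q1):
        s = 1 if query[q] == target[q - diag] else -1
        if run_score <= 0:
            run_score = s
            run_start = q
        else:
            run_score += s
        if run_score > 0 and (best is None or run_score > best[0]):
            best = (run_score, run_start, q + 1)
    if best is None:
        return None
    score, qs, qe = best
    return Hsp(score, qs, qe, qs - diag, qe - diag)


def find_hsps(query: str, target: str, seed_k: int) -> list[Hsp]:
    """All per-diagonal best segments on diagonals holding >=1 exact
    k-mer seed.  Case-insensitive."""
    query = query.upper()
    target = target.upper()
    if len(query) < seed_k or len(target) < seed_k:
        return []
    t_index = _kmer_positions(target, seed_k)
    diagonals: set[int] = set()
    for i in range(len(query) - seed_k + 1):
        for j in t_index.get(query[i:i + seed_k], ()):
            diagonals.add(i - j)
    hsps = []
    for diag in diagonals:
        hsp = _diagonal_hsp(query, target, diag)
        if hsp is not None:
            hsps.append(hsp)
    return hsps


def best_ungapped_score(query: str, target: str, seed_k: int) -> int:
    """Best single-diagonal ungapped score between two sequences on the
    forward strand; 0 when no seed hit."""
    hsps = find_hsps(query, target, seed_k)
    return max((h.score for h in hsps), default=0)


def parse_locus_id(bait_id: str) -> str:
    """Locus id of a bait record: the part before the first '|'."""
    return bait_id.split("|", 1)[0]


class BaitIndex:
    """Bait sequences grouped by locus, queried for best-hit loci."""

    def __init__(self, baits: list[SequenceRecord],
                 params: MatchParams = MatchParams()):
        if not baits:
            raise ValueError("empty bait set")
        self.params = params
        self.by_locus: dict[str, list[SequenceRecord]] = defaultdict(list)
        for bait in baits:
            self.by_locus[parse_locus_id(bait.id)].append(bait)
        self.by_locus = dict(self.by_locus)

    @property
    def loci(self) -> list[str]:
        return sorted(self.by_locus)

    def locus_scores(self, seq: str) -> dict[str, int]:
        """Best ungapped score per locus over both strands of ``seq``."""
        k = self.params.seed_k
        strands = (seq, revcomp(seq))
        scores: dict[str, int] = {}
        for locus, baits in self.by_locus.items():
            best = 0
            for bait in baits:
                for strand_seq in strands:
                    best = max(best, best_ungapped_score(strand_seq, bait.seq, k))
            if best > 0:
                scores[locus] = best
        return scores

    def best_locus(self, seq: str) -> tuple[str, int] | None:
        """Single best-scoring locus at >= min_score, ties to the
        lexicographically smallest locus id (warning logged)."""
        scores = self.locus_scores(seq)
        if not scores:
            return None
        top = max(scores.values())
        if top < self.params.min_score:
            return None
        winners = sorted(locus for locus, s in scores.items() if s == top)
        if len(winners) > 1:
            logger.warning(
                "score tie across loci %s at %d; keeping %s",
                winners, top, winners[0],
            )
        return winners[0], top


def assign_to_bins(
    seqs: list[SequenceRecord],
    baits: list[SequenceRecord],
    params: MatchParams = MatchParams(),
) -> tuple[list[GeneBin], list[SequenceRecord]]:
    """Assign each sequence to the gene bin of its best-matching locus;
    sequences without a hit >= min_score are returned unassigned."""
    index = BaitIndex(baits, params)
    bins: dict[str, GeneBin] = {}
    unassigned: list[SequenceRecord] = []
    for seq in seqs:
        hit = index.best_locus(seq.seq)
        if hit is None:
            unassigned.append(seq)
            continue
        locus, score = hit
        bin_ = bins.setdefault(locus, GeneBin(locus))
        bin_.members.append(seq)
        bin_.scores[seq.id] = score
    ordered = [bins[locus] for locus in sorted(bins)]
    return ordered, unassigned
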