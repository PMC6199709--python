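"""Treelikeness scoring by quartet four-point evaluation and locus selection.

This is an explicit surrogate for black-box matrix-reduction software: a
locus scores the fraction of sampled taxon quartets whose pairwise
p-distances satisfy a resolved four-point condition, and loci are ranked by
treelikeness weighted by taxon coverage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations
from math import comb

from .contamination import p_distance
from .seqio_core import LocusAlignment

__all__ = [
    "TreelikenessParams",
    "LocusScore",
    "treelikeness",
    "filter_min_taxa",
    "select_informative",
]


@dataclass(frozen=True)
class TreelikenessParams:
    max_quartets: int = 2000
    resolution_margin: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_quartets < 1:
            raise ValueError("max_quartets must be >= 1")
        if self.resolution_margin < 0:
            raise ValueError("resolution_margin must be >= 0")


@dataclass(frozen=True)
class LocusScore:
    locus_id: str
    n_taxa: int
    treelikeness: float
    n_quartets_evaluated: int


def _quartet_resolved(d: dict[tuple[str, str], float],
                      quartet: tuple[str, ...], margin: float) -> bool | None:
    """Four-point check for one quartet; None when any distance is missing."""
    a, b, c, e = quartet

    def dist(x, y):
        return d.get((x, y)) if (x, y) in d else d.get((y, x))

    sums = []
    for pairing in (((a, b), (c, e)), ((a, c), (b, e)), ((a, e), (b, c))):
        total = 0.0
        for x, y in pairing:
            dd = dist(x, y)
            if dd is None:
                return None
            total += dd
        sums.append(total)
    sums.sort()
    return (sums[1] - sums[0]) > margin


def treelikeness(aln: LocusAlignment,
                 params: TreelikenessParams = TreelikenessParams()) -> LocusScore:
    """Fraction of resolved quartets among those evaluated.

    Quartets are enumerated exhaustively when C(n,4) <= max_quartets, else
    sampled uniformly without replacement with the seeded RNG.  Quartets
    touching an undefined pairwise distance are skipped.
    """
    taxa = sorted(aln.rows)
    distances: dict[tuple[str, str], float] = {}
    per_taxon_ok: dict[str, bool] = {t: False for t in taxa}
    for a, b in combinations(taxa, 2):
        dist, _ = p_distance(aln, a, b)
        if dist is not None:
            distances[(a, b)] = dist
            per_taxon_ok[a] = per_taxon_ok[b] = True
    evaluable_taxa = [t for t in taxa if per_taxon_ok[t]]
    if len(evaluable_taxa) < 4:
        raise ValueError(
            f"locus {aln.locus_id}: fewer than 4 taxa with evaluable distances"
        )
    n = len(taxa)
    total = comb(n, 4)
    if total <= params.max_quartets:
        quartets = combinations(taxa, 4)
    else:
        rng = random.Random(params.rng_seed)
        chosen: set[tuple[str, ...]] = set()
        while len(chosen) < params.max_quartets:
            chosen.add(tuple(sorted(rng.sample(taxa, 4))))
        quartets = sorted(chosen)
    n_eval = 0
    n_resolved = 0
    for quartet in quartets:
        resolved = _quartet_resolved(distances, quartet, params.resolution_margin)
        if resolved is None:
            continue
        n_eval += 1
        n_resolved += resolved
    score = n_resolved / n_eval if n_eval else 0.0
    return LocusScore(aln.locus_id, aln.n_taxa, score, n_eval)


def effective_taxa(aln: LocusAlignment) -> int:
    """Rows holding at least one character that is not gap/undetermined."""
    count = 0
    for seq in aln.rows.values():
        upper = seq.upper()
        if any(c not in "-N?." for c in upper):
            count += 1
    return count


def filter_min_taxa(
    loci: list[LocusAlignment], min_taxa: int = 4
) -> tuple[list[LocusAlignment], list[LocusAlignment]]:
    """Exclude loci with fewer than ``min_taxa`` non-empty rows."""
    kept, excluded = [], []
    for aln in loci:
        (kept if effective_taxa(aln) >= min_taxa else excluded).append(aln)
    return kept, excluded


def select_informative(
    scores: list[LocusScore],
    presence: dict[str, set[str]],
    n_target: int,
) -> list[str]:
    """Top ``n_target`` loci by treelikeness x taxon-coverage fraction.

    Ties break by taxon count descending, then locus id ascending, so the
    ranking is deterministic.
    """
    if n_target <= 0:
        raise ValueError("n_target must be > 0")
    if n_target > len(scores):
        raise ValueError("n_target exceeds the number of scored loci")
    total_taxa = len(set().union(*presence.values())) if presence else 0
    if total_taxa == 0:
        raise ValueError("empty taxon universe")

    def composite(s: LocusScore) -> float:
        return s.treelikeness * (len(presence.get(s.locus_id, ())) / total_taxa)

    ranked = sorted(
        scores, key=lambda s: (-composite(s), -s.n_taxa, s.locus_id)
    )
    return [s.locus_id for s in ranked[:n_target]]
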