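"""Cross-contamination screening by p-distance between distant taxa.

For every pair of taxa from different groups, each locus where both are
present with enough comparable sites contributes one p-distance; the locus
is flagged for that pair when the distance falls at or below the threshold.
A pair whose flagged-locus percentage reaches the alarm level is reported
as suspected contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .seqio_core import LocusAlignment, TaxonGroups

__all__ = [
    "ScreenParams",
    "ContaminationReport",
    "p_distance",
    "screen_cross_contamination",
]

# comparable characters: unambiguous nucleotides only
_COMPARABLE = np.zeros(256, dtype=bool)
for _c in b"ACGT":
    _COMPARABLE[_c] = True


@dataclass(frozen=True)
class ScreenParams:
    p_threshold: float = 0.002
    min_overlap: int = 1
    pct_alarm: float = 5.0
    within_groups: bool = False  # debug: also test intra-group pairs

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 < self.pct_alarm <= 100.0:
            raise ValueError("pct_alarm must be in (0, 100]")


@dataclass
class PairStats:
    n_evaluable: int = 0
    n_flagged: int = 0

    @property
    def percentage(self) -> float:
        if self.n_evaluable == 0:
            return 0.0
        return 100.0 * self.n_flagged / self.n_evaluable


@dataclass
class ContaminationReport:
    per_pair: dict[tuple[str, str], PairStats] = field(default_factory=dict)
    flagged_loci: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    params: ScreenParams = field(default_factory=ScreenParams)

    @property
    def max_percentage(self) -> float:
        return max((s.percentage for s in self.per_pair.values()), default=0.0)

    @property
    def suspected_pairs(self) -> list[tuple[str, str]]:
        return sorted(
            pair for pair, s in self.per_pair.items()
            if s.percentage >= self.params.pct_alarm
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxonA\ttaxonB\tn_evaluable\tn_flagged\tpercentage\tsuspected\n")
            for (a, b), s in sorted(self.per_pair.items()):
                fh.write(
                    f"{a}\t{b}\t{s.n_evaluable}\t{s.n_flagged}"
                    f"\t{s.percentage:.4f}"
                    f"\t{int(s.percentage >= self.params.pct_alarm)}\n"
                )


def p_distance(aln: LocusAlignment, a: str, b: str,
               min_overlap: int = 1) -> tuple[float | None, int]:
    """Uncorrected distance over sites where both rows hold an unambiguous
    nucleotide; ``(None, n_comparable)`` when the overlap is too small."""
    for taxon in (a, b):
        if taxon not in aln.rows:
            raise KeyError(f"taxon {taxon!r} absent from locus {aln.locus_id}")
    enc = aln.encoded()
    ra, rb = enc[a], enc[b]
    mask = _COMPARABLE[ra] & _COMPARABLE[rb]
    n_comparable = int(mask.sum())
    if n_comparable < min_overlap:
        return None, n_comparable
    mismatches = int(((ra != rb) & mask).sum())
    return mismatches / n_comparable, n_comparable


def screen_cross_contamination(
    loci: list[LocusAlignment],
    groups: TaxonGroups,
    params: ScreenParams = ScreenParams(),
) -> ContaminationReport:
    """Flag near-identical inter-group pairs locus by locus and aggregate
    to per-pair percentages."""
    if not loci:
        raise ValueError("no loci to screen")
    taxa = sorted(groups.assignment)
    if len({groups.assignment[t] for t in taxa}) < 2 and not params.within_groups:
        raise ValueError("no distant pairs: need >= 2 taxon groups")
    pairs = [
        (a, b) for a, b in combinations(taxa, 2)
        if params.within_groups or groups.assignment[a] != groups.assignment[b]
    ]
    report = ContaminationReport(params=params)
    for pair in pairs:
        report.per_pair[pair] = PairStats()
    for aln in loci:
        present = set(aln.rows)
        for pair in pairs:
            a, b = pair
            if a not in present or b not in present:
                continue
            dist, _ = p_distance(aln, a, b, params.min_overlap)
            if dist is None:
                continue
            stats = report.per_pair[pair]
            stats.n_evaluable += 1
            if dist <= params.p_threshold:
                stats.n_flagged += 1
                report.flagged_loci.append((aln.locus_id, pair, dist))
    return report
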