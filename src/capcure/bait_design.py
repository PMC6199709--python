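"""Tile candidate baits across exon sequences and drop soft-masked baits.

Baits of a fixed length are laid down with a fixed overlap; the exon is
right-padded with ``N`` so the tiling comes out exact.  Pad characters are
uppercase and therefore never count as soft-masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio_core import SequenceRecord

__all__ = ["BaitDesignParams", "Bait", "tile_baits", "filter_softmasked"]


@dataclass(frozen=True)
class BaitDesignParams:
    bait_length: int = 120
    overlap: int = 60
    max_n_fraction: float | None = None  # optional practicality filter, off by default

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.bait_length:
            raise ValueError("require 0 < overlap < bait_length")

    @property
    def step(self) -> int:
        return self.bait_length - self.overlap


@dataclass(frozen=True)
class Bait:
    source_locus: str
    start: int  # 0-based offset on the padded source
    seq: str


def expected_bait_count(length: int, params: BaitDesignParams) -> int:
    """Closed form: 1 + ceil(max(0, length - bait_length) / step)."""
    return 1 + math.ceil(max(0, length - params.bait_length) / params.step)


def tile_baits(exon: SequenceRecord,
               params: BaitDesignParams = BaitDesignParams()) -> list[Bait]:
    """Tile baits at offsets 0, step, 2*step, ... over the N-padded exon."""
    bl, step = params.bait_length, params.step
    length = len(exon.seq)
    padded_len = max(length, bl)
    overhang = (padded_len - bl) % step
    if overhang:
        padded_len += step - overhang
    padded = exon.seq + "N" * (padded_len - length)
    baits = [
        Bait(exon.id, start, padded[start:start + bl])
        for start in range(0, padded_len - bl + 1, step)
    ]
    if params.max_n_fraction is not None:
        limit = params.max_n_fraction * bl
        baits = [b for b in baits if b.seq.upper().count("N") <= limit]
    return baits


def filter_softmasked(baits: list[Bait]) -> tuple[list[Bait], list[Bait]]:
    """Partition baits into (kept, removed); a bait is removed iff its
    sequence contains any lowercase (soft-masked) character."""
    kept, removed = [], []
    for bait in baits:
        (removed if any(c.islower() for c in bait.seq) else kept).append(bait)
    return kept, removed
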