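"""Frame prediction, stop-codon trimming, intron splicing and the
reciprocal-best-hit paralog screen.

A contig keeps its bin only if, searched back against the full bait set,
its best hit is the locus it was binned to; otherwise it is flagged as a
potential paralog and excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .read_curation import BaitIndex, Hsp, MatchParams, find_hsps
from .seqio_core import SequenceRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "FrameCall",
    "OrthologyVerdict",
    "predict_frame",
    "splice_to_exon",
    "reciprocal_best_hit",
]

_FRAME_ORDER = [("+", 0), ("+", 1), ("+", 2), ("-", 0), ("-", 1), ("-", 2)]


@dataclass(frozen=True)
class FrameCall:
    strand: str  # '+' or '-'
    offset: int  # 0, 1 or 2 on the called strand
    aa_seq: str  # stop-free after trimming
    n_internal_stops_before_trim: int


@dataclass(frozen=True)
class OrthologyVerdict:
    contig_id: str
    assigned_locus: str
    reverse_best_locus: str
    status: str  # 'ortholog' or 'paralog_flagged'


def _translate_frame(nt: str, offset: int) -> str:
    sub = nt[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


def _longest_stop_free(aa: str) -> int:
    return max((len(run) for run in aa.split("*")), default=0)


def predict_frame(record: SequenceRecord) -> FrameCall:
    """Call the reading frame of a nucleotide record.

    All six strand/offset translations are scored; the call minimizes the
    internal-stop count, then prefers a frame ending in a terminal stop
    (a complete CDS), then the longest stop-free stretch, then the fixed
    order +0,+1,+2,-0,-1,-2.  The trailing partial codon and a terminal
    stop are dropped; if internal stops remain, the amino-acid sequence
    is truncated at the first one and a warning is logged.
    """
    nt = record.seq.upper()
    if len(nt) < 3:
        raise ValueError(f"{record.id}: sequence shorter than one codon")
    rc = revcomp(nt)
    candidates = []
    for rank, (strand, offset) in enumerate(_FRAME_ORDER):
        aa = _translate_frame(nt if strand == "+" else rc, offset)
        has_terminal_stop = aa.endswith("*")
        body = aa[:-1] if has_terminal_stop else aa
        n_internal = body.count("*")
        candidates.append((
            n_internal,
            0 if has_terminal_stop else 1,
            -_longest_stop_free(aa),
            rank,
            strand,
            offset,
            body,
        ))
    n_internal, _, _, _, strand, offset, body = min(candidates)
    aa_seq = body
    if n_internal:
        aa_seq = body.split("*", 1)[0]
        logger.warning(
            "%s: %d internal stop(s) in best frame %s%d; truncating",
            record.id, n_internal, strand, offset,
        )
    return FrameCall(strand, offset, aa_seq, n_internal)


# ---------------------------------------------------------------------------
# intron splicing


def _chain_hsps(hsps: list[Hsp]) -> tuple[int, list[Hsp]]:
    """Best collinear chain (strictly advancing on query and target);
    small boundary overlaps are tolerated and penalised one point per
    overlapping position, then trimmed at reconstruction."""
    if not hsps:
        return 0, []
    hsps = sorted(hsps, key=lambda h: (h.t_start, h.q_start))
    score = [h.score for h in hsps]
    prev = [-1] * len(hsps)
    for i, b in enumerate(hsps):
        for j in range(i):
            a = hsps[j]
            if not (b.t_end > a.t_end and b.q_end > a.q_end
                    and b.t_start >= a.t_start and b.q_start >= a.q_start):
                continue
            overlap = max(0, a.t_end - b.t_start, a.q_end - b.q_start)
            if overlap >= b.q_end - b.q_start:
                continue
            cand = score[j] + b.score - overlap
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
    best_i = max(range(len(hsps)), key=lambda i: score[i])
    chain = []
    i = best_i
    while i != -1:
        chain.append(hsps[i])
        i = prev[i]
    chain.reverse()
    return score[best_i], chain


def splice_to_exon(contig: SequenceRecord, bait: SequenceRecord,
                   params: MatchParams = MatchParams()) -> SequenceRecord:
    """Concatenate the contig segments that chain collinearly onto the
    bait exon, removing intron insertions.

    Raises ``ValueError("no exon structure found")`` when no collinear
    chain reaches ``min_score``.
    """
    best = None
    for strand_seq in (contig.seq, revcomp(contig.seq)):
        hsps = find_hsps(strand_seq, bait.seq, params.seed_k)
        chain_score, chain = _chain_hsps(hsps)
        if best is None or chain_score > best[0]:
            best = (chain_score, chain, strand_seq)
    chain_score, chain, strand_seq = best
    if chain_score < params.min_score or not chain:
        raise ValueError(f"{contig.id}: no exon structure found")
    parts = []
    prev_q_end = prev_t_end = -1
    for hsp in chain:
        trim = max(0, prev_t_end - hsp.t_start, prev_q_end - hsp.q_start)
        parts.append(strand_seq[hsp.q_start + trim: hsp.q_end])
        prev_q_end, prev_t_end = hsp.q_end, hsp.t_end
    return SequenceRecord(contig.id, "".join(parts))


def reciprocal_best_hit(contig: SequenceRecord, assigned_locus: str,
                        index: BaitIndex) -> OrthologyVerdict:
    """Search the contig back against the FULL bait set; the verdict is
    ortholog iff the top locus equals the assigned one."""
    hit = index.best_locus(contig.seq)
    reverse_best = hit[0] if hit is not None else ""
    status = "ortholog" if reverse_best == assigned_locus else "paralog_flagged"
    return OrthologyVerdict(contig.id, assigned_locus, reverse_best, status)
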