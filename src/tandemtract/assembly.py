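"""Greedy overlap-layout-consensus draft assembly and iterative pileup polishing.

Functional desk-scale stand-in for a long-read OLC assembler followed by
successive map-and-refine rounds: a draft contig is laid out from read
overlaps, then each refinement round re-selects reads by its thresholds,
aligns them to the current reference and takes a column-majority consensus,
iterating until the reference stops moving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import edit_distance, pileup_consensus
from .reads import select_assembly_reads

logger = logging.getLogger(__name__)

__all__ = ["AssemblyError", "RefinementConfig", "RoundReport",
           "assemble_draft", "polish", "polish_detailed"]


class AssemblyError(RuntimeError):
    """Raised when reads cannot be laid out into a single contig."""


@dataclass(frozen=True)
class RefinementConfig:
    """Refinement schedule: per-round (min_length, min_quality) strict thresholds."""

    rounds: tuple = ((4000, 0.85), (4500, 0.80))
    max_iterations: int = 3
    convergence: int = 0  # max consensus-to-consensus edit distance to stop

    def __post_init__(self):
        if not self.rounds:
            raise ValueError("at least one refinement round is required")
        for min_len, min_q in self.rounds:
            if min_len < 0 or not 0.0 <= min_q <= 1.0:
                raise ValueError(f"invalid round thresholds ({min_len}, {min_q})")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


# --- overlap detection -----------------------------------------------------

_KMER = 16
_MIN_SEED_VOTES = 3
_VOTE_TOLERANCE = 20


def _unique_kmers(seq: str, k: int = _KMER) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in seen:
            dup.add(km)
        else:
            seen[km] = i
    for km in dup:
        del seen[km]
    return seen


def _pair_offset(kmers_a: dict[str, int], kmers_b: dict[str, int]):
    """Estimated start of read b in read a coordinates, from shared unique k-mers."""
    votes = [kmers_a[km] - kmers_b[km] for km in kmers_a.keys() & kmers_b.keys()]
    if len(votes) < _MIN_SEED_VOTES:
        return None, 0
    votes.sort()
    offset = votes[len(votes) // 2]
    support = sum(1 for v in votes if abs(v - offset) <= _VOTE_TOLERANCE)
    if support < _MIN_SEED_VOTES:
        return None, 0
    return offset, support


def _layout_offsets(seqs: list[str], anchor: int) -> list[int]:
    """Breadth-first placement of every read relative to the anchor read."""
    n = len(seqs)
    kmers = [_unique_kmers(s) for s in seqs]
    offsets: dict[int, int] = {anchor: 0}
    frontier = [anchor]
    while frontier:
        nxt = []
        for i in frontier:
            for j in range(n):
                if j in offsets:
                    continue
                off, support = _pair_offset(kmers[i], kmers[j])
                if support:
                    offsets[j] = offsets[i] + off
                    nxt.append(j)
        frontier = sorted(nxt)
    if len(offsets) != n:
        missing = sorted(set(range(n)) - set(offsets))
        raise AssemblyError(
            f"fragmented input: {len(missing)} read(s) share no overlap with "
            f"the main layout (indices {missing})")
    return [offsets[i] for i in range(n)]


# a putative extension shorter than the offset-estimation error is noise
_MIN_EXTENSION = 2 * _VOTE_TOLERANCE


def assemble_draft(reads, max_consensus_rounds: int = 3) -> str:
    """Greedy OLC draft: overlap (seed-and-vote), layout, pileup consensus.

    Deterministic given input order: overlaps are estimated from shared
    unique 16-mers, reads are laid out left to right relative to the
    highest-quality read, stitched into a backbone, and the backbone is
    corrected by column-majority pileup rounds over all reads.
    """
    reads = list(reads)
    if not reads:
        raise AssemblyError("no reads to assemble")
    seqs = [r.sequence for r in reads]
    if len(seqs) == 1:
        return seqs[0]
    anchor = max(range(len(reads)),
                 key=lambda i: (reads[i].quality, len(seqs[i]), -i))
    offsets = _layout_offsets(seqs, anchor)
    order = sorted(range(len(seqs)), key=lambda i: (offsets[i], i))
    origin = offsets[order[0]]
    backbone = seqs[order[0]]
    for i in order[1:]:
        rel = offsets[i] - origin
        if rel > len(backbone):
            raise AssemblyError("fragmented input: coverage gap in layout")
        end = rel + len(seqs[i])
        # extend only on evidence beyond the offset jitter, except for an
        # exact suffix-prefix continuation (error-free tiling)
        extension = end - len(backbone)
        if extension <= 0:
            continue
        overlap = len(backbone) - rel
        if extension >= _MIN_EXTENSION or backbone[rel:] == seqs[i][:overlap]:
            backbone += seqs[i][overlap:]
    draft = backbone
    for _ in range(max_consensus_rounds):
        new = pileup_consensus(draft, seqs, tie_break="lex",
                               trim_uncovered_ends=True).consensus
        if new == draft:
            break
        draft = new
    return draft


# --- iterative refinement --------------------------------------------------


@dataclass
class RoundReport:
    """What one refinement round did to the reference."""

    round_index: int
    min_length: int
    min_quality: float
    reads_used: int
    edit_distances: list = field(default_factory=list)  # per iteration
    converged: bool = False
    skipped: bool = False


def polish_detailed(reference: str, reads,
                    config: RefinementConfig | None = None) -> tuple[str, list[RoundReport]]:
    """Run the refinement schedule; return the final consensus and round reports."""
    if not reference:
        raise ValueError("reference must be non-empty")
    if config is None:
        config = RefinementConfig()
    reports = []
    for idx, (min_len, min_q) in enumerate(config.rounds):
        selected = select_assembly_reads(reads, min_len, min_q)
        report = RoundReport(idx, min_len, min_q, len(selected))
        if not selected:
            logger.warning("refinement round %d: no reads pass (>%d nt, >%s); skipped",
                           idx, min_len, min_q)
            report.skipped = True
            reports.append(report)
            continue
        seqs = [r.sequence for r in selected]
        for _ in range(config.max_iterations):
            new = pileup_consensus(reference, seqs, tie_break="lex",
                                   trim_uncovered_ends=True).consensus
            d = edit_distance(new, reference,
                              band=abs(len(new) - len(reference)) + 200)
            report.edit_distances.append(d)
            reference = new
            if d <= config.convergence:
                report.converged = True
                break
        reports.append(report)
    return reference, reports


def polish(reference: str, reads, config: RefinementConfig | None = None) -> str:
    """Refinement schedule without the per-round report."""
    return polish_detailed(reference, reads, config)[0]
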