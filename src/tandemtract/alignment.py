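"""Alignment primitives shared by the consensus, polishing and verification stages.

Two engines live here:

* a banded global/semi-global edit-distance aligner (numba-compiled) used for
  the high-volume read-versus-reference alignments behind pileup consensus;
* a thin wrapper over :class:`Bio.Align.PairwiseAligner` for scored local
  alignment (percent-identity reporting).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from numba import njit

from .dna import decode, encode, validate_dna

_INF = 1 << 30

# move codes in the traceback matrix
_START, _DIAG, _UP, _LEFT = 0, 1, 2, 3

# pileup column codes: 0-3 bases, 4 deletion
_DEL = 4


@njit(cache=True)
def _banded_dp(ref, qry, band, free_ref_ends, mismatch_cost):  # pragma: no cover - numba
    """Banded edit-distance DP of query against reference.

    Rows are reference positions, columns query positions; gaps cost 1,
    a mismatch costs ``mismatch_cost``.
    With ``free_ref_ends`` the alignment may leave a prefix/suffix of the
    *reference* unconsumed at no cost (reads covering part of a contig).
    Returns (distance, moves, last_col, start_row) where ``last_col[i]`` is
    the cost of consuming the full query by reference row ``i``.
    """
    n, m = ref.size, qry.size
    prev = np.full(m + 1, _INF, np.int64)
    cur = np.full(m + 1, _INF, np.int64)
    moves = np.zeros((n + 1, m + 1), np.uint8)
    last_col = np.full(n + 1, _INF, np.int64)

    plo = 0
    phi = min(m, band)
    for j in range(phi + 1):
        prev[j] = j
        moves[0, j] = _LEFT
    moves[0, 0] = _START
    if m <= band:
        last_col[0] = prev[m]

    for i in range(1, n + 1):
        c = (i * m) // n
        lo = max(0, c - band)
        hi = min(m, c + band)
        # invalidate stale cells outside the previous row's band
        if lo >= 1 and lo - 1 < plo:
            prev[lo - 1] = _INF
        for j in range(phi + 1, hi + 1):
            prev[j] = _INF
        if lo >= 1:
            cur[lo - 1] = _INF
        for j in range(lo, hi + 1):
            best = _INF
            mv = _START
            if j == 0:
                if free_ref_ends:
                    best = 0
                    mv = _START
                elif prev[0] < _INF:
                    best = prev[0] + 1
                    mv = _UP
            else:
                s = prev[j - 1]
                if s < _INF:
                    if ref[i - 1] != qry[j - 1]:
                        s += mismatch_cost
                    if s < best:
                        best = s
                        mv = _DIAG
                if prev[j] < _INF and prev[j] + 1 < best:
                    best = prev[j] + 1
                    mv = _UP
                if cur[j - 1] < _INF and cur[j - 1] + 1 < best:
                    best = cur[j - 1] + 1
                    mv = _LEFT
            cur[j] = best
            moves[i, j] = mv
        if hi == m:
            last_col[i] = cur[m]
        for j in range(lo, hi + 1):
            prev[j] = cur[j]
        plo = lo
        phi = hi

    if free_ref_ends:
        # prefer the deepest row among equal costs (maximal ref coverage)
        best_i = n
        best_d = last_col[n]
        for i in range(n, -1, -1):
            if last_col[i] < best_d:
                best_d = last_col[i]
                best_i = i
        return best_d, moves, last_col, best_i
    return last_col[n], moves, last_col, n


@njit(cache=True)
def _banded_cost(ref, qry, band, mismatch_cost, ins_cost, del_cost):  # pragma: no cover - numba
    """Score-only variant of :func:`_banded_dp` (global, no traceback).

    ``ins_cost`` charges query bases absent from the reference, ``del_cost``
    reference bases absent from the query; unequal costs let the objective
    approximate the negative log-likelihood of an asymmetric error channel.
    """
    n, m = ref.size, qry.size
    prev = np.full(m + 1, _INF, np.int64)
    cur = np.full(m + 1, _INF, np.int64)
    plo = 0
    phi = min(m, band)
    for j in range(phi + 1):
        prev[j] = j * ins_cost
    for i in range(1, n + 1):
        c = (i * m) // n
        lo = max(0, c - band)
        hi = min(m, c + band)
        if lo >= 1 and lo - 1 < plo:
            prev[lo - 1] = _INF
        for j in range(phi + 1, hi + 1):
            prev[j] = _INF
        if lo >= 1:
            cur[lo - 1] = _INF
        for j in range(lo, hi + 1):
            best = _INF
            if j == 0:
                if prev[0] < _INF:
                    best = prev[0] + del_cost
            else:
                s = prev[j - 1]
                if s < _INF:
                    if ref[i - 1] != qry[j - 1]:
                        s += mismatch_cost
                    if s < best:
                        best = s
                if prev[j] + del_cost < best:
                    best = prev[j] + del_cost
                if cur[j - 1] + ins_cost < best:
                    best = cur[j - 1] + ins_cost
            cur[j] = best
        for j in range(lo, hi + 1):
            prev[j] = cur[j]
        plo = lo
        phi = hi
    return prev[m]


@njit(cache=True)
def _traceback(moves, qry, n, m, end_row):  # pragma: no cover - numba
    """Walk the move matrix back from (end_row, m).

    Returns ``col`` (per reference row: aligned query base code, 4 for a
    deletion, -1 for uncovered), ``ins_first`` (per junction ``i`` — the gap
    before reference row ``i`` — the first inserted query base, or -1) and
    ``qpos`` (per junction: query offset at that reference boundary, before
    any insertion at the junction).
    """
    col = np.full(n, -1, np.int8)
    ins_first = np.full(n + 1, -1, np.int8)
    qpos = np.zeros(n + 1, np.int64)
    for k in range(end_row, n + 1):
        qpos[k] = m
    i, j = end_row, m
    while True:
        qpos[i] = j
        mv = moves[i, j]
        if mv == _START:
            break
        if mv == _DIAG:
            i -= 1
            j -= 1
            col[i] = qry[j]
        elif mv == _UP:
            i -= 1
            col[i] = _DEL
        else:  # _LEFT: insertion relative to the reference at junction i
            j -= 1
            ins_first[i] = qry[j]
    for k in range(i):
        qpos[k] = j
    return col, ins_first, i, qpos


def _band_for(n: int, m: int, extra: int | None = None) -> int:
    if extra is None:
        extra = max(100, n // 20)
    return abs(n - m) + extra


def edit_distance(a: str, b: str, band: int | None = None) -> int:
    """Edit (Levenshtein) distance between two DNA strings.

    ``band=None`` runs the full unbanded DP (exact); a band is an upper-bound
    accelerator, exact whenever the true alignment stays inside it.
    """
    ac, bc = encode(a), encode(b)
    if ac.size == 0:
        return bc.size
    if bc.size == 0:
        return ac.size
    if band is None:
        band = max(ac.size, bc.size)
    return int(_banded_cost(ac, bc, band, 1, 1, 1))


@dataclass
class PileupResult:
    """Consensus plus supporting per-column tallies from one pileup round."""

    consensus: str
    coverage: np.ndarray  # per reference position
    n_aligned: int


def align_to_reference(ref_codes: np.ndarray, qry_codes: np.ndarray,
                       band_extra: int | None = None, mismatch_cost: int = 2):
    """Align a read to a reference, free at reference ends.

    The default mismatch cost of 2 (gaps cost 1) keeps substitutions from
    absorbing insertion/deletion pairs inside repeat tracts, which sharpens
    the per-column indel votes used by pileup consensus.

    Returns (distance, col, ins_first, start_row, end_row, qpos); see
    :func:`_traceback` for the encodings.
    """
    band = _band_for(ref_codes.size, qry_codes.size, band_extra)
    d, moves, _, end_row = _banded_dp(ref_codes, qry_codes, band, True,
                                      mismatch_cost)
    col, ins_first, start_row, qpos = _traceback(moves, qry_codes,
                                                 ref_codes.size,
                                                 qry_codes.size, end_row)
    return int(d), col, ins_first, start_row, end_row, qpos


def pileup_consensus(reference: str, sequences, *, tie_break: str = "lex",
                     band_extra: int | None = None,
                     min_insert_fraction: float = 0.5,
                     deletion_on_tie: bool = True,
                     mismatch_cost: int = 2,
                     trim_uncovered_ends: bool = False) -> PileupResult:
    """Column-majority consensus of ``sequences`` aligned to ``reference``.

    Every read is aligned to the reference (reference ends free, so partial
    reads cover a sub-interval). Per reference column the plurality symbol
    among {A, C, G, T, deletion} wins. A tie between the best base and the
    deletion resolves to the deletion when ``deletion_on_tie`` (counteracts
    an insertion-dominant channel), else to the base. Base-versus-base ties
    resolve to the reference base when ``tie_break == "ref"`` (and the
    reference base is among the tied maxima), otherwise to the
    lexicographically smaller base. Insertions seen in at least
    ``min_insert_fraction`` of the reads covering a junction are incorporated
    (one base per junction per round; iterate to converge on longer
    insertions). Columns with zero coverage keep the reference base, except
    that ``trim_uncovered_ends`` drops zero-coverage runs at the reference
    ends (spurious backbone overhangs that no read supports).
    """
    reference = validate_dna(reference, name="reference")
    ref_codes = encode(reference)
    n = ref_codes.size
    counts = np.zeros((n, 5), np.int64)
    cov = np.zeros(n, np.int64)
    ins_counts = np.zeros((n + 1, 4), np.int64)
    ins_cov = np.zeros(n + 1, np.int64)
    n_aligned = 0
    idx = np.arange(n)
    for seq in sequences:
        q = encode(validate_dna(seq, name="read"))
        _, col, ins_first, start, end, _ = align_to_reference(
            ref_codes, q, band_extra, mismatch_cost)
        covered = col >= 0
        np.add.at(counts, (idx[covered], col[covered].astype(np.int64)), 1)
        cov[covered] += 1
        has_ins = ins_first >= 0
        jidx = np.nonzero(has_ins)[0]
        np.add.at(ins_counts, (jidx, ins_first[jidx].astype(np.int64)), 1)
        ins_cov[start:end + 1] += 1
        n_aligned += 1

    first, last = 0, n  # emit columns [first, last) and junctions [first, last]
    if trim_uncovered_ends and n_aligned and cov.any():
        covered_idx = np.nonzero(cov > 0)[0]
        first, last = int(covered_idx[0]), int(covered_idx[-1]) + 1

    out = []
    for i in range(first, last + 1):
        # insertion at junction i (before reference position i); a strict
        # majority is required, which keeps a 2-deep pileup from absorbing
        # every insertion of the second read
        tot = int(ins_counts[i].sum())
        if tot > 0 and ins_cov[i] > 0 and tot > min_insert_fraction * ins_cov[i]:
            out.append(int(np.argmax(ins_counts[i])))  # argmax ties -> smaller base
        if i == last:
            break
        if cov[i] == 0:
            out.append(int(ref_codes[i]))
            continue
        base_counts = counts[i, :4]
        best = int(base_counts.max())
        n_del = int(counts[i, _DEL])
        if n_del > best or (deletion_on_tie and 0 < best == n_del):
            continue  # deletion wins
        tied = np.nonzero(base_counts == best)[0]
        if tie_break == "ref" and ref_codes[i] in tied:
            out.append(int(ref_codes[i]))
        else:
            out.append(int(tied[0]))
    return PileupResult(decode(np.array(out, np.uint8)), cov, n_aligned)


# channel-aware costs for the refinement objective: read insertions are the
# dominant error mode, deletions second, substitutions rare (integer
# approximation of the channel's -log probabilities)
_REFINE_COSTS = (4, 2, 3)  # mismatch, insertion, deletion


def _total_distance(cons: np.ndarray, seqs: list, slack: int = 60,
                    costs: tuple = _REFINE_COSTS) -> int:
    mm, ins, dele = costs
    total = 0
    for q in seqs:
        total += int(_banded_cost(cons, q, abs(cons.size - q.size) + slack,
                                  mm, ins, dele))
    return total


def _apply_moves(cons: np.ndarray, moves) -> np.ndarray:
    """Apply (pos, kind, base) edits; positions refer to the input array."""
    out = cons
    for pos, kind, base in sorted(moves, reverse=True):
        if kind == "del":
            out = np.delete(out, pos)
        elif kind == "sub":
            out = out.copy()
            out[pos] = base
        else:
            out = np.insert(out, pos, base)
    return out


def refine_consensus(consensus: str, sequences, *, max_sweeps: int = 6,
                     min_votes: int = 2, pair_span: int = 50,
                     spacing: int = 60, max_candidates: int = 150,
                     band_extra: int | None = None) -> str:
    """Vote-guided search that minimises the total read-to-consensus distance.

    Plurality pileup stalls inside repeat tracts: co-optimal indel placements
    scatter equivalent votes over several columns so that no column reaches a
    majority, and single point edits toward the truth can even be locally
    uphill (a surplus unit here compensates a missing base there). This pass
    therefore collects minority indel/substitution votes as candidate moves —
    single point edits plus compensating deletion+insertion pairs up to
    ``pair_span`` nt apart — and accepts only moves that strictly lower the
    summed banded edit distance of all reads to the full consensus.
    Deterministic; sweeps stop when no move improves the objective.
    """
    consensus = validate_dna(consensus, name="consensus")
    seqs = [encode(validate_dna(s, name="read")) for s in sequences]
    if not seqs:
        return consensus
    cons = encode(consensus)
    total = _total_distance(cons, seqs)
    for _ in range(max_sweeps):
        n = cons.size
        counts = np.zeros((n, 5), np.int64)
        ins_counts = np.zeros((n + 1, 4), np.int64)
        idx = np.arange(n)
        for q in seqs:
            _, col, ins_first, _, _, _ = align_to_reference(cons, q, band_extra)
            covered = col >= 0
            np.add.at(counts, (idx[covered], col[covered].astype(np.int64)), 1)
            jidx = np.nonzero(ins_first >= 0)[0]
            np.add.at(ins_counts, (jidx, ins_first[jidx].astype(np.int64)), 1)

        scored = []  # (-votes, pos, kind, base)
        for i in range(n):
            if counts[i, _DEL] >= min_votes:
                scored.append((-int(counts[i, _DEL]), i, "del", -1))
            alt = int(counts[i, :4].argmax())
            if alt != cons[i] and counts[i, alt] >= min_votes:
                scored.append((-int(counts[i, alt]), i, "sub", alt))
        for i in range(n + 1):
            tot = int(ins_counts[i].sum())
            if tot >= min_votes:
                scored.append((-tot, i, "ins", int(np.argmax(ins_counts[i]))))
        scored.sort()
        scored = scored[:max_candidates]

        moves = [[(pos, kind, base)] for _, pos, kind, base in scored]
        dels = [pos for _, pos, kind, _ in scored if kind == "del"]
        inss = [(pos, base) for _, pos, kind, base in scored if kind == "ins"]
        # compensating pairs: each deletion with its nearest few insertions
        for i in dels:
            near = [(j, b) for j, b in inss if 2 <= abs(i - j) <= pair_span]
            near.sort(key=lambda jb: (abs(jb[0] - i), jb))
            moves += [[(i, "del", -1), (j, "ins", b)] for j, b in near[:3]]

        improving = []
        for move in moves:
            var = _apply_moves(cons, move)
            delta = _total_distance(var, seqs) - total
            if delta < 0:
                improving.append((delta, move))
        if not improving:
            break
        improving.sort(key=lambda x: (x[0], x[1]))
        chosen, used = [], []
        for _, move in improving:
            span = [p for p, _, _ in move]
            if all(abs(p - u) >= spacing for p in span for u in used):
                chosen.extend(move)
                used.extend(span)
        var = _apply_moves(cons, chosen)
        new_total = _total_distance(var, seqs)
        if new_total >= total:
            # interacting edits overshot; fall back to the single best move
            var = _apply_moves(cons, improving[0][1])
            new_total = _total_distance(var, seqs)
            if new_total >= total:
                break
        cons, total = var, new_total
    return decode(cons)


DEFAULT_LOCAL_SCORING = {
    "match": 5.0,
    "mismatch": -4.0,
    "gap_open": -12.0,
    "gap_extend": -4.0,
}


@dataclass
class LocalAlignment:
    """Best local alignment of a query against a target."""

    score: float
    matches: int
    mismatches: int
    gaps: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gaps


def local_alignment(query: str, target: str, *, match: float = 5.0,
                    mismatch: float = -4.0, gap_open: float = -12.0,
                    gap_extend: float = -4.0) -> LocalAlignment:
    """Best-scoring local (Smith–Waterman, affine-gap) alignment."""
    query = validate_dna(query, name="query")
    target = validate_dna(target, name="target")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )
    aln = aligner.align(target, query)[0]
    counts = aln.counts()
    t_blocks, q_blocks = aln.aligned
    return LocalAlignment(
        score=float(aln.score),
        matches=int(counts.identities),
        mismatches=int(counts.mismatches),
        gaps=int(counts.gaps),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
    )
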