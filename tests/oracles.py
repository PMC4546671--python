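"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own algorithms: plain recursion /
full-matrix DP, no banding, no shared code paths.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def brute_force_min_leftover(tract: str, motifs: tuple[str, ...]) -> int:
    """Minimum uncovered nucleotides over all motif tilings (memoized recursion)."""

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i == len(tract):
            return 0
        score = 1 + best(i + 1)  # leave position i uncovered
        for m in motifs:
            if tract.startswith(m, i):
                score = min(score, best(i + len(m)))
        return score

    return best(0)


def levenshtein(a: str, b: str) -> int:
    """Full-matrix unit-cost edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j - 1] + (a[i - 1] != b[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[m]


def block_edit_distance(a: tuple, b: tuple) -> int:
    """Unit-cost edit distance over symbol sequences (plain recursion + memo)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(d(i + 1, j + 1) + (a[i] != b[j]),
                   d(i + 1, j) + 1,
                   d(i, j + 1) + 1)

    return d(0, 0)


def gotoh_local(query: str, target: str, match: float = 5.0,
                mismatch: float = -4.0, gap_open: float = -12.0,
                gap_extend: float = -4.0):
    """Textbook affine-gap Smith-Waterman (Gotoh). Returns (score, matches, columns).

    Gap penalties follow the open-includes-first-extension convention (a
    length-1 gap costs ``gap_open``), matching Bio.Align.PairwiseAligner.
    Traceback prefers diagonal, then gap-in-target, then gap-in-query.
    """
    n, m = len(query), len(target)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (consume target)
    F = np.full((n + 1, m + 1), NEG)  # gap in target (consume query)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if query[i - 1] == target[j - 1] else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
    end = np.unravel_index(np.argmax(H), H.shape)
    score = float(H[end])
    # traceback for match/column counts
    i, j = int(end[0]), int(end[1])
    matches = mismatches = gaps = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if query[i - 1] == target[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                matches += query[i - 1] == target[j - 1]
                mismatches += query[i - 1] != target[j - 1]
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            gaps += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
        else:
            gaps += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
    return score, matches, matches + mismatches + gaps
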