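"""Read filtering cascade and per-molecule multi-pass consensus.

Selector semantics follow the two distinct filter styles of the workflow:
the initial cleanup filter keeps reads at the boundary (length >= L and
quality >= Q), while the per-round assembly selectors are strict
(length > L and quality > Q). Both are configurable at the call site.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .alignment import pileup_consensus, refine_consensus
from .dna import validate_dna
from .simulate import ReadRecord

__all__ = [
    "filter_reads",
    "select_assembly_reads",
    "select_multipass",
    "group_by_molecule",
    "molecule_consensus",
    "write_filter_audit",
]


def filter_reads(reads, min_length: int = 50, min_quality: float = 0.75,
                 audit: list | None = None) -> list[ReadRecord]:
    """Initial cleanup filter: keep length >= min_length AND quality >= min_quality.

    Order-preserving; the input list is not modified. When ``audit`` is a
    list, one ``(read_id, reason)`` tuple is appended per removed read.
    """
    if min_length < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    kept = []
    for r in reads:
        if len(r.sequence) < min_length:
            if audit is not None:
                audit.append((r.read_id, f"length<{min_length}"))
        elif r.quality < min_quality:
            if audit is not None:
                audit.append((r.read_id, f"quality<{min_quality}"))
        else:
            kept.append(r)
    return kept


def select_assembly_reads(reads, min_length: int, min_quality: float) -> list[ReadRecord]:
    """Per-round assembly selection: strictly length > min_length and quality > min_quality."""
    if min_length < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    return [r for r in reads
            if len(r.sequence) > min_length and r.quality > min_quality]


def select_multipass(reads, min_passes: int = 7,
                     min_predicted_accuracy: float = 0.99) -> list[ReadRecord]:
    """Keep reads with passes >= min_passes and predicted accuracy > the cutoff."""
    if min_passes < 1:
        raise ValueError("min_passes must be >= 1")
    return [r for r in reads
            if r.passes >= min_passes
            and r.predicted_accuracy > min_predicted_accuracy]


def group_by_molecule(reads) -> dict[str, list[ReadRecord]]:
    """Group reads by source molecule, preserving first-seen order."""
    groups: dict[str, list[ReadRecord]] = {}
    for r in reads:
        groups.setdefault(r.source_molecule, []).append(r)
    return groups


def molecule_consensus(pass_sequences, max_rounds: int = 4) -> str:
    """Majority-vote consensus of the passes of one molecule.

    The first pass seeds the layout; all passes are aligned to the current
    consensus and voted column-wise, with base ties resolved toward the
    current reference (the first pass in round one). Re-aligning to the
    refined consensus repeats until it stops changing or ``max_rounds`` is
    reached, then minority-vote candidates are re-examined by local search
    (see :func:`tandemtract.alignment.refine_consensus`), which resolves the
    indel placement ambiguity that plurality voting cannot inside repeats.
    A single pass is returned unchanged.
    """
    seqs = [validate_dna(s, name="pass") for s in pass_sequences]
    if not seqs:
        raise ValueError("molecule_consensus requires at least one pass")
    if len(seqs) == 1:
        return seqs[0]
    ref = seqs[0]
    for _ in range(max_rounds):
        new = pileup_consensus(ref, seqs, tie_break="ref",
                               deletion_on_tie=False).consensus
        if new == ref:
            break
        ref = new
    if len(seqs) < 3:
        return ref  # no meaningful majority signal to refine against
    return refine_consensus(ref, seqs)


def write_filter_audit(audit, path) -> None:
    """Write per-read removal decisions as a two-column TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "reason"])
        w.writerows(audit)
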