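"""Simulation of repeat-expansion templates and multi-pass single-molecule reads.

A template is an ordered list of motif blocks between unique 5'/3' flanks.
Reads emulate circular multi-pass sequencing of one molecule: every pass is
an independent draw from an insertion-dominant per-base error channel applied
to the same template copy, and each pass carries the molecule's pass count
and a model-predicted consensus accuracy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .dna import Category, decode, encode, random_dna, validate_dna

__all__ = [
    "MotifBlock",
    "ExpansionTemplate",
    "ErrorModel",
    "EditLedger",
    "ReadRecord",
    "TruncatedGeometric",
    "build_template",
    "corrupt",
    "corrupt_detailed",
    "expected_consensus_accuracy",
    "simulate_reads",
    "write_reads_fasta",
    "write_read_metadata",
    "load_reads",
]


@dataclass(frozen=True)
class MotifBlock:
    """One occurrence of a motif within the repeat tract."""

    motif: str
    category: Category = Category.INTERRUPTION

    def __post_init__(self):
        object.__setattr__(self, "motif", validate_dna(self.motif, name="motif"))
        if not 1 <= len(self.motif) <= 10:
            raise ValueError("motif length must be between 1 and 10 nt")


@dataclass(frozen=True)
class ExpansionTemplate:
    """Ground-truth expansion: motif blocks flanked by unique sequence."""

    flank5: str
    blocks: tuple
    flank3: str

    def __post_init__(self):
        object.__setattr__(self, "flank5",
                           validate_dna(self.flank5, allow_empty=True, name="flank5"))
        object.__setattr__(self, "flank3",
                           validate_dna(self.flank3, allow_empty=True, name="flank3"))
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError("template must contain at least one block")

    @property
    def repeat_tract(self) -> str:
        return "".join(b.motif for b in self.blocks)

    @property
    def sequence(self) -> str:
        return self.flank5 + self.repeat_tract + self.flank3

    @property
    def repeat_interval(self) -> tuple[int, int]:
        """Half-open interval of the repeat tract on the full sequence."""
        start = len(self.flank5)
        return start, start + len(self.repeat_tract)

    def __len__(self) -> int:
        return len(self.flank5) + len(self.repeat_tract) + len(self.flank3)

    def block_motifs(self) -> list[str]:
        return [b.motif for b in self.blocks]


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base error channel, insertion-dominant by default.

    Per template base: substitution with ``p_substitution`` (to one of the
    three other bases), else deletion with ``p_deletion``; independently a
    single random base is inserted after the position with ``p_insertion``.
    """

    p_insertion: float = 0.10
    p_deletion: float = 0.04
    p_substitution: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("p_insertion", "p_deletion", "p_substitution"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {p}")

    @property
    def total_rate(self) -> float:
        return self.p_insertion + self.p_deletion + self.p_substitution

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class EditLedger:
    """Record of the edits the channel actually applied to one sequence."""

    insertions: int
    deletions: int
    substitutions: int
    original_length: int

    @property
    def error_fraction(self) -> float:
        if self.original_length == 0:
            return 0.0
        return (self.insertions + self.deletions + self.substitutions) / self.original_length


@dataclass
class ReadRecord:
    """A single pass of one molecule, with molecule-level pass metadata."""

    read_id: str
    sequence: str
    quality: float          # 1 - realized per-base error rate of this pass
    passes: int             # pass count of the source molecule
    predicted_accuracy: float
    source_molecule: str

    def __post_init__(self):
        self.sequence = validate_dna(self.sequence, name="sequence")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if not 0.0 <= self.quality <= 1.0:
            raise ValueError("quality must be in [0, 1]")
        if not 0.0 <= self.predicted_accuracy <= 1.0:
            raise ValueError("predicted_accuracy must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)


def build_template(block_spec, flank5: str = "", flank3: str = "",
                   canonical: str = "ATTCT") -> ExpansionTemplate:
    """Expand ``[(motif, repeat_count), ...]`` into an :class:`ExpansionTemplate`.

    Blocks are emitted in order; a motif equal to ``canonical`` is tagged
    canonical, every other motif is tagged as an interruption.
    """
    canonical = validate_dna(canonical, name="canonical")
    blocks: list[MotifBlock] = []
    for motif, count in block_spec:
        motif = validate_dna(motif, name="motif")
        if count < 1:
            raise ValueError(f"repeat_count must be >= 1, got {count}")
        cat = Category.CANONICAL if motif == canonical else Category.INTERRUPTION
        blocks.extend(MotifBlock(motif, cat) for _ in range(count))
    return ExpansionTemplate(flank5, tuple(blocks), flank3)


def corrupt_detailed(sequence: str, model: ErrorModel,
                     rng: np.random.Generator | None = None) -> tuple[str, EditLedger]:
    """Apply the error channel; return the corrupted sequence and its ledger."""
    codes = encode(validate_dna(sequence, name="sequence"))
    if rng is None:
        rng = model.rng()
    n = codes.size
    u = rng.random(n)
    sub = u < model.p_substitution
    dele = (u >= model.p_substitution) & (u < model.p_substitution + model.p_deletion)
    ins = rng.random(n) < model.p_insertion
    newbase = (codes + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    insbase = rng.integers(0, 4, size=n, dtype=np.uint8)

    keep = ~dele
    emitted = np.where(sub & keep, newbase, codes)
    slot = keep.astype(np.int64) + ins.astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(slot)[:-1])) if n else np.zeros(0, np.int64)
    out = np.empty(int(slot.sum()), np.uint8)
    out[starts[keep]] = emitted[keep]
    out[starts[ins] + keep[ins]] = insbase[ins]
    ledger = EditLedger(int(ins.sum()), int(dele.sum()), int(sub.sum()), n)
    return decode(out), ledger


def corrupt(sequence: str, model: ErrorModel,
            rng: np.random.Generator | None = None) -> str:
    """Apply the error channel and return only the corrupted sequence."""
    return corrupt_detailed(sequence, model, rng)[0]


def expected_consensus_accuracy(passes: int, model: ErrorModel) -> float:
    """Model-expected per-base accuracy of a majority consensus of ``passes``.

    A consensus base is taken as wrong when a strict majority of passes is
    erroneous at that site; even pass counts fall back to the next lower odd
    count (a tie resolves to an arbitrary single pass, which is no better).
    This is an operational stand-in for the instrument's predicted accuracy;
    it is 1 - q at one pass and non-decreasing in the pass count for q < 0.5.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    q = model.total_rate
    m = passes if passes % 2 == 1 else passes - 1
    t = (m + 1) // 2
    eps = float(binom.sf(t - 1, m, q))
    return 1.0 - eps


@dataclass(frozen=True)
class TruncatedGeometric:
    """Pass-count sampler: geometric(p) truncated to [1, max_passes]."""

    p: float = 0.35
    max_passes: int = 12

    def __call__(self, rng: np.random.Generator) -> int:
        k = int(rng.geometric(self.p))
        return min(k, self.max_passes)


def _resolve_passes(pass_distribution, molecule: int, rng: np.random.Generator) -> int:
    if pass_distribution is None:
        pass_distribution = TruncatedGeometric()
    if isinstance(pass_distribution, int):
        k = pass_distribution
    elif callable(pass_distribution):
        k = int(pass_distribution(rng))
    else:
        k = int(pass_distribution[molecule])
    if k < 1:
        raise ValueError("pass counts must be >= 1")
    return k


def simulate_reads(template: ExpansionTemplate, depth: int,
                   pass_distribution=None, model: ErrorModel | None = None,
                   id_prefix: str = "mol") -> list[ReadRecord]:
    """Simulate ``depth`` molecules; every pass becomes one :class:`ReadRecord`.

    ``pass_distribution`` may be an int (fixed pass count), a per-molecule
    sequence of ints, a callable ``f(rng) -> int``, or None for the default
    truncated geometric. All randomness flows from ``model.seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if model is None:
        model = ErrorModel()
    tpl_seq = template.sequence
    if not tpl_seq:
        raise ValueError("template sequence is empty")
    rng = model.rng()
    reads: list[ReadRecord] = []
    for mol in range(depth):
        k = _resolve_passes(pass_distribution, mol, rng)
        acc = expected_consensus_accuracy(k, model)
        name = f"{id_prefix}{mol:04d}"
        for p in range(k):
            seq, ledger = corrupt_detailed(tpl_seq, model, rng=rng)
            quality = max(0.0, 1.0 - ledger.error_fraction)
            reads.append(ReadRecord(
                read_id=f"{name}/{p}",
                sequence=seq,
                quality=quality,
                passes=k,
                predicted_accuracy=acc,
                source_molecule=name,
            ))
    return reads


# ---------------------------------------------------------------------------
# plain-text interchange: FASTA + sidecar TSV


METADATA_COLUMNS = ("read_id", "source_molecule", "length", "quality",
                    "passes", "predicted_accuracy")


def write_reads_fasta(reads, path, seed: int | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in reads:
            extra = f" seed={seed}" if seed is not None else ""
            fh.write(f">{r.read_id} molecule={r.source_molecule} passes={r.passes} "
                     f"quality={r.quality:.6f} "
                     f"predicted_accuracy={r.predicted_accuracy:.6f}{extra}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i:i + 80] + "\n")


def write_read_metadata(reads, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(METADATA_COLUMNS)
        for r in reads:
            w.writerow([r.read_id, r.source_molecule, len(r.sequence),
                        f"{r.quality:.6f}", r.passes,
                        f"{r.predicted_accuracy:.6f}"])


def load_reads(fasta_path, tsv_path) -> list[ReadRecord]:
    """Rehydrate ReadRecords from a FASTA plus its metadata sidecar."""
    from Bio import SeqIO

    meta = {}
    with Path(tsv_path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["read_id"]] = row
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.get(rec.id)
        if row is None:
            raise KeyError(f"read {rec.id!r} missing from metadata TSV")
        reads.append(ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq),
            quality=float(row["quality"]),
            passes=int(row["passes"]),
            predicted_accuracy=float(row["predicted_accuracy"]),
            source_molecule=row["source_molecule"],
        ))
    return reads


def random_flanks(len5: int, len3: int, seed: int = 0) -> tuple[str, str]:
    """Deterministic unique flank pair for synthetic templates."""
    rng = np.random.default_rng(seed)
    return random_dna(len5, rng), random_dna(len3, rng)
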