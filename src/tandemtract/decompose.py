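"""Motif-block decomposition of repeat tracts and composition statistics.

The tract is tiled with motifs from a dictionary by dynamic programming with
a lexicographic objective: (1) minimise uncovered (leftover) nucleotides,
(2) minimise the number of blocks, (3) prefer higher-priority motifs left to
right. Maximal uncovered intervals are reported as miscellaneous leftovers.
Coordinates are 0-based, half-open, on the forward strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .alignment import local_alignment
from .dna import Category, DnaError, validate_dna

__all__ = [
    "MotifDictionary",
    "Block",
    "RepeatDecomposition",
    "CompositionSummary",
    "FlankNotFoundError",
    "decompose",
    "composition",
    "locate_repeat_tract",
    "render_schematic",
    "decomposition_to_bed",
]

DEFAULT_CANONICAL = "ATTCT"
DEFAULT_INTERRUPTIONS = ("ATTTTCT", "ATATTCT", "ATTCTCT", "ATTCTTCT",
                         "ATTCC", "ATCCT", "ATCCC")
DEFAULT_MINOR = ("ACT", "ATC", "ATT", "ATCT", "ATTTCT", "ATTTCC", "ATCC")


def _default_priority(canonical, interruptions, minor):
    # canonical first, then longer known interruptions before shorter,
    # then minor motifs; length ties break lexicographically
    by_len = lambda motifs: sorted(motifs, key=lambda m: (-len(m), m))
    return (canonical, *by_len(interruptions), *by_len(minor))


@dataclass(frozen=True)
class MotifDictionary:
    """The motif vocabulary used to tile a repeat tract.

    ``priority`` is a total order over all motifs used for tie-breaking; it
    must contain the canonical motif and every interruption/minor motif
    exactly once.
    """

    canonical: str = DEFAULT_CANONICAL
    known_interruptions: tuple = DEFAULT_INTERRUPTIONS
    minor: tuple = DEFAULT_MINOR
    priority: tuple = ()

    def __post_init__(self):
        canonical = validate_dna(self.canonical, name="canonical")
        interruptions = tuple(validate_dna(m, name="interruption motif")
                              for m in self.known_interruptions)
        minor = tuple(validate_dna(m, name="minor motif") for m in self.minor)
        if canonical in interruptions or canonical in minor:
            raise ValueError("canonical motif must not appear in the other sets")
        if set(interruptions) & set(minor):
            raise ValueError("interruption and minor sets must be disjoint")
        priority = tuple(self.priority) or _default_priority(
            canonical, interruptions, minor)
        expected = {canonical, *interruptions, *minor}
        if len(priority) != len(set(priority)) or set(priority) != expected:
            raise ValueError("priority must cover every motif exactly once")
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "known_interruptions", interruptions)
        object.__setattr__(self, "minor", minor)
        object.__setattr__(self, "priority", priority)

    @property
    def motifs(self) -> tuple:
        return self.priority

    def category(self, motif: str) -> Category:
        if motif == self.canonical:
            return Category.CANONICAL
        if motif in self.known_interruptions or motif in self.minor:
            return Category.INTERRUPTION
        return Category.MISCELLANEOUS

    def is_minor(self, motif: str) -> bool:
        return motif in self.minor

    @classmethod
    def default(cls) -> "MotifDictionary":
        return cls.from_dict(json.loads(
            resources.files("tandemtract.data").joinpath(
                "default_motifs.json").read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "MotifDictionary":
        return cls(canonical=d["canonical"],
                   known_interruptions=tuple(d.get("known_interruptions", ())),
                   minor=tuple(d.get("minor", ())),
                   priority=tuple(d.get("priority", ())))

    @classmethod
    def from_json(cls, path) -> "MotifDictionary":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {"canonical": self.canonical,
                "known_interruptions": list(self.known_interruptions),
                "minor": list(self.minor),
                "priority": list(self.priority)}


@dataclass(frozen=True)
class Block:
    """One motif block on the tract: [start, end) spells ``motif``."""

    motif: str
    start: int
    end: int
    category: Category


@dataclass
class RepeatDecomposition:
    """Segmentation of a tract into motif blocks plus leftover intervals."""

    blocks: list
    leftovers: list  # [(start, end), ...]
    source_length: int
    sequence: str = ""

    def __post_init__(self):
        # tiling invariant: blocks and leftovers are sorted, disjoint and
        # jointly cover [0, source_length)
        pieces = sorted(
            [(b.start, b.end) for b in self.blocks] + list(self.leftovers))
        pos = 0
        for start, end in pieces:
            if start != pos or end <= start:
                raise ValueError("blocks and leftovers must tile the tract")
            pos = end
        if pos != self.source_length:
            raise ValueError("blocks and leftovers must tile the tract")
        if self.sequence:
            for b in self.blocks:
                if self.sequence[b.start:b.end] != b.motif:
                    raise ValueError(
                        f"block at {b.start} does not spell its motif {b.motif}")

    @property
    def block_motifs(self) -> list:
        return [b.motif for b in self.blocks]

    @property
    def leftover_nt(self) -> int:
        return sum(end - start for start, end in self.leftovers)


def decompose(tract: str, dictionary: MotifDictionary | None = None) -> RepeatDecomposition:
    """Optimal motif tiling of ``tract`` under the lexicographic objective."""
    tract = validate_dna(tract, name="tract")
    if dictionary is None:
        dictionary = MotifDictionary()
    motifs = dictionary.priority
    L = len(tract)

    # suffix DP: cost[i] = (min leftovers, min blocks) for tract[i:]
    leftover = [0] * (L + 1)
    blocks_n = [0] * (L + 1)
    for i in range(L - 1, -1, -1):
        best_lo, best_bl = leftover[i + 1] + 1, blocks_n[i + 1]
        for m in motifs:
            if tract.startswith(m, i):
                j = i + len(m)
                if j <= L:
                    clo, cbl = leftover[j], blocks_n[j] + 1
                    if (clo, cbl) < (best_lo, best_bl):
                        best_lo, best_bl = clo, cbl
        leftover[i], blocks_n[i] = best_lo, best_bl

    # left-to-right reconstruction, preferring motifs in priority order
    blocks: list[Block] = []
    leftover_pos: list[int] = []
    i = 0
    while i < L:
        chosen = None
        for m in motifs:
            j = i + len(m)
            if (j <= L and tract.startswith(m, i)
                    and leftover[j] == leftover[i]
                    and blocks_n[j] + 1 == blocks_n[i]):
                chosen = m
                break
        if chosen is not None:
            blocks.append(Block(chosen, i, i + len(chosen),
                                dictionary.category(chosen)))
            i += len(chosen)
        else:
            leftover_pos.append(i)
            i += 1

    intervals = []
    for p in leftover_pos:
        if intervals and intervals[-1][1] == p:
            intervals[-1][1] = p + 1
        else:
            intervals.append([p, p + 1])
    return RepeatDecomposition(blocks, [tuple(iv) for iv in intervals], L, tract)


@dataclass
class CompositionSummary:
    """Per-motif nucleotide/block tallies over one decomposition."""

    total_nt: int
    block_count: int
    nt_counts: dict = field(default_factory=dict)       # motif -> nt
    block_counts: dict = field(default_factory=dict)    # motif -> blocks
    miscellaneous_nt: int = 0
    canonical: str = DEFAULT_CANONICAL
    minor_motifs: tuple = ()

    @property
    def nt_percent(self) -> dict:
        return {m: 100.0 * c / self.total_nt for m, c in self.nt_counts.items()}

    @property
    def block_percent(self) -> dict:
        return {m: 100.0 * c / self.block_count for m, c in self.block_counts.items()}

    @property
    def miscellaneous_percent(self) -> float:
        return 100.0 * self.miscellaneous_nt / self.total_nt

    @property
    def canonical_nt_percent(self) -> float:
        return self.nt_percent.get(self.canonical, 0.0)

    @property
    def canonical_block_percent(self) -> float:
        if self.block_count == 0:
            return 0.0
        return self.block_percent.get(self.canonical, 0.0)

    @property
    def minor_nt_percent(self) -> float:
        """Rare-motif share: minor-set blocks plus leftovers, by nucleotides."""
        minor_nt = sum(self.nt_counts.get(m, 0) for m in self.minor_motifs)
        return 100.0 * (minor_nt + self.miscellaneous_nt) / self.total_nt

    def to_dict(self) -> dict:
        return {
            "total_nt": self.total_nt,
            "block_count": self.block_count,
            "nt_counts": dict(sorted(self.nt_counts.items())),
            "nt_percent": {m: round(v, 4) for m, v in sorted(self.nt_percent.items())},
            "block_counts": dict(sorted(self.block_counts.items())),
            "block_percent": {m: round(v, 4) for m, v in sorted(self.block_percent.items())},
            "miscellaneous_nt": self.miscellaneous_nt,
            "miscellaneous_percent": round(self.miscellaneous_percent, 4),
            "canonical": self.canonical,
            "canonical_nt_percent": round(self.canonical_nt_percent, 4),
            "canonical_block_percent": round(self.canonical_block_percent, 4),
            "minor_nt_percent": round(self.minor_nt_percent, 4),
        }


def composition(decomp: RepeatDecomposition,
                dictionary: MotifDictionary | None = None) -> CompositionSummary:
    """Nucleotide and block tallies per motif; repeat units = block count."""
    if dictionary is None:
        dictionary = MotifDictionary()
    nt_counts: dict[str, int] = {}
    block_counts: dict[str, int] = {}
    for b in decomp.blocks:
        nt_counts[b.motif] = nt_counts.get(b.motif, 0) + (b.end - b.start)
        block_counts[b.motif] = block_counts.get(b.motif, 0) + 1
    return CompositionSummary(
        total_nt=decomp.source_length,
        block_count=len(decomp.blocks),
        nt_counts=nt_counts,
        block_counts=block_counts,
        miscellaneous_nt=decomp.leftover_nt,
        canonical=dictionary.canonical,
        minor_motifs=dictionary.minor,
    )


class FlankNotFoundError(ValueError):
    """A flank did not align to the consensus at the required identity."""


def locate_repeat_tract(consensus: str, flank5: str, flank3: str,
                        min_identity: float = 0.80) -> tuple[int, int]:
    """Locate the repeat tract between the best local matches of the flanks.

    Returns the half-open interval strictly between the 3' end of the
    flank5 match and the 5' start of the flank3 match on the consensus.
    """
    consensus = validate_dna(consensus, name="consensus")
    flank5 = validate_dna(flank5, name="flank5")
    flank3 = validate_dna(flank3, name="flank3")
    if len(flank5) < 20 or len(flank3) < 20:
        raise ValueError("flanks must be at least 20 nt")
    hits = {}
    for name, flank in (("flank5", flank5), ("flank3", flank3)):
        aln = local_alignment(flank, consensus)
        identity = aln.matches / aln.columns if aln.columns else 0.0
        if identity < min_identity:
            raise FlankNotFoundError(
                f"flank not found: {name} aligns at {identity:.1%} identity "
                f"(< {min_identity:.0%})")
        hits[name] = aln
    start = hits["flank5"].target_end
    end = hits["flank3"].target_start
    if end < start:
        raise FlankNotFoundError("flank not found: flanks align out of order")
    return start, end


_LEFTOVER_GLYPH = "#"
_GLYPHS = "oABCDEFGHIJKLMNPQRSUVWXYZabcdefghij"


def render_schematic(decomp: RepeatDecomposition,
                     dictionary: MotifDictionary | None = None,
                     width: int = 60) -> str:
    """Plain-text block diagram: one glyph per block, 5'→3', plus a legend.

    The canonical motif is 'o', other motifs get letters in priority order,
    leftover intervals are '#'.
    """
    if dictionary is None:
        dictionary = MotifDictionary()
    glyph_of = {m: _GLYPHS[i] if i < len(_GLYPHS) else "?"
                for i, m in enumerate(dictionary.priority)}
    items = sorted(
        [(b.start, glyph_of.get(b.motif, "?")) for b in decomp.blocks]
        + [(start, _LEFTOVER_GLYPH) for start, _ in decomp.leftovers])
    row = "".join(g for _, g in items)
    lines = [row[i:i + width] for i in range(0, len(row), width)] or [""]
    used = {g for _, g in items}
    legend = [f"{glyph_of[m]} = {m}" for m in dictionary.priority
              if glyph_of[m] in used]
    if _LEFTOVER_GLYPH in used:
        legend.append(f"{_LEFTOVER_GLYPH} = miscellaneous")
    return "\n".join(lines + ["", "legend: " + ", ".join(legend)])


def plot_schematic(decomp: RepeatDecomposition,
                   dictionary: MotifDictionary | None = None,
                   blocks_per_row: int = 60, ax=None):
    """Optional graphical rendering of the block schematic (needs matplotlib).

    One rectangle per block, 5'->3' row-wise, coloured by motif; leftover
    intervals are black. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import patches

    if dictionary is None:
        dictionary = MotifDictionary()
    cmap = plt.get_cmap("tab20")
    colors = {m: ("white" if m == dictionary.canonical else cmap(i % 20))
              for i, m in enumerate(dictionary.priority)}
    items = sorted([(b.start, b.motif) for b in decomp.blocks]
                   + [(start, None) for start, _ in decomp.leftovers])
    if ax is None:
        _, ax = plt.subplots(
            figsize=(10, 0.35 * (len(items) // blocks_per_row + 1) + 0.5))
    for k, (_, motif) in enumerate(items):
        row, col = divmod(k, blocks_per_row)
        color = "black" if motif is None else colors.get(motif, "grey")
        ax.add_patch(patches.Rectangle((col, -row), 0.95, 0.8,
                                       facecolor=color, edgecolor="black",
                                       linewidth=0.3))
    ax.set_xlim(0, blocks_per_row)
    ax.set_ylim(-(len(items) // blocks_per_row) - 0.5, 1)
    ax.axis("off")
    return ax


def decomposition_to_bed(decomp: RepeatDecomposition, name: str) -> str:
    """BED-like annotation: name, start, end, motif, category (one line each)."""
    rows = [(b.start, b.end, b.motif, b.category.value) for b in decomp.blocks]
    rows += [(start, end, "leftover", Category.MISCELLANEOUS.value)
             for start, end in decomp.leftovers]
    rows.sort()
    return "".join(f"{name}\t{s}\t{e}\t{m}\t{c}\n" for s, e, m, c in rows)
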