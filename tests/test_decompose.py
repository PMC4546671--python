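import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemtract.decompose import (Block, FlankNotFoundError, MotifDictionary,
                                   RepeatDecomposition, composition,
                                   decompose, decomposition_to_bed,
                                   locate_repeat_tract, render_schematic)
from tandemtract.dna import Category, random_dna
from tandemtract.simulate import build_template, random_flanks

from .oracles import brute_force_min_leftover

LEAD_IN = "ATTTTCT" "ATTCT" "ATATTCT" "ATTCT" "ATATTCT" "ATTCT" "ATTTTCT"


class TestMotifDictionary:
    def test_default_priority_starts_with_canonical(self):
        d = MotifDictionary()
        assert d.priority[0] == "ATTCT"
        assert set(d.priority) == {d.canonical, *d.known_interruptions, *d.minor}

    def test_packaged_default_matches_builtin(self):
        assert MotifDictionary.default() == MotifDictionary()

    def test_canonical_cannot_be_interruption(self):
        with pytest.raises(ValueError):
            MotifDictionary(canonical="ATTCT", known_interruptions=("ATTCT",))

    def test_priority_must_cover_all(self):
        with pytest.raises(ValueError):
            MotifDictionary(priority=("ATTCT",))

    def test_json_roundtrip(self, tmp_path):
        d = MotifDictionary()
        p = tmp_path / "dict.json"
        import json
        p.write_text(json.dumps(d.to_dict()))
        assert MotifDictionary.from_json(p) == d


class TestDecompose:
    def test_two_canonical_blocks(self):
        d = decompose("ATTCTATTCT")
        assert [(b.motif, b.start, b.end) for b in d.blocks] == \
            [("ATTCT", 0, 5), ("ATTCT", 5, 10)]
        assert d.leftovers == []

    def test_interrupted_lead_in(self):
        d = decompose(LEAD_IN)
        assert d.block_motifs == ["ATTTTCT", "ATTCT", "ATATTCT", "ATTCT",
                                  "ATATTCT", "ATTCT", "ATTTTCT"]
        assert d.leftovers == []

    def test_heptamer_preferred_over_pentamer_plus_leftover(self):
        d = decompose("ATTCTCT")
        assert d.block_motifs == ["ATTCTCT"]
        assert d.leftovers == []

    def test_leftover_interval_merging(self):
        d = decompose("ATTCT" + "GGGG" + "ATTCT")
        assert d.block_motifs == ["ATTCT", "ATTCT"]
        assert d.leftovers == [(5, 9)]
        assert d.leftover_nt == 4

    def test_empty_tract_rejected(self):
        with pytest.raises(Exception):
            decompose("")

    @given(tract=st.text(alphabet="ACT", min_size=1, max_size=30),
           seed=st.integers(0, 10_000))
    @settings(max_examples=120, deadline=None)
    def test_leftover_minimality_matches_brute_force(self, tract, seed):
        rng = np.random.default_rng(seed)
        pool = ["ATTCT", "ACT", "ATC", "TCA", "CT", "AT", "TTT", "ATCT", "CAT"]
        k = int(rng.integers(2, 6))
        chosen = tuple(rng.choice(pool, size=k, replace=False))
        dictionary = MotifDictionary(canonical=chosen[0],
                                     known_interruptions=tuple(chosen[1:]),
                                     minor=())
        d = decompose(tract, dictionary)
        assert d.leftover_nt == brute_force_min_leftover(tract, chosen)

    @given(tract=st.text(alphabet="ACGT", min_size=1, max_size=200))
    @settings(max_examples=80, deadline=None)
    def test_tiling_partition_property(self, tract):
        d = decompose(tract)
        covered = sum(b.end - b.start for b in d.blocks) + d.leftover_nt
        assert covered == len(tract) == d.source_length

    def test_round_trip_of_template_spec(self):
        spec = [("ATTTTCT", 1), ("ATTCT", 1), ("ATATTCT", 1), ("ATTCT", 1),
                ("ATATTCT", 1), ("ATTCT", 1), ("ATTTTCT", 1),
                ("ATTCT", 20), ("ATCCT", 2), ("ATTCT", 5), ("ATCCC", 10)]
        t = build_template(spec)
        d = decompose(t.repeat_tract)
        assert d.block_motifs == t.block_motifs()
        assert d.leftovers == []


class TestRepeatDecompositionInvariants:
    def test_overlapping_blocks_rejected(self):
        blocks = [Block("ATTCT", 0, 5, Category.CANONICAL),
                  Block("ATTCT", 3, 8, Category.CANONICAL)]
        with pytest.raises(ValueError):
            RepeatDecomposition(blocks, [], 8)

    def test_gap_without_leftover_rejected(self):
        blocks = [Block("ATTCT", 0, 5, Category.CANONICAL)]
        with pytest.raises(ValueError):
            RepeatDecomposition(blocks, [], 7)

    def test_block_must_spell_motif(self):
        blocks = [Block("ATTCT", 0, 5, Category.CANONICAL)]
        with pytest.raises(ValueError):
            RepeatDecomposition(blocks, [], 5, sequence="GGGGG")


class TestComposition:
    def test_pure_canonical(self):
        summary = composition(decompose("ATTCT" * 10))
        assert summary.block_count == 10
        assert summary.canonical_nt_percent == 100.0
        assert summary.canonical_block_percent == 100.0
        assert summary.miscellaneous_nt == 0

    def test_percentages_from_known_block_spec(self):
        spec = [("ATTCT", 30), ("ATCCT", 10), ("ATCCC", 10)]
        t = build_template(spec)
        summary = composition(decompose(t.repeat_tract))
        total = 30 * 5 + 10 * 5 + 10 * 5
        assert summary.total_nt == total
        assert summary.nt_percent["ATTCT"] == pytest.approx(100 * 150 / total)
        assert summary.nt_percent["ATCCT"] == pytest.approx(100 * 50 / total)
        assert summary.block_count == 50

    @given(tract=st.text(alphabet="ACGT", min_size=1, max_size=150))
    @settings(max_examples=60, deadline=None)
    def test_percentages_sum_to_100(self, tract):
        summary = composition(decompose(tract))
        total_pct = sum(summary.nt_percent.values()) + summary.miscellaneous_percent
        assert total_pct == pytest.approx(100.0)
        assert sum(summary.nt_counts.values()) + summary.miscellaneous_nt == \
            summary.total_nt

    def test_minor_percent_includes_leftovers(self):
        # ATT is in the minor set; GGGG becomes a leftover
        tract = "ATTCT" * 10 + "ATT" + "GGGG"
        summary = composition(decompose(tract))
        expected = 100.0 * (3 + 4) / len(tract)
        assert summary.minor_nt_percent == pytest.approx(expected)


class TestLocateRepeatTract:
    def test_exact_synthetic_interval(self, small_template):
        start, end = locate_repeat_tract(small_template.sequence,
                                         small_template.flank5,
                                         small_template.flank3)
        assert (start, end) == small_template.repeat_interval

    def test_tolerant_to_flank_substitutions(self, small_template):
        flank5 = list(small_template.flank5)
        for pos in (10, 50, 90, 130, 170):
            flank5[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[flank5[pos]]
        start, end = locate_repeat_tract(small_template.sequence,
                                         "".join(flank5),
                                         small_template.flank3)
        assert (start, end) == small_template.repeat_interval

    def test_missing_flank_raises(self, small_template):
        absent = random_dna(100, np.random.default_rng(99))
        with pytest.raises(FlankNotFoundError, match="flank not found"):
            locate_repeat_tract(small_template.sequence,
                                small_template.flank5, absent)

    def test_short_flank_rejected(self, small_template):
        with pytest.raises(ValueError):
            locate_repeat_tract(small_template.sequence, "ACGTACGT",
                                small_template.flank3)


class TestRenderSchematic:
    def test_three_blocks_three_glyphs(self):
        text = render_schematic(decompose("ATTCT" * 3))
        assert text.splitlines()[0] == "ooo"

    def test_no_leftovers_no_black_glyphs(self):
        assert "#" not in render_schematic(decompose("ATTCT" * 5))

    def test_leftovers_shown(self):
        text = render_schematic(decompose("ATTCTGGGGATTCT"))
        assert "#" in text
        assert "miscellaneous" in text

    def test_3prime_block_contiguity(self):
        tract = "ATTCT" * 20 + "ATCCC" * 15
        row = render_schematic(decompose(tract), width=1000).splitlines()[0]
        # the 3' end of the row is one contiguous run of the ATCCC glyph
        glyph = row[-1]
        assert row.endswith(glyph * 15)
        assert glyph != "o"


def test_bed_export_shape():
    d = decompose("ATTCTGGGGATTCT")
    bed = decomposition_to_bed(d, "cons")
    lines = [l.split("\t") for l in bed.strip().splitlines()]
    assert len(lines) == 3
    assert lines[1][3] == "leftover"
    assert all(l[0] == "cons" for l in lines)


def test_flanked_template_decomposition(small_template):
    start, end = locate_repeat_tract(small_template.sequence,
                                     small_template.flank5,
                                     small_template.flank3)
    d = decompose(small_template.sequence[start:end])
    assert d.block_motifs == small_template.block_motifs()
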