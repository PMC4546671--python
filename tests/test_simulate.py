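import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemtract.dna import Category, DnaError
from tandemtract.simulate import (ErrorModel, ExpansionTemplate,
                                  TruncatedGeometric, build_template, corrupt,
                                  corrupt_detailed,
                                  expected_consensus_accuracy, load_reads,
                                  simulate_reads, write_read_metadata,
                                  write_reads_fasta)

SUBJECT_C_LEAD_IN = [("ATTTTCT", 1), ("ATTCT", 1), ("ATATTCT", 1),
                     ("ATTCT", 1), ("ATATTCT", 1), ("ATTCT", 1),
                     ("ATTTTCT", 1)]


class TestBuildTemplate:
    def test_simple_concatenation(self):
        t = build_template([("ATTCT", 3)])
        assert t.sequence == "ATTCTATTCTATTCT"
        assert len(t) == 15

    def test_interrupted_lead_in_block(self):
        # seven alternating blocks, 43 nt total
        t = build_template(SUBJECT_C_LEAD_IN)
        assert t.repeat_tract == ("ATTTTCT" "ATTCT" "ATATTCT" "ATTCT"
                                  "ATATTCT" "ATTCT" "ATTTTCT")
        assert len(t.repeat_tract) == 43
        assert [b.motif for b in t.blocks] == [m for m, _ in SUBJECT_C_LEAD_IN]

    def test_block_count_514(self):
        # mixed-motif config expanding to exactly 514 repeat units
        spec = SUBJECT_C_LEAD_IN + [("ATTCT", 300), ("ATCCT", 27),
                                    ("ATTCT", 30), ("ATCCC", 150)]
        t = build_template(spec)
        assert len(t.blocks) == 7 + 300 + 27 + 30 + 150 == 514

    def test_categories(self):
        t = build_template([("ATTCT", 1), ("ATCCT", 1)])
        assert t.blocks[0].category is Category.CANONICAL
        assert t.blocks[1].category is Category.INTERRUPTION

    def test_flank_lengths_in_invariant(self):
        t = build_template([("ATTCT", 2)], "AAAA", "GGG")
        assert len(t) == 4 + 10 + 3
        assert t.repeat_interval == (4, 14)

    def test_non_acgt_rejected(self):
        with pytest.raises(DnaError):
            build_template([("ATTCN", 1)])

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            build_template([("ATTCT", 0)])

    def test_empty_blocks_rejected(self):
        with pytest.raises(ValueError):
            ExpansionTemplate("AAAA", (), "GGGG")


class TestCorrupt:
    def test_zero_error_identity(self, zero_model):
        seq = "ACGTACGTAA" * 50
        assert corrupt(seq, zero_model) == seq

    def test_determinism(self, default_model):
        seq = "ACGT" * 500
        assert corrupt(seq, default_model) == corrupt(seq, default_model)

    def test_insertion_rate_within_3_sigma(self):
        # binomial oracle: n=10000, p=0.10 -> sigma = sqrt(n p (1-p)) = 30
        n, p = 10_000, 0.10
        model = ErrorModel(p_insertion=p, p_deletion=0.04,
                           p_substitution=0.01, seed=123)
        rng = np.random.default_rng(0)
        seq = "".join(np.random.default_rng(5).choice(list("ACGT"), n))
        _, ledger = corrupt_detailed(seq, model, rng=rng)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(ledger.insertions - n * p) <= 3 * sigma

    def test_ledger_reconciles_lengths(self, default_model):
        seq = "ACGTTGCA" * 200
        out, ledger = corrupt_detailed(seq, default_model)
        assert len(out) == len(seq) + ledger.insertions - ledger.deletions

    @given(length=st.integers(0, 300),
           pi=st.floats(0, 0.3), pd_=st.floats(0, 0.3), ps=st.floats(0, 0.3),
           seed=st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_ledger_reconciliation_property(self, length, pi, pd_, ps, seed):
        seq = "ACGT" * (length // 4 + 1)
        seq = seq[:length] if length else "A"
        model = ErrorModel(pi, pd_, ps, seed=seed)
        out, ledger = corrupt_detailed(seq, model)
        assert len(out) == len(seq) + ledger.insertions - ledger.deletions
        assert ledger.original_length == len(seq)

    def test_law_of_large_numbers_over_100kb(self):
        model = ErrorModel(seed=99)
        seq = "ATTCT" * 20_000  # 100 kb
        _, ledger = corrupt_detailed(seq, model)
        n = len(seq)
        for observed, p in ((ledger.insertions, model.p_insertion),
                            (ledger.deletions, model.p_deletion),
                            (ledger.substitutions, model.p_substitution)):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 4 * sigma

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(p_insertion=1.0)


class TestPredictedAccuracy:
    def test_monotone_in_passes(self, default_model):
        accs = [expected_consensus_accuracy(k, default_model)
                for k in range(1, 13)]
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_single_pass_equals_one_minus_rate(self, default_model):
        assert expected_consensus_accuracy(1, default_model) == pytest.approx(
            1 - default_model.total_rate)

    def test_zero_error_is_perfect(self, zero_model):
        assert expected_consensus_accuracy(5, zero_model) == 1.0


class TestSimulateReads:
    def test_zero_error_reads_match_template(self, small_template, zero_model):
        reads = simulate_reads(small_template, 5, 1, zero_model)
        assert len(reads) == 5
        for r in reads:
            assert r.sequence == small_template.sequence
            assert r.quality == 1.0
            assert r.predicted_accuracy == 1.0

    def test_one_record_per_pass(self, small_template, default_model):
        reads = simulate_reads(small_template, 3, [2, 3, 1], default_model)
        assert len(reads) == 6
        by_mol = {}
        for r in reads:
            by_mol.setdefault(r.source_molecule, []).append(r)
        assert sorted(len(v) for v in by_mol.values()) == [1, 2, 3]
        for group in by_mol.values():
            assert len({r.passes for r in group}) == 1

    def test_multipass_predicted_accuracy_beats_single_pass_quality(
            self, small_template, default_model):
        reads = simulate_reads(small_template, 2, 7, default_model)
        for r in reads:
            assert r.predicted_accuracy > r.quality

    def test_fixed_seed_reproducible(self, small_template, default_model):
        a = simulate_reads(small_template, 4, 2, default_model)
        b = simulate_reads(small_template, 4, 2, default_model)
        assert [(r.read_id, r.sequence, r.quality) for r in a] == \
               [(r.read_id, r.sequence, r.quality) for r in b]

    def test_truncated_geometric_bounds(self, rng):
        dist = TruncatedGeometric(p=0.2, max_passes=12)
        draws = [dist(rng) for _ in range(500)]
        assert min(draws) >= 1 and max(draws) <= 12

    def test_depth_validation(self, small_template, default_model):
        with pytest.raises(ValueError):
            simulate_reads(small_template, 0, 1, default_model)


def test_fasta_tsv_roundtrip(tmp_path, small_template, default_model):
    reads = simulate_reads(small_template, 3, 2, default_model)
    fasta = tmp_path / "reads.fasta"
    tsv = tmp_path / "reads.tsv"
    write_reads_fasta(reads, fasta, seed=default_model.seed)
    write_read_metadata(reads, tsv)
    assert f"seed={default_model.seed}" in fasta.read_text()
    back = load_reads(fasta, tsv)
    assert [(r.read_id, r.sequence, r.passes, r.source_molecule) for r in back] == \
           [(r.read_id, r.sequence, r.passes, r.source_molecule) for r in reads]
    for orig, rt in zip(reads, back):
        assert rt.quality == pytest.approx(orig.quality, abs=1e-6)
        assert rt.predicted_accuracy == pytest.approx(orig.predicted_accuracy, abs=1e-6)
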