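"""Span merging and the neighbor-condensation reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import interval_union_oracle
from viropanel.cluster import ClusterParams
from viropanel.condense import condense_neighbors, condense_species_set, merge_spans
from viropanel.errors import ContractError
from viropanel.seqio import GenomicInterval, SequenceRecord, parse_subseq_header
from viropanel.simulate import MutationSpec, simulate_neighbor, simulate_parent

K = 100


class TestMergeSpans:
    def test_overlap_merge(self):
        got = merge_spans([GenomicInterval("n", 0, 100), GenomicInterval("n", 50, 150)])
        assert [(g.start, g.end) for g in got] == [(0, 150)]

    def test_bookended_merge(self):
        got = merge_spans([GenomicInterval("n", 0, 100), GenomicInterval("n", 100, 200)])
        assert [(g.start, g.end) for g in got] == [(0, 200)]

    def test_single_base_gap_stays_separate(self):
        got = merge_spans([GenomicInterval("n", 0, 100), GenomicInterval("n", 101, 200)])
        assert [(g.start, g.end) for g in got] == [(0, 100), (101, 200)]

    def test_mixed_seq_ids_rejected(self):
        with pytest.raises(ContractError):
            merge_spans([GenomicInterval("a", 0, 5), GenomicInterval("b", 0, 5)])

    @settings(derandomize=True, max_examples=300)
    @given(
        raw=st.lists(
            st.tuples(st.integers(0, 180), st.integers(1, 60)), min_size=0, max_size=25
        )
    )
    def test_matches_boolean_array_oracle(self, raw):
        intervals = [GenomicInterval("n", s, s + l) for s, l in raw]
        got = [(g.start, g.end) for g in merge_spans(intervals)]
        expected = interval_union_oracle([(s, s + l) for s, l in raw], 260)
        assert got == expected
        # output disjoint and sorted
        for (s1, e1), (s2, e2) in zip(got, got[1:]):
            assert e1 < s2


class TestCondenseNeighbors:
    def test_identical_neighbor_fully_redundant(self):
        parent = simulate_parent(2000, seed=1)
        nb = SequenceRecord("nb", parent.residues)
        entries, stats = condense_neighbors(parent, [nb])
        assert entries == []
        assert stats.retained_bp == 0
        assert stats.input_bp == 2000
        assert stats.reduction_ratio == 0.0

    def test_novel_insert_recovered_as_single_flanked_span(self):
        parent = simulate_parent(3000, seed=2)
        nb, truth = simulate_neighbor(parent, MutationSpec(novel_inserts=((1500, 500),), seed=3))
        entries, stats = condense_neighbors(parent, [nb])
        assert len(entries) == 1
        (entry,) = entries
        (ins,) = truth
        assert entry.span.start <= ins.start and entry.span.end >= ins.end
        assert ins.start - entry.span.start <= K - 1
        assert entry.span.end - ins.end <= K - 1
        # excision fidelity and header round-trip
        assert entry.residues == nb.residues[entry.span.start : entry.span.end]
        desc, parsed = parse_subseq_header(entry.header())
        assert desc == nb.description
        assert parsed == GenomicInterval(nb.id, entry.span.start, entry.span.end)

    def test_fully_novel_neighbor_retained_whole(self, rng):
        from conftest import random_seq

        parent = simulate_parent(2000, seed=4)
        nb = SequenceRecord("nb", random_seq(rng, 800))
        entries, stats = condense_neighbors(parent, [nb])
        assert len(entries) == 1
        assert (entries[0].span.start, entries[0].span.end) == (0, 800)
        assert stats.retained_bp == 800

    def test_short_neighbor_skipped_but_counted(self, caplog):
        parent = simulate_parent(1000, seed=5)
        nb = SequenceRecord("tiny", "ACGT" * 10)
        entries, stats = condense_neighbors(parent, [nb])
        assert entries == []
        assert stats.input_bp == 40

    def test_retained_bp_monotone_in_threshold(self):
        parent = simulate_parent(1500, seed=6)
        nbs = [
            simulate_neighbor(parent, MutationSpec(substitution_rate=0.05, seed=s))[0]
            for s in range(3)
        ]
        retained = []
        for thr in (0.85, 0.92, 0.97):
            _, stats = condense_neighbors(
                parent, nbs, ClusterParams(identity_threshold=thr)
            )
            retained.append(stats.retained_bp)
        assert retained == sorted(retained)

    def test_divergent_offset_conservation(self):
        """Every divergent k-mer lies inside an output span and every output
        position is touched by a divergent k-mer."""
        from viropanel.cluster import ParentScanIndex

        parent = simulate_parent(1500, seed=7)
        nb, _ = simulate_neighbor(
            parent, MutationSpec(substitution_rate=0.12, seed=8)
        )
        entries, _ = condense_neighbors(parent, [nb])
        represented, _ = ParentScanIndex(parent).classify_offsets(nb)
        divergent_offsets = np.nonzero(~represented)[0]
        spans = [(e.span.start, e.span.end) for e in entries]
        covered = np.zeros(nb.length, dtype=bool)
        for o in divergent_offsets:
            assert any(s <= o and o + K <= e for s, e in spans)
            covered[o : o + K] = True
        for s, e in spans:
            assert covered[s:e].all()

    def test_idempotence_entries_stay_divergent(self):
        parent = simulate_parent(2000, seed=9)
        nb, _ = simulate_neighbor(parent, MutationSpec(novel_inserts=((600, 400),), seed=10))
        entries, _ = condense_neighbors(parent, [nb])
        for entry in entries:
            again = SequenceRecord("re", entry.residues)
            _, stats = condense_neighbors(parent, [again])
            assert stats.retained_bp >= entry.length - 2 * (K - 1)
            assert stats.retained_bp > 0


class TestCondenseSpeciesSet:
    def test_empty_neighbor_set(self):
        parent = simulate_parent(1000, seed=11)
        entries, stats, table = condense_species_set(parent, [])
        assert entries == [] and stats.input_bp == 0
        assert stats.reduction_ratio == 0.0
        assert len(table) == 0

    def test_identical_neighbors_retain_nothing(self):
        parent = simulate_parent(1000, seed=12)
        nbs = [SequenceRecord(f"n{i}", parent.residues) for i in range(10)]
        entries, stats, table = condense_species_set(parent, nbs)
        assert stats.retained_bp == 0
        assert table["retained_bp"].sum() == 0
        assert list(table["neighbor_id"]) == [n.id for n in nbs]

    def test_table_totals_match_aggregate_stats(self):
        parent = simulate_parent(1200, seed=13)
        nbs = [
            simulate_neighbor(parent, MutationSpec(substitution_rate=0.13, seed=s))[0]
            for s in range(4)
        ]
        entries, stats, table = condense_species_set(parent, nbs)
        assert table["retained_bp"].sum() == stats.retained_bp
        assert table["entries"].sum() == stats.entries_out == len(entries)
        assert table["length"].sum() == stats.input_bp
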