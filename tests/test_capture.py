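"""Coverage, deduplication, enrichment and contig-recovery metrics."""

import numpy as np
import pytest

from conftest import random_seq
from oracles import depth_oracle
from viropanel.align import Orientation
from viropanel.capture import (
    AlignmentRecord,
    boc_gain,
    contig_recovery,
    coverage_report,
    dedup_by_start,
    enrichment,
    read_alignment_tsv,
    read_sam,
    select_species_reference,
    write_alignment_tsv,
)
from viropanel.errors import ContractError
from viropanel.seqio import Provenance, SequenceRecord, TargetEntry


def _aln(start, end, ref="r", orient=Orientation.FORWARD, q=30, name=None):
    return AlignmentRecord(
        read_id=name or f"rd{start}_{orient.value}",
        ref_id=ref,
        start=start,
        end=end,
        orientation=orient,
        quality=q,
    )


class TestSelectSpeciesReference:
    def test_argmax_within_species(self):
        got = select_species_reference({"A": 500, "B": 800}, {"A": "sp", "B": "sp"})
        assert got == {"sp": "B"}

    def test_tie_breaks_to_lexicographically_smallest(self):
        got = select_species_reference({"B": 500, "A": 500}, {"A": "sp", "B": "sp"})
        assert got == {"sp": "A"}

    def test_random_maps_match_exhaustive_argmax(self, rng):
        refs = [f"ref{i}" for i in range(30)]
        species_of = {r: f"sp{rng.integers(0, 5)}" for r in refs}
        covered = {r: int(rng.integers(0, 1000)) for r in refs}
        got = select_species_reference(covered, species_of)
        for sp, chosen in got.items():
            group = [r for r in refs if species_of[r] == sp]
            best = max(covered[r] for r in group)
            assert covered[chosen] == best
            assert chosen == min(r for r in group if covered[r] == best)


class TestCoverageReport:
    def test_no_alignments_is_one_full_gap(self):
        rep = coverage_report([], "r", 500)
        assert rep.breadth == 0.0
        assert rep.gaps == [500]
        assert rep.median_gap == 500

    def test_full_single_read(self):
        rep = coverage_report([_aln(0, 400)], "r", 400)
        assert rep.breadth == 100.0
        assert rep.gaps == []
        assert rep.max_gap == 0 and rep.median_gap == 0.0

    def test_two_islands_arithmetic(self):
        rep = coverage_report([_aln(0, 100), _aln(200, 300)], "r", 400)
        assert rep.breadth == 50.0
        assert rep.gaps == [100, 100]
        assert rep.median_gap == 100.0 and rep.max_gap == 100

    def test_breadth_and_gaps_conserve_length(self, rng):
        for _ in range(50):
            L = int(rng.integers(50, 400))
            n = int(rng.integers(0, 20))
            alns = []
            for _ in range(n):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, L + 1))
                alns.append(_aln(s, e))
            rep = coverage_report(alns, "r", L)
            covered = L - sum(rep.gaps)
            assert rep.breadth == pytest.approx(100.0 * covered / L)
            depth = depth_oracle(alns, L)
            assert covered == sum(1 for d in depth if d > 0)
            assert rep.mean_depth == pytest.approx(sum(depth) / L)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ContractError):
            coverage_report([_aln(0, 600)], "r", 500)
        with pytest.raises(ContractError):
            coverage_report([_aln(0, 10, ref="other")], "r", 500)


class TestBocGain:
    def test_abstract_medians_example(self):
        pre = coverage_report([_aln(0, 20)], "r", 1000)  # 2.0% breadth
        post = coverage_report([_aln(0, 756)], "r", 1000)  # 75.6% breadth
        assert pre.breadth == pytest.approx(2.0)
        assert post.breadth == pytest.approx(75.6)
        assert boc_gain(pre, post) == pytest.approx(73.6)

    def test_antisymmetry_and_zero(self):
        a = coverage_report([_aln(0, 100)], "r", 400)
        b = coverage_report([_aln(0, 300)], "r", 400)
        assert boc_gain(a, a) == 0.0
        assert boc_gain(a, b) == -boc_gain(b, a)

    def test_reference_mismatch_rejected(self):
        a = coverage_report([], "r1", 100)
        b = coverage_report([], "r2", 100)
        with pytest.raises(ContractError):
            boc_gain(a, b)


class TestDedupByStart:
    def test_highest_quality_wins(self):
        lo = _aln(10, 110, q=20, name="lo")
        hi = _aln(10, 110, q=30, name="hi")
        kept = dedup_by_start([lo, hi])
        assert [a.read_id for a in kept] == ["hi"]

    def test_quality_tie_keeps_first(self):
        first = _aln(10, 110, q=30, name="first")
        second = _aln(10, 110, q=30, name="second")
        assert [a.read_id for a in dedup_by_start([first, second])] == ["first"]

    def test_both_orientations_retained(self):
        f = _aln(10, 110, orient=Orientation.FORWARD)
        r = _aln(10, 110, orient=Orientation.REVERSE)
        assert len(dedup_by_start([f, r])) == 2

    def test_idempotent_and_depth_never_increases(self, rng):
        alns = [
            _aln(int(s), int(s) + 50, q=int(q), name=f"n{i}")
            for i, (s, q) in enumerate(
                zip(rng.integers(0, 200, size=100), rng.integers(0, 60, size=100))
            )
        ]
        once = dedup_by_start(alns)
        assert dedup_by_start(once) == once
        before = depth_oracle(alns, 260)
        after = depth_oracle(once, 260)
        assert all(a <= b for a, b in zip(after, before))


class TestEnrichment:
    def test_median_style_arithmetic(self):
        res = enrichment(10, 1_000_000, 6740, 1_000_000)
        assert res.fold == pytest.approx(674.0)
        assert not res.lower_bound
        assert res.fold_display == "674"

    def test_zero_precapture_renders_lower_bound(self):
        res = enrichment(0, 10**6, 13, 10**6)
        assert res.lower_bound
        assert res.fold == pytest.approx(13.0)
        assert res.fold_display == ">13"

    def test_fold_times_pre_fraction_equals_post_fraction(self, rng):
        for _ in range(30):
            pv = int(rng.integers(1, 1000))
            pt = int(rng.integers(1000, 10**6))
            qv = int(rng.integers(0, 1000))
            qt = int(rng.integers(1000, 10**6))
            res = enrichment(pv, pt, qv, qt)
            assert res.fold * res.pre_fraction == pytest.approx(res.post_fraction)

    def test_scale_invariance(self):
        a = enrichment(7, 1000, 210, 2000)
        b = enrichment(70, 10000, 2100, 20000)
        assert a.fold == pytest.approx(b.fold)

    def test_zero_totals_rejected(self):
        with pytest.raises(ContractError):
            enrichment(0, 0, 5, 10)


class TestContigRecovery:
    def test_contig_copied_from_entry(self, rng):
        res = random_seq(rng, 400)
        panel = [
            TargetEntry(source_id="t", residues=res, provenance=Provenance.PARENT_TILED)
        ]
        contig = SequenceRecord("c", res[50:350])
        alns = [_aln(0, 300, ref="c")]
        ident, breadth = contig_recovery(contig, panel, alns)
        assert ident == pytest.approx(100.0)
        assert breadth == pytest.approx(100.0)

    def test_unrelated_panel_low_identity_no_crash(self, rng):
        panel = [
            TargetEntry(
                source_id="t", residues=random_seq(rng, 300), provenance=Provenance.PARENT_TILED
            )
        ]
        contig = SequenceRecord("c", random_seq(rng, 200))
        ident, breadth = contig_recovery(contig, panel, [])
        assert ident is not None and ident < 80.0
        assert breadth == 0.0

    def test_empty_panel_identity_absent(self, rng):
        contig = SequenceRecord("c", random_seq(rng, 150))
        ident, _ = contig_recovery(contig, [], [])
        assert ident is None

    def test_forty_percent_divergence_recovers_sixty(self, rng):
        """A contig mutated to ~40% divergence from its nearest panel entry
        reports a top-HSP identity near 60%."""
        from conftest import substitute

        res = random_seq(rng, 600)
        panel = [
            TargetEntry(source_id="t", residues=res, provenance=Provenance.PARENT_TILED)
        ]
        pos = rng.choice(600, size=240, replace=False)
        contig = SequenceRecord("c", substitute(res, pos, rng))
        ident, _ = contig_recovery(contig, panel, [])
        assert ident == pytest.approx(60.0, abs=3.0)


class TestAlignmentIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        alns = [
            _aln(int(s), int(s) + 80, orient=o, q=int(q), name=f"r{i}")
            for i, (s, o, q) in enumerate(
                zip(
                    rng.integers(0, 100, size=10),
                    [Orientation.FORWARD, Orientation.REVERSE] * 5,
                    rng.integers(0, 60, size=10),
                )
            )
        ]
        path = tmp_path / "aln.tsv"
        write_alignment_tsv(alns, path)
        assert read_alignment_tsv(path) == alns

    def test_read_sam_keeps_mapped_primary_only(self, tmp_path):
        sam = "\n".join(
            [
                "@HD\tVN:1.6\tSO:unsorted",
                "@SQ\tSN:virus1\tLN:1000",
                # mapped forward read, 100M
                "r1\t0\tvirus1\t11\t60\t100M\t*\t0\t0\t*\t*",
                # mapped reverse read
                "r2\t16\tvirus1\t201\t40\t50M\t*\t0\t0\t*\t*",
                # unmapped (counted in total, not in records)
                "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*",
                # secondary (ignored entirely)
                "r4\t256\tvirus1\t301\t30\t100M\t*\t0\t0\t*\t*",
                # read with a deletion: aligned span covers the deletion
                "r5\t0\tvirus1\t401\t50\t40M10D40M\t*\t0\t0\t*\t*",
                "",
            ]
        )
        path = tmp_path / "in.sam"
        path.write_text(sam)
        records, total = read_sam(path)
        assert total == 4  # r1, r2, r3, r5
        by_id = {r.read_id: r for r in records}
        assert set(by_id) == {"r1", "r2", "r5"}
        assert (by_id["r1"].start, by_id["r1"].end) == (10, 110)
        assert by_id["r2"].orientation is Orientation.REVERSE
        assert (by_id["r5"].start, by_id["r5"].end) == (400, 490)
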