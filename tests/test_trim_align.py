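"""Projection, optimal aligning-region search, MSA, filters, supermatrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aflpcap.insilico_aflp import revcomp
from aflpcap.orthology import OrthologyGroup
from aflpcap.similarity import HitRecord
from aflpcap.synthdata import simulate_genome
from aflpcap.trim_align import (
    GroupRejected,
    MultipleAlignment,
    NoFeasibleWindow,
    ProjectedSpan,
    TrimWindow,
    align_group,
    build_supermatrix,
    filter_low_similarity,
    find_trim_window,
    pairwise_similarity,
    project_members,
    trim_group,
)

from tests._oracles import brute_force_window, nw_global_score


def hit(q, s, qstart, qend, sstart, send, bitscore=300.0):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=98.0,
        aln_len=abs(qend - qstart) + 1, mismatch=1, gapopen=0,
        qstart=qstart, qend=qend, sstart=sstart, send=send,
        evalue=1e-40, bitscore=bitscore,
    )


def group_with(members):
    og = OrthologyGroup(og_id="og0001", reference_id="ref")
    og.members.update(members)
    return og


class TestProjection:
    def test_reference_self_projection(self):
        og = group_with({"reference": ("ref", hit("ref", "ref", 1, 200, 1, 200))})
        spans = project_members(og, {"ref": 200}, 200)
        assert (spans[0].ref_start, spans[0].ref_end) == (0, 200)

    def test_plus_strand_offset_arithmetic(self):
        # member length 150, qstart=11 aligns to sstart=101 -> offset 90
        og = group_with({
            "reference": ("ref", hit("ref", "ref", 1, 240, 1, 240)),
            "s1": ("m1", hit("m1", "ref", 11, 60, 101, 150)),
        })
        spans = {s.sample: s for s in project_members(og, {"ref": 240, "m1": 150}, 240)}
        assert (spans["s1"].ref_start, spans["s1"].ref_end) == (90, 240)
        assert spans["s1"].strand == "+"

    def test_minus_strand_equals_projecting_reverse_complement(self):
        # a minus hit (send < sstart) must give the same span as projecting
        # the reverse-complemented member with flipped query coordinates
        L = 150
        minus = hit("m1", "ref", 11, 60, 150, 101)
        og = group_with({
            "reference": ("ref", hit("ref", "ref", 1, 240, 1, 240)),
            "s1": ("m1", minus),
        })
        spans = {s.sample: s for s in project_members(og, {"ref": 240, "m1": L}, 240)}
        # flipped coordinates: qstart' = L - qend + 1 = 91, sstart' = 101
        flipped = hit("m1", "ref", L - 60 + 1, L - 11 + 1, 101, 150)
        og2 = group_with({
            "reference": ("ref", hit("ref", "ref", 1, 240, 1, 240)),
            "s1": ("m1", flipped),
        })
        spans2 = {s.sample: s for s in project_members(og2, {"ref": 240, "m1": L}, 240)}
        assert (spans["s1"].ref_start, spans["s1"].ref_end) == (
            spans2["s1"].ref_start, spans2["s1"].ref_end,
        )
        assert spans["s1"].strand == "-" and spans2["s1"].strand == "+"

    def test_hit_exceeding_member_length_rejected(self):
        og = group_with({
            "reference": ("ref", hit("ref", "ref", 1, 240, 1, 240)),
            "s1": ("m1", hit("m1", "ref", 11, 160, 101, 250)),
        })
        with pytest.raises(ValueError, match="exceed"):
            project_members(og, {"ref": 240, "m1": 150}, 240)


def spans_of(intervals):
    return [
        ProjectedSpan(f"s{i}", f"m{i}", a, b) for i, (a, b) in enumerate(intervals)
    ]


class TestTrimWindow:
    def test_documented_example(self):
        spans = spans_of([(0, 100), (10, 120), (50, 200), (90, 210)])
        w = find_trim_window(spans, threshold=0.5)
        assert (w.ref_start, w.ref_end) == (10, 200)
        assert w.boundary_coverage_up >= 2 and w.boundary_coverage_down >= 2

    def test_identical_spans(self):
        spans = spans_of([(0, 500)] * 4)
        w = find_trim_window(spans, 0.5)
        assert (w.ref_start, w.ref_end) == (0, 500)

    def test_disjoint_spans_threshold_one_infeasible(self):
        with pytest.raises(NoFeasibleWindow):
            find_trim_window(spans_of([(0, 100), (200, 300)]), 1.0)

    def test_single_span_rejected(self):
        with pytest.raises(GroupRejected):
            find_trim_window(spans_of([(0, 100)]), 0.5)

    @given(
        st.lists(
            st.tuples(st.integers(-50, 300), st.integers(10, 200)),
            min_size=2, max_size=12,
        ),
        st.sampled_from([0.3, 0.5, 0.8, 1.0]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_column_scan(self, raw, threshold):
        intervals = [(a, a + l) for a, l in raw]
        spans = spans_of(intervals)
        expected = brute_force_window(intervals, threshold)
        if expected is None:
            with pytest.raises(NoFeasibleWindow):
                find_trim_window(spans, threshold)
        else:
            w = find_trim_window(spans, threshold)
            assert (w.ref_start, w.ref_end) == expected
            # maximality: no strictly wider window has feasible boundaries
            import math
            k = math.ceil(threshold * len(spans))
            cov = lambda p: sum(1 for s in spans if s.covers(p))
            assert cov(w.ref_start - 1) < k or w.ref_start == min(
                s.ref_start for s in spans
            )
            assert cov(w.ref_end) < k or w.ref_end == max(s.ref_end for s in spans)


class TestTrimGroup:
    def test_window_superset_keeps_everything(self):
        seqs = {"m0": "A" * 100, "m1": "C" * 110}
        spans = [ProjectedSpan("s0", "m0", 0, 100), ProjectedSpan("s1", "m1", 10, 120)]
        window = TrimWindow(0, 120, 2, 2)
        assert trim_group(seqs, spans, window) == seqs

    def test_intersection_maps_to_local_coordinates(self):
        seq = simulate_genome(120, 0.5, 5)
        spans = [ProjectedSpan("s1", "m1", 90, 210), ProjectedSpan("s0", "m0", 10, 200)]
        seqs = {"m1": seq, "m0": "G" * 190}
        window = TrimWindow(10, 200, 2, 2)
        out = trim_group(seqs, spans, window)
        assert out["m1"] == seq[0:110]  # local [0, 110)
        # trimming never lengthens and output is a substring of the input
        for mid, trimmed in out.items():
            assert trimmed in seqs[mid]

    def test_member_outside_window_dropped(self):
        spans = [
            ProjectedSpan("s0", "m0", 200, 300),
            ProjectedSpan("s1", "m1", 0, 50),
        ]
        out = trim_group({"m0": "A" * 100, "m1": "C" * 50}, spans, TrimWindow(200, 300, 1, 1))
        assert set(out) == {"m0"}


class TestAlignGroup:
    def test_identical_sequences_gap_free(self):
        s = simulate_genome(150, 0.5, 8)
        aln = align_group({"a": s, "b": s, "c": s})
        assert aln.length == 150
        assert all("-" not in row for row in aln.rows.values())

    def test_three_base_insertion_creates_gap_columns(self):
        s = simulate_genome(200, 0.5, 9)
        t = s[:100] + "TAG" + s[100:]
        aln = align_group({"a": s, "b": t, "c": s})
        assert aln.length == 203
        assert aln.rows["a"].count("-") == 3 and aln.rows["c"].count("-") == 3
        assert "-" not in aln.rows["b"]
        # pairwise projection of the alignment scores at the global-DP optimum
        score = 0
        for x, y in zip(aln.rows["a"], aln.rows["b"]):
            if x == "-" or y == "-":
                continue
            score += 2 if x == y else -3
        gap_cost = 5 + 3 * 2
        assert score - gap_cost == nw_global_score(s, t, free_end_gaps=False)

    def test_single_sequence_rejected(self):
        with pytest.raises(GroupRejected):
            align_group({"a": "ACGT"})

    def test_row_set_preserved(self):
        seqs = {f"r{i}": simulate_genome(100, 0.5, 10 + i) for i in range(4)}
        aln = align_group(seqs)
        assert set(aln.rows) == set(seqs)
        for name, seq in seqs.items():
            assert aln.rows[name].replace("-", "") == seq


class TestSimilarityFilter:
    def test_identical_rows_kept(self):
        aln = MultipleAlignment({"a": "ACGTACGT", "b": "ACGTACGT"})
        out = filter_low_similarity(aln, 0.30)
        assert set(out.rows) == {"a", "b"}
        assert pairwise_similarity(out.rows["a"], out.rows["b"]) == 1.0

    def test_planted_junk_row_removed(self):
        # a random row sits at ~25% identity per aligned column, below the
        # 30% cutoff; planted directly in the alignment (gap-free columns)
        s = simulate_genome(200, 0.5, 20)
        junk = simulate_genome(200, 0.5, 21)
        aln = MultipleAlignment({"a": s, "b": s, "c": s, "junk": junk})
        out = filter_low_similarity(aln, 0.30, realign=False)
        assert "junk" not in out.rows
        assert set(out.rows) == {"a", "b", "c"}

    def test_row_at_exactly_cutoff_kept(self):
        # c matches exactly 3 of 10 columns of both a and b: mean sim 0.30
        aln = MultipleAlignment({
            "a": "AAAAAAAAAA",
            "b": "AAAAAAAAAA",
            "c": "AAACCCCCCC",
        })
        out = filter_low_similarity(aln, 0.30, realign=False)
        assert "c" in out.rows

    def test_all_rows_removed_rejects_group(self):
        aln = MultipleAlignment({"a": "AAAAAAAAAA", "b": "CCCCCCCCCC"})
        with pytest.raises(GroupRejected):
            filter_low_similarity(aln, 0.30)

    def test_no_shared_columns_zero_similarity(self):
        assert pairwise_similarity("AA--", "--AA") == 0.0


class TestSupermatrix:
    def test_single_full_locus_fully_complete(self):
        aln = MultipleAlignment({"sp1": "ACGT", "sp2": "ACGT", "sp3": "AGGT"})
        sm = build_supermatrix({"og1": aln}, min_taxa=3)
        assert sm.completeness_by_locus == 1.0
        assert sm.completeness_by_characters == 1.0
        assert sm.partitions == [("og1", 1, 4)]

    def test_hand_computed_occupancy_arithmetic(self):
        # 2 loci (100 and 200 cols) x 3 species; sp3 missing the 200-col locus
        rows100 = {sp: "A" * 100 for sp in ("sp1", "sp2", "sp3")}
        rows200 = {sp: "C" * 200 for sp in ("sp1", "sp2")}
        sm = build_supermatrix(
            {"og1": MultipleAlignment(rows100), "og2": MultipleAlignment(rows200)},
            min_taxa=2,
        )
        assert sm.completeness_by_locus == pytest.approx(5 / 6)
        assert sm.completeness_by_characters == pytest.approx((3 * 300 - 200) / (3 * 300))
        assert sm.rows["sp3"] == "A" * 100 + "-" * 200
        assert sm.length == 300

    def test_min_taxa_exclusion(self):
        five = MultipleAlignment({f"sp{i}": "ACGT" for i in range(5)})
        six = MultipleAlignment({f"sp{i}": "TTTT" for i in range(6)})
        sm = build_supermatrix({"small": five, "big": six}, min_taxa=6)
        assert [p[0] for p in sm.partitions] == ["big"]
        with pytest.raises(ValueError):
            build_supermatrix({"small": five}, min_taxa=6)

    def test_partition_tiling_and_row_lengths(self, rng):
        alignments = {}
        for i in range(6):
            n_sp = int(rng.integers(3, 7))
            length = int(rng.integers(10, 80))
            rows = {
                f"sp{j}": simulate_genome(length, 0.5, int(rng.integers(2**31)))
                for j in range(n_sp)
            }
            alignments[f"og{i}"] = MultipleAlignment(rows)
        sm = build_supermatrix(alignments, min_taxa=3)
        # partitions tile [1, total] without overlap
        pos = 1
        for og_id, start, end in sm.partitions:
            assert start == pos
            assert end >= start
            pos = end + 1
        assert pos - 1 == sm.length
        assert sm.length == sum(e - s + 1 for _, s, e in sm.partitions)
        assert all(len(row) == sm.length for row in sm.rows.values())


class TestWriters:
    def test_outputs_are_consistent(self, tmp_path):
        from aflpcap.trim_align import (
            write_partitions_raxml,
            write_supermatrix_fasta,
            write_supermatrix_phylip,
        )

        aln = MultipleAlignment({"sp1": "ACGT", "sp2": "AC-T"})
        sm = build_supermatrix({"og1": aln}, min_taxa=2)
        write_supermatrix_phylip(sm, tmp_path / "m.phy")
        lines = (tmp_path / "m.phy").read_text().splitlines()
        assert lines[0] == "2 4"
        write_partitions_raxml(sm, tmp_path / "m.part")
        assert (tmp_path / "m.part").read_text() == "DNA, og1 = 1-4\n"
        write_supermatrix_fasta(sm, tmp_path / "m.fa")
        assert (tmp_path / "m.fa").read_text() == ">sp1\nACGT\n>sp2\nAC-T\n"
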