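"""Reference/contig/read coloring and color-gap adjustment."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import omguide as og
from omguide.coloring import ColoredFragment, ColoredOpticalMap, ColoredRead
from omguide.formats import PafRecord
from omguide.omalign import AlignmentBlock, OMAlignment


def _maps(counts):
    return [
        og.OpticalMap(f"chr{k}", "XhoI", [1000.0] * n) for k, n in enumerate(counts)
    ]


@pytest.mark.parametrize(
    "counts,s,checks",
    [
        ([3, 2], 10, {("chr0", 0): 0, ("chr0", 2): 2, ("chr1", 0): 10, ("chr1", 1): 11}),
        ([4], 10, {("chr0", 3): 3}),
        ([12, 5], 100, {("chr1", 0): 100, ("chr1", 4): 104}),
        ([9], 10, {}),
        ([10], 100, {}),  # s strictly greater than the max fragment count
    ],
)
def test_reference_color_numbering(counts, s, checks):
    rc = og.assign_reference_colors(_maps(counts))
    assert rc.s == s
    for (chrom, i), color in checks.items():
        assert rc.color(chrom, i) == color
    all_colors = list(rc.all_colors())
    assert len(all_colors) == len(set(all_colors))  # globally unique


def test_reference_coloring_rejects_empty():
    with pytest.raises(ValueError):
        og.assign_reference_colors([])
    with pytest.raises(ValueError):
        og.assign_reference_colors([og.OpticalMap("c", "XhoI", [])])


def _ref_coloring(fragment_lengths):
    """Single-chromosome reference with the given fragment lengths."""
    return og.assign_reference_colors([og.OpticalMap("chr0", "XhoI", fragment_lengths)])


class TestColorContig:
    def test_one_to_one(self):
        rc = _ref_coloring([1.0] * 5 + [9.0])  # fragment 5 has length 9, color 5
        contig = og.OpticalMap("c", "XhoI", [7.0])
        aln = OMAlignment("c", "chr0", "forward", [AlignmentBlock(0, 0, 5, 5)], 1.0)
        out = og.color_contig(contig, aln, rc)
        assert out.fragments == [ColoredFragment(7.0, 5)]

    def test_one_to_many_splits_keeping_proportions(self):
        rc = _ref_coloring([1.0, 1.0, 6.0, 4.0])  # colors 2,3 have lengths 6,4
        contig = og.OpticalMap("c", "XhoI", [12.0])
        aln = OMAlignment("c", "chr0", "forward", [AlignmentBlock(0, 0, 2, 3)], 1.0)
        out = og.color_contig(contig, aln, rc)
        assert [(pytest.approx(f.length), f.color) for f in out.fragments] == [
            (pytest.approx(7.2), 2), (pytest.approx(4.8), 3)
        ]

    def test_many_to_one_merges(self):
        rc = _ref_coloring([1.0] * 8 + [9.0])  # fragment 8, color 8
        contig = og.OpticalMap("c", "XhoI", [3.0, 4.0])
        aln = OMAlignment("c", "chr0", "forward", [AlignmentBlock(0, 1, 8, 8)], 1.0)
        out = og.color_contig(contig, aln, rc)
        assert out.fragments == [ColoredFragment(7.0, 8)]

    def test_many_to_many_and_unaligned_tails(self):
        rc = _ref_coloring([5.0, 3.0, 2.0, 6.0])
        contig = og.OpticalMap("c", "XhoI", [10.0, 4.0, 6.0, 99.0])
        aln = OMAlignment(
            "c", "chr0", "forward", [AlignmentBlock(1, 2, 1, 2)], 1.0
        )
        out = og.color_contig(contig, aln, rc)
        # leading and trailing fragments untouched and uncolored
        assert out.fragments[0] == ColoredFragment(10.0, None)
        assert out.fragments[-1] == ColoredFragment(99.0, None)
        mid = out.fragments[1:3]
        assert [f.color for f in mid] == [1, 2]
        assert sum(f.length for f in mid) == pytest.approx(10.0)
        assert [f.length for f in mid] == [pytest.approx(6.0), pytest.approx(4.0)]

    def test_reverse_orientation_reverses_color_order(self):
        rc = _ref_coloring([5.0, 3.0, 2.0])
        contig = og.OpticalMap("c", "XhoI", [2.0, 3.0, 5.0])
        aln = OMAlignment(
            "c", "chr0", "reverse",
            [AlignmentBlock(0, 0, 0, 0), AlignmentBlock(1, 1, 1, 1),
             AlignmentBlock(2, 2, 2, 2)],
            1.0,
        )
        out = og.color_contig(contig, aln, rc)
        assert [f.color for f in out.fragments] == [2, 1, 0]
        assert [f.length for f in out.fragments] == [2.0, 3.0, 5.0]

    def test_length_conservation_on_random_blocks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ref_lens = list(rng.uniform(500, 20000, size=10))
            rc = _ref_coloring(ref_lens)
            nq = int(rng.integers(1, 7))
            qfrags = list(rng.uniform(500, 20000, size=nq))
            contig = og.OpticalMap("c", "XhoI", qfrags)
            # one random block covering the whole query
            r_from = int(rng.integers(0, 8))
            r_to = int(rng.integers(r_from, 10))
            aln = OMAlignment(
                "c", "chr0", "forward",
                [AlignmentBlock(0, nq - 1, r_from, r_to)], 1.0,
            )
            out = og.color_contig(contig, aln, rc)
            assert out.total_length == pytest.approx(sum(qfrags), rel=1e-9)

    def test_block_out_of_range_errors(self):
        rc = _ref_coloring([5.0])
        contig = og.OpticalMap("c", "XhoI", [5.0])
        aln = OMAlignment("c", "chr0", "forward", [AlignmentBlock(0, 0, 0, 3)], 1.0)
        with pytest.raises(IndexError):
            og.color_contig(contig, aln, rc)


def _rec(qname="r", qlen=100, qstart=0, qend=100, strand="+", tname="c",
         tlen=60, tstart=0, tend=60, nmatch=None, alnlen=None):
    alnlen = alnlen if alnlen is not None else max(qend - qstart, tend - tstart)
    nmatch = nmatch if nmatch is not None else alnlen
    return PafRecord(qname, qlen, qstart, qend, strand, tname, tlen, tstart,
                     tend, nmatch, alnlen, 255)


class TestSelectReadAlignment:
    def test_passing_match_fraction_selects_best(self):
        opts = og.ColoringOptions()
        rec = _rec(nmatch=85, qend=100, tend=60)
        assert og.select_read_alignment([rec], {"c"}, opts) is rec

    def test_below_match_fraction_leaves_uncolored(self):
        opts = og.ColoringOptions()
        rec = _rec(nmatch=70)
        assert og.select_read_alignment([rec], {"c"}, opts) is None

    def test_only_best_discards_uncolored_winner(self):
        opts = og.ColoringOptions()
        win = _rec(tname="dark", nmatch=90)
        lose = _rec(tname="lit", nmatch=85)
        assert og.select_read_alignment([win, lose], {"lit"}, opts) is None

    def test_best_colored_falls_back_to_colored_target(self):
        opts = og.ColoringOptions(selection_mode="best_colored")
        win = _rec(tname="dark", nmatch=90)
        lose = _rec(tname="lit", nmatch=85)
        assert og.select_read_alignment([win, lose], {"lit"}, opts) is lose

    def test_best_hiscoring_requires_fraction_of_read(self):
        opts = og.ColoringOptions(selection_mode="best_hiscoring")
        rec = _rec(tname="lit", nmatch=79)
        assert og.select_read_alignment([rec], {"lit"}, opts) is None
        rec2 = _rec(tname="lit", nmatch=80)
        assert og.select_read_alignment([rec2], {"lit"}, opts) is rec2

    def test_empty_gives_none(self):
        assert og.select_read_alignment([], {"c"}, og.ColoringOptions()) is None


def _colored_contig():
    return ColoredOpticalMap(
        "c", [ColoredFragment(10.0, 100), ColoredFragment(20.0, 101),
              ColoredFragment(30.0, 102)]
    )


class TestColorRead:
    def test_cumulative_lookup(self):
        contig = _colored_contig()
        rec = _rec(qlen=28, qend=28, tstart=12, tend=40, nmatch=28, alnlen=28)
        opts = og.ColoringOptions(extend_tails=False, match_fraction=None)
        assert og.color_read(rec, contig, opts) == ColoredRead("r", 101, 102)

    def test_tail_extension_pulls_start_back(self):
        contig = _colored_contig()
        rec = _rec(qlen=33, qstart=5, qend=33, tstart=12, tend=40, nmatch=28,
                   alnlen=28)
        opts = og.ColoringOptions(extend_tails=True, match_fraction=None)
        assert og.color_read(rec, contig, opts) == ColoredRead("r", 100, 102)

    def test_full_span_gives_first_and_last_colors(self):
        contig = _colored_contig()
        rec = _rec(qlen=60, qend=60, tstart=0, tend=60)
        opts = og.ColoringOptions(match_fraction=None)
        assert og.color_read(rec, contig, opts) == ColoredRead("r", 100, 102)

    def test_uncolored_endpoint_gives_none(self):
        contig = ColoredOpticalMap(
            "c", [ColoredFragment(10.0, None), ColoredFragment(50.0, 101)]
        )
        rec = _rec(qlen=20, qend=20, tstart=2, tend=22)
        opts = og.ColoringOptions(extend_tails=False, match_fraction=None)
        assert og.color_read(rec, contig, opts) is None

    def test_reverse_colored_contig_swaps_interval(self):
        contig = ColoredOpticalMap(
            "c", [ColoredFragment(10.0, 102), ColoredFragment(20.0, 101),
                  ColoredFragment(30.0, 100)]
        )
        rec = _rec(qlen=28, qend=28, tstart=12, tend=40, nmatch=28, alnlen=28)
        opts = og.ColoringOptions(extend_tails=False, match_fraction=None)
        assert og.color_read(rec, contig, opts) == ColoredRead("r", 100, 101)

    def test_wrong_contig_errors(self):
        rec = _rec(tname="other")
        with pytest.raises(ValueError):
            og.color_read(rec, _colored_contig(), og.ColoringOptions())


class TestAdjustColors:
    def test_worked_gap_removal_example(self):
        # used colors {1,2,4,7,8,10} with base 1 remap to consecutive
        # {1,2,3,4,5,6}: 1->1, 2->2, 4->3, 7->4, 8->5, 10->6
        reads = [ColoredRead("a", 1, 2), ColoredRead("b", 4, 4),
                 ColoredRead("c", 7, 8), ColoredRead("d", 10, 10)]
        adjusted, cmap = og.adjust_colors(reads, s=100, base=1)
        assert cmap == {1: 1, 2: 2, 4: 3, 7: 4, 8: 5, 10: 6}
        assert adjusted[-1] == ColoredRead("d", 6, 6)

    def test_no_gaps_is_identity(self):
        reads = [ColoredRead("a", 0, 2), ColoredRead("b", 2, 4)]
        adjusted, cmap = og.adjust_colors(reads, s=10)
        assert cmap == {c: c for c in range(5)}
        assert adjusted == reads

    def test_per_chromosome_blocks_untouched(self):
        reads = [ColoredRead("a", 0, 1), ColoredRead("b", 3, 3),
                 ColoredRead("c", 10, 10), ColoredRead("d", 12, 12)]
        _, cmap = og.adjust_colors(reads, s=10)
        assert cmap == {0: 0, 1: 1, 3: 2, 10: 10, 12: 11}

    def test_spanning_chromosomes_is_an_error(self):
        with pytest.raises(ValueError):
            og.adjust_colors([ColoredRead("a", 9, 10)], s=10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 80), st.integers(0, 15)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1, max_size=20,
        )
    )
    def test_order_preserving_bijection_and_idempotence(self, intervals):
        reads = [
            ColoredRead(f"r{i}", s, e) for i, (s, e) in enumerate(intervals)
        ]
        adjusted, cmap = og.adjust_colors(reads, s=100)
        olds = sorted(cmap)
        news = [cmap[o] for o in olds]
        assert sorted(set(news)) == news  # injective and order preserving
        again, cmap2 = og.adjust_colors(adjusted, s=100)
        assert again == adjusted
        assert all(cmap2[c] == c for c in cmap2)
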