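"""Overlap graph construction, color filtering, propagation and unitigs."""
import itertools

import pytest

import omguide as og
from omguide.assembly import (
    GuidanceParams, OverlapGraph, build_graph, edge_consistent, filter_edges,
    find_unitigs, layout_sequence, propagate_colors,
)
from omguide.formats import PafRecord


def chain_paf(read_lens, overlap, extra=()):
    """PAF records for reads laid consecutively with a fixed exact overlap."""
    recs = []
    pos = [0]
    for L in read_lens[:-1]:
        pos.append(pos[-1] + L - overlap)
    names = [f"r{i}" for i in range(len(read_lens))]
    pairs = list(zip(range(len(names) - 1), range(1, len(names)))) + list(extra)
    for i, j in pairs:
        qs = pos[j] - pos[i]
        span = min(pos[i] + read_lens[i], pos[j] + read_lens[j]) - pos[j]
        if span <= 0:
            continue
        recs.append(
            PafRecord(names[i], read_lens[i], qs, qs + span, "+",
                      names[j], read_lens[j], 0, span, span, span)
        )
    return recs


def graph_from_chain(n=3, length=2000, overlap=1000, colors=None, extra=()):
    recs = chain_paf([length] * n, overlap, extra=extra)
    params = GuidanceParams(min_overlap_bp=100)
    return build_graph(recs, colors, params), params


class TestBuildGraph:
    def test_chain_reduces_to_path(self):
        # chain of 3 with the transitive 0->2 edge present in the input
        g, _ = graph_from_chain(3, overlap=1400, extra=[(0, 2)])
        # brute-force transitive-reduction oracle: an edge is redundant iff a
        # two-edge path reproduces its offset
        assert ("r2", "+") not in g.succ[("r0", "+")]
        assert list(g.succ[("r0", "+")]) == [("r1", "+")]
        assert list(g.succ[("r1", "+")]) == [("r2", "+")]
        # mirror edges present
        assert list(g.succ[("r2", "-")]) == [("r1", "-")]

    def test_chain_offsets_add_up(self):
        g, _ = graph_from_chain(3, overlap=1400, extra=[(0, 2)])
        e01 = g.succ[("r0", "+")][("r1", "+")]
        e12 = g.succ[("r1", "+")][("r2", "+")]
        assert e01.offset == e12.offset == 600
        assert e01.olen == 1400

    def test_contained_read_removed(self):
        big = PafRecord("small", 500, 0, 500, "+", "big", 3000, 1000, 1500, 500, 500)
        dove = chain_paf([2000, 2000], 800)
        g = build_graph(dove + [big], None, GuidanceParams(min_overlap_bp=100))
        assert "small" not in g.read_len
        assert "r0" in g.read_len
        assert "big" in g.read_len and not g.succ[("big", "+")]

    def test_missing_color_leaves_vertex_uncolored(self):
        g, _ = graph_from_chain(3, colors={"r0": (1, 2)})
        assert "r0" in g.colors and "r1" not in g.colors

    def test_short_overlaps_filtered(self):
        recs = chain_paf([2000, 2000], 50)
        g = build_graph(recs, None, GuidanceParams(min_overlap_bp=500))
        assert g.n_edges == 0

    def test_reverse_strand_overlap_orients_vertices(self):
        # suffix of r0 equals suffix of r1 reverse-complemented:
        # r0(+) dovetails into r1(-)
        rec = PafRecord("r0", 2000, 1000, 2000, "-", "r1", 2000, 1000, 2000,
                        1000, 1000)
        g = build_graph([rec], None, GuidanceParams(min_overlap_bp=100))
        assert ("r1", "-") in g.succ[("r0", "+")]
        assert ("r0", "-") in g.succ[("r1", "+")]


class TestFilterEdges:
    @pytest.mark.parametrize(
        "cu,cv,kept",
        [
            ((5, 6), (6, 7), True),   # step 0 exists
            ((5, 6), (8, 9), False),  # min distance 2
            ((7, 8), (5, 6), False),  # reverse color order
            ((5, 5), (6, 6), True),   # step exactly d
        ],
    )
    def test_consistency_rule(self, cu, cv, kept):
        assert edge_consistent(cu, cv, 1) is kept

    def test_filter_removes_inconsistent_and_uncolored(self):
        colors = {"r0": (5, 6), "r1": (8, 9), "r2": (9, 9)}
        g, params = graph_from_chain(4, colors=colors)
        g2 = filter_edges(g, params)
        assert "r3" not in g2.read_len  # uncolored, propagation disabled
        assert ("r1", "+") not in g2.succ[("r0", "+")]  # distance 2
        assert ("r2", "+") in g2.succ[("r1", "+")]

    def test_reverse_order_direction_removed_mirror_kept(self):
        colors = {"r0": (5, 5), "r1": (6, 6)}
        g, params = graph_from_chain(2, colors=colors)
        g2 = filter_edges(g, params)
        assert ("r1", "+") in g2.succ[("r0", "+")]
        assert ("r0", "-") not in g2.succ[("r1", "-")]  # decreasing direction


class TestPropagateColors:
    def _chain(self, colors):
        g, _ = graph_from_chain(3, colors=colors)
        return g

    def test_contiguous_collection_colors_vertex(self):
        g = self._chain({"r0": (3, 4), "r2": (4, 5)})
        g2 = propagate_colors(g, GuidanceParams(propagation_limit=5))
        assert g2.colors["r1"] == (3, 5)

    def test_gap_in_collection_deletes_vertex(self):
        g = self._chain({"r0": (3, 3), "r2": (6, 6)})
        g2 = propagate_colors(g, GuidanceParams(propagation_limit=5))
        assert "r1" not in g2.read_len

    def test_isolated_uncolored_vertex_deleted(self):
        g = OverlapGraph({"lone": 1000, "a": 1000}, {"a": (1, 1)})
        g2 = propagate_colors(g, GuidanceParams(propagation_limit=5))
        assert "lone" not in g2.read_len

    def test_hop_limit_respected(self):
        recs = chain_paf([2000] * 5, 1000)
        g = build_graph(recs, {"r0": (3, 3)}, GuidanceParams(min_overlap_bp=100))
        g2 = propagate_colors(g, GuidanceParams(propagation_limit=1))
        assert g2.colors.get("r1") == (3, 3)
        assert "r3" not in g2.read_len  # two hops away from any color


class TestFindUnitigs:
    def test_clean_chain_is_one_unitig(self):
        g, _ = graph_from_chain(4)
        unitigs = find_unitigs(g)
        assert len(unitigs) == 1
        assert unitigs[0].read_ids == ["r0", "r1", "r2", "r3"]
        assert [r[2] for r in unitigs[0].reads] == [0, 1000, 2000, 3000]

    def test_branch_splits_unitigs(self):
        # r1 has two successors: r2 and the branch read rb
        recs = chain_paf([2000] * 3, 1000)
        recs.append(
            PafRecord("r1", 2000, 1200, 2000, "+", "rb", 2000, 0, 800, 800, 800)
        )
        g = build_graph(recs, None, GuidanceParams(min_overlap_bp=100))
        unitigs = find_unitigs(g)
        read_sets = sorted(tuple(u.read_ids) for u in unitigs)
        assert ("r0", "r1") in read_sets
        assert len(unitigs) == 3  # stem, and the two branch tips

    def test_empty_graph(self):
        assert find_unitigs(OverlapGraph({}, None)) == []

    def test_mirror_paths_not_duplicated(self):
        g, _ = graph_from_chain(5)
        unitigs = find_unitigs(g)
        all_reads = list(itertools.chain.from_iterable(u.read_ids for u in unitigs))
        assert len(all_reads) == len(set(all_reads)) == 5

    def test_rainbow_violation_raises(self):
        colors = {"r0": (5, 5), "r1": (9, 9)}
        g, _ = graph_from_chain(2, colors=colors)
        # deliberately skip filtering: the inconsistent edge must trip the check
        with pytest.raises(AssertionError):
            find_unitigs(g, max_color_step=1)


class TestLayout:
    def test_exact_dovetail(self):
        reads = {"a": "AAACCC", "b": "CCCGGG"}
        u = og.Unitig("u", [("a", "+", 0), ("b", "+", 3)], [3])
        assert layout_sequence(u, reads) == "AAACCCGGG"

    def test_single_read(self):
        u = og.Unitig("u", [("a", "+", 0)], [])
        assert layout_sequence(u, {"a": "ACGT"}) == "ACGT"

    def test_three_reads_half_overlaps(self):
        reads = {f"r{i}": "A" * 100 for i in range(3)}
        u = og.Unitig(
            "u", [("r0", "+", 0), ("r1", "+", 50), ("r2", "+", 100)], [50, 50]
        )
        assert len(layout_sequence(u, reads)) == 200

    def test_reverse_orientation_uses_reverse_complement(self):
        reads = {"a": "AAACCC", "b": "TTTGGG"}  # rc(b) = CCCAAA
        u = og.Unitig("u", [("a", "+", 0), ("b", "-", 3)], [3])
        assert layout_sequence(u, reads) == "AAACCCAAA"

    def test_gap_errors(self):
        u = og.Unitig("u", [("a", "+", 0), ("b", "+", 10)], [1])
        with pytest.raises(ValueError):
            layout_sequence(u, {"a": "AAA", "b": "CCC"})

    def test_length_arithmetic(self):
        g, _ = graph_from_chain(4, length=2000, overlap=700)
        reads = {f"r{i}": "A" * 2000 for i in range(4)}
        (u,) = find_unitigs(g)
        seq = layout_sequence(u, reads)
        assert len(seq) == 4 * 2000 - sum(u.olens)


class TestAssemble:
    def test_uncolored_run_equals_unfiltered_unitigs(self):
        reads = {f"r{i}": "ACGT" * 500 for i in range(3)}
        recs = chain_paf([2000] * 3, 1000)
        params = GuidanceParams(min_overlap_bp=100)
        res = og.assemble(reads, recs, None, params)
        direct = find_unitigs(build_graph(recs, None, params))
        assert [u.read_ids for u in res.unitigs] == [u.read_ids for u in direct]

    def test_unicolored_equals_uncolored(self):
        reads = {f"r{i}": "ACGT" * 500 for i in range(4)}
        recs = chain_paf([2000] * 4, 1000)
        params = GuidanceParams(min_overlap_bp=100)
        plain = og.assemble(reads, recs, None, params)
        uni = og.assemble(reads, recs, {r: (7, 7) for r in reads}, params)
        assert sorted(map(tuple, (u.read_ids for u in plain.unitigs))) == sorted(
            map(tuple, (u.read_ids for u in uni.unitigs))
        )

    def test_guided_removes_spurious_cross_edge(self):
        # two chains with one spurious edge between them; colors sit in
        # different chromosome blocks (step >> d)
        recs = chain_paf([2000] * 6, 1000)
        recs = [r for r in recs if not (r.qname == "r2" and r.tname == "r3")]
        spurious = PafRecord("r2", 2000, 1000, 2000, "+", "r3", 2000, 0, 1000,
                             1000, 1000)
        colors = {f"r{i}": (i, i + 1) for i in range(3)}
        colors.update({f"r{i}": (100 + i, 101 + i) for i in range(3, 6)})
        reads = {f"r{i}": "ACGT" * 500 for i in range(6)}
        params = GuidanceParams(min_overlap_bp=100)
        guided = og.assemble(reads, recs + [spurious], colors, params)
        sets = sorted(tuple(u.read_ids) for u in guided.unitigs)
        assert sets == [("r0", "r1", "r2"), ("r3", "r4", "r5")]
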