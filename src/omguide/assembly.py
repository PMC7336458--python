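"""Colored overlap graph construction and rainbow-path unitig assembly.

The graph follows the standard bidirected assembly-graph convention: each
read contributes two oriented vertices (``(read, '+')`` and ``(read, '-')``)
and every dovetail overlap contributes an edge and its complementary mirror
edge.  Construction follows the miniasm layout recipe: internal matches and
contained reads are dropped, dovetails above the length thresholds are kept,
and transitive edges are reduced.

Guidance uses the reads' color intervals.  An edge (u, v) is *consistent*
when some color of v is equal to, or at most ``max_color_step`` greater
than, some color of u; all other edges — reverse color order or too distant
— are removed.  Consistency is judged per directed edge, so of a mirror pair
only the orientation that travels in increasing-color direction survives
(both survive on equal colors).  Unitigs are maximal non-branching paths of
the filtered graph; by construction every such path is a rainbow path
(non-decreasing colors with bounded steps), which is re-checked at runtime.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional

from .digestion import reverse_complement
from .formats import PafRecord
from .overlap import overlap_reads  # re-exported: part of this module's surface

__all__ = [
    "GuidanceParams", "OverlapGraph", "Unitig", "overlap_reads", "build_graph",
    "filter_edges", "propagate_colors", "find_unitigs", "layout_sequence",
    "assemble", "AssemblyResult", "edge_consistent",
]

logger = logging.getLogger(__name__)


@dataclass
class GuidanceParams:
    """Graph construction and color-guidance parameters.

    max_color_step
        Largest allowed forward color step across an edge (d).
    propagation_limit
        Hop limit for color propagation through uncolored vertices;
        0 disables propagation, in which case uncolored reads are dropped.
    min_overlap_bp / min_overlap_fraction
        Minimum dovetail alignment length, absolute and as a fraction of the
        shorter read.
    max_overhang / overhang_ratio
        Unaligned overhang tolerance when classifying a hit as a dovetail.
    reduction_fuzz
        Offset slack (bp) for transitive edge reduction.
    """

    max_color_step: int = 1
    propagation_limit: int = 0
    min_overlap_bp: int = 500
    min_overlap_fraction: float = 0.0
    max_overhang: int = 1000
    overhang_ratio: float = 0.8
    reduction_fuzz: int = 100

    def __post_init__(self) -> None:
        if self.max_color_step < 0 or self.propagation_limit < 0:
            raise ValueError("max_color_step and propagation_limit must be >= 0")


class Edge(NamedTuple):
    offset: int  # start-to-start distance in layout coordinates
    olen: int    # approximate overlap span in bases


def flip(v):
    return (v[0], "-" if v[1] == "+" else "+")


class OverlapGraph:
    """Directed graph over oriented reads with dovetail edges."""

    def __init__(self, read_lengths: Mapping[str, int], colors=None):
        self.read_len = dict(read_lengths)
        self.colors = dict(colors) if colors else {}
        self.succ: dict = {}
        self.pred: dict = {}
        for read in self.read_len:
            self.add_read(read)

    # -- construction -----------------------------------------------------
    def add_read(self, read: str) -> None:
        for o in "+-":
            self.succ.setdefault((read, o), {})
            self.pred.setdefault((read, o), set())

    def add_overlap(self, u, v, offset: int, olen: int) -> None:
        """Add a dovetail edge u->v and its complement flip(v)->flip(u)."""
        if u[0] == v[0]:
            raise ValueError("self-loops are not allowed")
        if olen <= 0:
            raise ValueError("edge overlap length must be > 0")
        comp_offset = offset + self.read_len[v[0]] - self.read_len[u[0]]
        self._add_edge(u, v, Edge(offset, olen))
        self._add_edge(flip(v), flip(u), Edge(comp_offset, olen))

    def _add_edge(self, u, v, e: Edge) -> None:
        existing = self.succ[u].get(v)
        if existing is not None and existing.olen >= e.olen:
            return
        self.succ[u][v] = e
        self.pred[v].add(u)

    # -- removal ----------------------------------------------------------
    def remove_edge(self, u, v) -> None:
        if v in self.succ.get(u, {}):
            del self.succ[u][v]
            self.pred[v].discard(u)

    def remove_read(self, read: str) -> None:
        for o in "+-":
            v = (read, o)
            for w in list(self.succ.get(v, {})):
                self.remove_edge(v, w)
            for u in list(self.pred.get(v, ())):
                self.remove_edge(u, v)
            self.succ.pop(v, None)
            self.pred.pop(v, None)
        self.read_len.pop(read, None)
        self.colors.pop(read, None)

    # -- queries ----------------------------------------------------------
    def reads(self):
        return list(self.read_len)

    def vertices(self):
        return list(self.succ)

    def edges(self):
        for u, targets in self.succ.items():
            for v, e in targets.items():
                yield u, v, e

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.succ.values())

    def copy(self) -> "OverlapGraph":
        g = OverlapGraph({}, None)
        g.read_len = dict(self.read_len)
        g.colors = dict(self.colors)
        g.succ = {v: dict(t) for v, t in self.succ.items()}
        g.pred = {v: set(p) for v, p in self.pred.items()}
        return g


def edge_consistent(cu, cv, d: int) -> bool:
    """True when some color of the target is 0..d greater than some color of
    the source (the consistent-edge condition).

    A vertex's colors are the full closed interval between its read's start
    and end colors (the start/end pair is a compact encoding of the
    contiguous set of fragments the read overlaps), so the existence test
    ranges over the two intervals: reverse-ordered and too-distant edges are
    removed, overlapping or adjacent intervals are consistent.
    """
    su, eu = min(cu), max(cu)
    sv, ev = min(cv), max(cv)
    return sv <= eu + d and ev >= su


def classify_hit(rec: PafRecord, params: GuidanceParams):
    """Classify a PAF hit: ('internal', None), ('contained', read_id) or
    ('dovetail', u, v, offset, olen) in oriented coordinates."""
    ql, qs, qe = rec.qlen, rec.qstart, rec.qend
    tl = rec.tlen
    if rec.strand == "+":
        ts, te = rec.tstart, rec.tend
    else:
        ts, te = tl - rec.tend, tl - rec.tstart
    bq, eq = qs, ql - qe
    bt, et = ts, tl - te
    maplen = max(qe - qs, rec.tend - rec.tstart)
    if min(bq, bt) + min(eq, et) > min(
        params.max_overhang, maplen * params.overhang_ratio
    ):
        return ("internal", None)
    if bq <= bt and eq <= et:
        return ("contained", rec.qname)
    if bq >= bt and eq >= et:
        return ("contained", rec.tname)
    vq = (rec.qname, "+")
    vt = (rec.tname, rec.strand)
    if bq > bt:
        return ("dovetail", vq, vt, bq - bt, ql - (bq - bt))
    return ("dovetail", vt, vq, bt - bq, tl - (bt - bq))


def build_graph(
    overlaps: Iterable[PafRecord],
    colors=None,
    params: Optional[GuidanceParams] = None,
    read_lengths: Optional[Mapping[str, int]] = None,
) -> OverlapGraph:
    """Miniasm-style graph construction from PAF overlaps.

    Internal matches are dropped, contained reads removed entirely, dovetail
    edges above the thresholds kept (with their mirror complements), and
    transitive edges reduced.  ``colors`` maps read ids to their
    ``(start_color, end_color)``; reads absent from it are uncolored
    vertices.
    """
    if params is None:
        params = GuidanceParams()
    overlaps = list(overlaps)

    lengths: dict = dict(read_lengths) if read_lengths else {}
    usable = []
    for rec in overlaps:
        ok = True
        for name, length in ((rec.qname, rec.qlen), (rec.tname, rec.tlen)):
            known = lengths.get(name)
            if known is None:
                lengths[name] = length
            elif known != length:
                logger.warning(
                    "skipping PAF record %s->%s: contradictory length for %s",
                    rec.qname, rec.tname, name,
                )
                ok = False
        if ok:
            usable.append(rec)

    contained: set = set()
    candidates = []
    seen_reads: set = set()
    for rec in usable:
        if rec.qname == rec.tname:
            continue
        seen_reads.update((rec.qname, rec.tname))
        if rec.alnlen < params.min_overlap_bp:
            continue
        if rec.alnlen < params.min_overlap_fraction * min(rec.qlen, rec.tlen):
            continue
        kind, *info = classify_hit(rec, params)
        if kind == "contained":
            contained.add(info[0])
        elif kind == "dovetail":
            candidates.append(info)

    g = OverlapGraph(
        {r: lengths[r] for r in lengths if r in seen_reads and r not in contained},
        colors,
    )
    for u, v, offset, olen in candidates:
        if u[0] in contained or v[0] in contained:
            continue
        if offset <= 0 or olen <= 0:
            logger.warning("skipping contradictory dovetail %s -> %s", u, v)
            continue
        g.add_overlap(u, v, offset, olen)

    n_before = g.n_edges
    _transitive_reduction(g, params.reduction_fuzz)
    logger.info(
        "graph: %d reads (%d contained removed), %d edges (%d transitive removed)",
        len(g.read_len), len(contained), g.n_edges, n_before - g.n_edges,
    )
    return g


def _transitive_reduction(g: OverlapGraph, fuzz: int) -> None:
    """Remove edges implied by a two-edge path with matching offsets."""
    to_remove: set = set()
    for v, targets in g.succ.items():
        if len(targets) < 2:
            continue
        for w, e1 in targets.items():
            for x, e2 in g.succ.get(w, {}).items():
                if x in targets and x != v and x != w:
                    if abs(e1.offset + e2.offset - targets[x].offset) <= fuzz:
                        to_remove.add((v, x))
    for v, x in to_remove:
        g.remove_edge(v, x)
        g.remove_edge(flip(x), flip(v))


def filter_edges(g: OverlapGraph, params: GuidanceParams) -> OverlapGraph:
    """Remove uncolored vertices and color-inconsistent edges."""
    g2 = g.copy()
    dropped = 0
    for read in g2.reads():
        if read not in g2.colors:
            g2.remove_read(read)
            dropped += 1
    removed = 0
    for u, v, _e in list(g2.edges()):
        if not edge_consistent(g2.colors[u[0]], g2.colors[v[0]], params.max_color_step):
            g2.remove_edge(u, v)
            removed += 1
    logger.info(
        "color filter: %d uncolored reads dropped, %d inconsistent edges removed, "
        "%d edges kept", dropped, removed, g2.n_edges,
    )
    return g2


def propagate_colors(g: OverlapGraph, params: GuidanceParams) -> OverlapGraph:
    """Assign colors to uncolored vertices from nearby colored ones.

    Each uncolored read collects the colors of colored reads reachable
    within ``propagation_limit`` hops through uncolored reads only, in either
    edge direction.  If the union of collected color intervals is contiguous
    the read is colored with its (min, max); otherwise — or if nothing is
    collected — the read is deleted.  Decisions use the original coloring.
    """
    if params.propagation_limit < 1:
        raise ValueError("propagation requires propagation_limit >= 1")
    g2 = g.copy()

    adj: dict = {}
    for u, v, _e in g2.edges():
        adj.setdefault(u[0], set()).add(v[0])
        adj.setdefault(v[0], set()).add(u[0])

    to_delete, to_color = [], {}
    for read in sorted(g2.reads()):
        if read in g2.colors:
            continue
        collected = []
        visited = {read}
        frontier = {read}
        for _hop in range(params.propagation_limit):
            nxt = set()
            for x in frontier:
                for nb in adj.get(x, ()):
                    if nb in visited:
                        continue
                    visited.add(nb)
                    if nb in g2.colors:
                        collected.append(g2.colors[nb])
                    else:
                        nxt.add(nb)
            frontier = nxt
        if not collected:
            to_delete.append(read)
            continue
        intervals = sorted((min(c), max(c)) for c in collected)
        hi = intervals[0][1]
        contiguous = True
        for s, e in intervals[1:]:
            if s > hi + 1:
                contiguous = False
                break
            hi = max(hi, e)
        if contiguous:
            to_color[read] = (intervals[0][0], hi)
        else:
            to_delete.append(read)

    for read in to_delete:
        g2.remove_read(read)
    g2.colors.update(to_color)
    logger.info(
        "propagation: %d uncolored reads colored, %d deleted",
        len(to_color), len(to_delete),
    )
    return g2


@dataclass
class Unitig:
    """A maximal non-branching path, laid out without consensus."""

    name: str
    reads: list  # (read_id, orientation, offset) with strictly increasing offsets
    olens: list  # overlap length at each internal junction
    color_interval: Optional[tuple] = None
    sequence: Optional[str] = None

    def internal_links(self):
        for (a, b, olen) in zip(self.reads, self.reads[1:], self.olens):
            yield (a[0], a[1]), (b[0], b[1]), olen

    @property
    def read_ids(self):
        return [r[0] for r in self.reads]


def find_unitigs(
    g: OverlapGraph, max_color_step: Optional[int] = None
) -> list:
    """Emit maximal non-branching paths as unitigs.

    Paths extend while the next vertex has in-degree 1 and the current
    vertex out-degree 1.  Candidate paths are emitted longest-first and a
    path contributing no new read is suppressed (this removes the mirror
    image of each path that the bidirected construction implies).  When
    ``max_color_step`` is given, every emitted path is asserted to be a
    rainbow path; a violation signals a filtering bug.  Output is ordered by
    smallest read id.
    """
    succ, pred = g.succ, g.pred

    def extendable_back(v) -> bool:
        if len(pred[v]) != 1:
            return False
        (p,) = tuple(pred[v])
        return len(succ[p]) == 1

    paths = []
    assigned: set = set()
    for v in sorted(succ):
        if extendable_back(v):
            continue
        path = [v]
        seen = {v}
        cur = v
        while len(succ[cur]) == 1:
            (w,) = tuple(succ[cur])
            if len(pred[w]) != 1 or w in seen:
                break
            path.append(w)
            seen.add(w)
            cur = w
        paths.append(path)
        assigned.update(path)
    for v in sorted(succ):  # remaining vertices sit on isolated cycles
        if v in assigned:
            continue
        path = [v]
        seen = {v}
        cur = v
        while len(succ[cur]) == 1:
            (w,) = tuple(succ[cur])
            if w in seen:
                break
            path.append(w)
            seen.add(w)
            cur = w
        paths.append(path)
        assigned.update(path)

    unitigs = []
    used_reads: set = set()
    for path in sorted(paths, key=lambda p: (-len(p), p)):
        if all(v[0] in used_reads for v in path):
            continue  # mirror (or mirror fragment) of an emitted path
        used_reads.update(v[0] for v in path)
        if max_color_step is not None:
            for a, b in zip(path, path[1:]):
                ca, cb = g.colors.get(a[0]), g.colors.get(b[0])
                if ca is None or cb is None or not edge_consistent(ca, cb, max_color_step):
                    raise AssertionError(
                        f"non-rainbow path at {a}->{b} (colors {ca}->{cb}): "
                        "edge filtering failed to enforce the rainbow condition"
                    )
        offsets = [0]
        olens = []
        for a, b in zip(path, path[1:]):
            e = succ[a][b]
            offsets.append(offsets[-1] + e.offset)
            olens.append(e.olen)
        colored = [g.colors[v[0]] for v in path if v[0] in g.colors]
        interval = (
            (min(min(c) for c in colored), max(max(c) for c in colored))
            if colored else None
        )
        unitigs.append(
            Unitig(
                name="",
                reads=[(v[0], v[1], off) for v, off in zip(path, offsets)],
                olens=olens,
                color_interval=interval,
            )
        )

    unitigs.sort(key=lambda u: min(u.read_ids))
    for i, u in enumerate(unitigs):
        u.name = f"utg{i + 1:06d}"
    return unitigs


def layout_sequence(unitig: Unitig, reads: Mapping[str, str]) -> str:
    """Layout-only unitig sequence: first oriented read plus each successive
    read's non-overlapping suffix; mismatches resolve in favor of the
    earlier read (no consensus)."""
    parts = []
    end = 0
    for rid, orient, offset in unitig.reads:
        if offset < 0:
            raise ValueError(f"negative offset for read {rid!r} in {unitig.name}")
        seq = reads[rid] if orient == "+" else reverse_complement(reads[rid])
        skip = end - offset
        if skip < 0:
            raise ValueError(
                f"gap before read {rid!r} in {unitig.name}: offsets imply a break"
            )
        if skip < len(seq):
            parts.append(seq[skip:])
            end = offset + len(seq)
    return "".join(parts)


@dataclass
class AssemblyResult:
    unitigs: list
    graph: OverlapGraph
    stats: dict = field(default_factory=dict)


def assemble(
    reads: Mapping[str, str],
    overlaps: Iterable[PafRecord],
    colors=None,
    params: Optional[GuidanceParams] = None,
) -> AssemblyResult:
    """Full (guided or unguided) unitig assembly from reads and overlaps.

    With ``colors=None`` the color-filtering stage is skipped entirely and
    the result is the plain miniasm-style layout assembly.  Otherwise colors
    are optionally propagated, inconsistent edges removed, and rainbow-path
    unitigs emitted.
    """
    if params is None:
        params = GuidanceParams()
    g = build_graph(
        overlaps, colors, params, read_lengths={r: len(s) for r, s in reads.items()}
    )
    stats = {"n_reads_in_graph": len(g.read_len), "n_edges_raw": g.n_edges}
    if colors is not None:
        if params.propagation_limit > 0:
            g = propagate_colors(g, params)
        g = filter_edges(g, params)
        stats["n_edges_filtered"] = g.n_edges
        unitigs = find_unitigs(g, max_color_step=params.max_color_step)
    else:
        unitigs = find_unitigs(g)
    for u in unitigs:
        u.sequence = layout_sequence(u, reads)
    stats["n_unitigs"] = len(unitigs)
    logger.info("assembly: %d unitigs", len(unitigs))
    return AssemblyResult(unitigs=unitigs, graph=g, stats=stats)
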