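"""Coloring of reference fragments, contigs and reads.

Location on the genome-wide optical map is encoded as integer *colors*.
Fragment ``i`` of chromosome ``k`` receives color ``k*s + i``, where ``s``
is the smallest power of ten strictly greater than the largest per-chromosome
fragment count, so every color occurs exactly once genome-wide and the
chromosome is recoverable as ``color // s``.

Contigs inherit colors through their optical-map alignment: each alignment
block's query fragments are replaced by rescaled copies of the matched
reference fragments carrying the reference colors.  Reads inherit a
``(start_color, end_color)`` interval from the colored contig they align to
best, found by accumulating contig fragment lengths over the aligned target
interval.  Finally, colors unused by every read are squeezed out so that the
used colors are consecutive within each chromosome.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import accumulate
from typing import Iterable, NamedTuple, Optional

from .digestion import OpticalMap
from .omalign import OMAlignment

logger = logging.getLogger(__name__)


@dataclass
class ReferenceColoring:
    """Globally unique integer colors for every reference map fragment."""

    chromosome_order: list
    s: int
    fragment_lengths: dict  # map_id -> list of fragment lengths

    def chromosome_index(self, map_id: str) -> int:
        return self.chromosome_order.index(map_id)

    def color(self, map_id: str, frag_index: int) -> int:
        n = len(self.fragment_lengths[map_id])
        if not 0 <= frag_index < n:
            raise IndexError(f"fragment {frag_index} out of range for {map_id!r}")
        return self.chromosome_index(map_id) * self.s + frag_index

    def colors_for(self, map_id: str) -> range:
        k = self.chromosome_index(map_id)
        return range(k * self.s, k * self.s + len(self.fragment_lengths[map_id]))

    def chromosome_of(self, color: int) -> int:
        return color // self.s

    def all_colors(self):
        for map_id in self.chromosome_order:
            yield from self.colors_for(map_id)


def assign_reference_colors(ref_maps: Iterable[OpticalMap]) -> ReferenceColoring:
    """Number reference fragments 0..n-1 per chromosome, offset by k*s."""
    ref_maps = list(ref_maps)
    if not ref_maps:
        raise ValueError("need at least one reference chromosome map")
    for m in ref_maps:
        if len(m.fragments) == 0:
            raise ValueError(f"reference map {m.map_id!r} is empty")
    max_count = max(len(m.fragments) for m in ref_maps)
    s = 1
    while s <= max_count:
        s *= 10
    return ReferenceColoring(
        chromosome_order=[m.map_id for m in ref_maps],
        s=s,
        fragment_lengths={m.map_id: list(m.fragments) for m in ref_maps},
    )


class ColoredFragment(NamedTuple):
    length: float
    color: Optional[int]


@dataclass
class ColoredOpticalMap:
    """An optical map whose fragments carry reference colors (or None)."""

    map_id: str
    fragments: list  # list of ColoredFragment

    @property
    def total_length(self) -> float:
        return sum(f.length for f in self.fragments)

    @property
    def colors(self) -> list:
        return [f.color for f in self.fragments if f.color is not None]


def color_contig(
    contig_map: OpticalMap, aln: OMAlignment, ref_coloring: ReferenceColoring
) -> ColoredOpticalMap:
    """Transfer reference colors onto a contig map through its alignment.

    Per block, the N matched query fragments (total length n) are replaced by
    M new fragments: the M matched reference fragments with lengths rescaled
    by n/m (m = their total reference length), carrying the reference colors.
    Total length is conserved.  Query fragments outside every block keep
    their length and stay uncolored.  Reverse-orientation alignments yield
    colors in decreasing order along the original contig.
    """
    if aln.query_id != contig_map.map_id:
        raise ValueError(
            f"alignment is for {aln.query_id!r}, not contig {contig_map.map_id!r}"
        )
    ref_lens = ref_coloring.fragment_lengths[aln.ref_id]
    qfrags = list(contig_map.fragments)
    if aln.orientation == "reverse":
        qfrags = qfrags[::-1]

    out: list = []
    pos = 0
    for blk in aln.blocks:
        if not (0 <= blk.q_from <= blk.q_to < len(qfrags)):
            raise IndexError(f"block query range out of bounds: {blk}")
        if not (0 <= blk.r_from <= blk.r_to < len(ref_lens)):
            raise IndexError(f"block reference range out of bounds: {blk}")
        if blk.q_from < pos:
            raise ValueError(f"overlapping or out-of-order blocks at {blk}")
        for i in range(pos, blk.q_from):  # unaligned gap: keep, uncolored
            out.append(ColoredFragment(qfrags[i], None))
        n = sum(qfrags[blk.q_from : blk.q_to + 1])
        m = sum(ref_lens[blk.r_from : blk.r_to + 1])
        for u in range(blk.r_from, blk.r_to + 1):
            out.append(
                ColoredFragment(ref_lens[u] / m * n, ref_coloring.color(aln.ref_id, u))
            )
        pos = blk.q_to + 1
    for i in range(pos, len(qfrags)):
        out.append(ColoredFragment(qfrags[i], None))

    if aln.orientation == "reverse":
        out = out[::-1]
    return ColoredOpticalMap(contig_map.map_id, out)


@dataclass
class ColoredRead:
    """A read with its (start_color, end_color) location interval."""

    read_id: str
    start_color: int
    end_color: int

    def __post_init__(self) -> None:
        if self.start_color > self.end_color:
            raise ValueError(
                f"read {self.read_id!r}: start_color > end_color after normalization"
            )


@dataclass
class ColoringOptions:
    """Options controlling how reads inherit colors from contigs.

    selection_mode
        ``only_best``: the globally best alignment by matching bases; the
        read stays uncolored if that alignment's contig is uncolored.
        ``best_colored``: best alignment among colored contigs.
        ``best_hiscoring``: best among colored contigs, required to match at
        least ``match_fraction`` of the read.
    match_fraction
        A selected alignment must match at least this fraction of the whole
        read length or the read is left uncolored (None disables the rule).
    extend_tails
        Extend the aligned contig interval by the read's unaligned tail
        lengths (clamped to the contig).
    adjust_colors
        Squeeze unused colors out after read coloring.
    """

    selection_mode: str = "only_best"
    match_fraction: Optional[float] = 0.8
    extend_tails: bool = True
    adjust_colors: bool = True
    min_s_score: float = 0.0

    def __post_init__(self) -> None:
        if self.selection_mode not in ("only_best", "best_colored", "best_hiscoring"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.match_fraction is not None and not 0 < self.match_fraction <= 1:
            raise ValueError("match_fraction must be in (0, 1]")


def select_read_alignment(records, colored_ids, opts: ColoringOptions):
    """Pick the one alignment used to color a read, or None.

    ``records`` are all PAF records of a single read; ``colored_ids`` the set
    of contig ids that received colors.  Ties on matching bases are broken by
    longer alignment, then lexicographic target name.
    """
    records = list(records)
    if not records:
        return None
    key = lambda r: (-r.nmatch, -r.alnlen, r.tname)

    if opts.selection_mode == "only_best":
        best = min(records, key=key)
        if best.tname not in colored_ids:
            return None
    else:
        colored = [r for r in records if r.tname in colored_ids]
        if not colored:
            return None
        best = min(colored, key=key)
        if opts.selection_mode == "best_hiscoring":
            t = opts.match_fraction if opts.match_fraction is not None else 0.8
            if best.nmatch < t * best.qlen:
                return None
    if opts.match_fraction is not None and best.nmatch < opts.match_fraction * best.qlen:
        return None
    return best


def color_read(rec, contig: ColoredOpticalMap, opts: ColoringOptions):
    """Color one read from its alignment to a colored contig, or None.

    The aligned contig interval is ``[tstart, tend)``; with tail extension it
    becomes ``[tstart - qstart, tend + (qlen - qend))`` clamped to the
    contig.  The start (end) color is the color of the first fragment whose
    cumulative length strictly exceeds the interval start (end); an endpoint
    past the last cumulative sum takes the last fragment.  If either endpoint
    lands on an uncolored fragment the read stays uncolored.  Colors are
    swapped if the contig was colored in reverse, so start <= end.
    """
    if rec.tname != contig.map_id:
        raise ValueError(f"record targets {rec.tname!r}, not contig {contig.map_id!r}")
    total = contig.total_length
    i, j = float(rec.tstart), float(rec.tend)
    if i < 0 or j > rec.tlen or i >= j:
        raise ValueError(f"alignment interval [{i}, {j}) outside [0, {rec.tlen}]")
    if opts.extend_tails:
        a = rec.qstart
        b = rec.qlen - rec.qend
        i = max(0.0, i - a)
        j = min(float(total), j + b)

    cum = list(accumulate(f.length for f in contig.fragments))

    def frag_at(pos: float) -> int:
        for idx, c in enumerate(cum):
            if c > pos:
                return idx
        return len(cum) - 1

    start = contig.fragments[frag_at(i)].color
    end = contig.fragments[frag_at(j)].color
    if start is None or end is None:
        logger.debug(
            "read %s endpoint on uncolored fragment of %s; left uncolored",
            rec.qname, contig.map_id,
        )
        return None
    if start > end:
        start, end = end, start
    return ColoredRead(rec.qname, start, end)


def adjust_colors(
    colored_reads,
    ref_coloring: Optional[ReferenceColoring] = None,
    *,
    s: Optional[int] = None,
    base: int = 0,
):
    """Remap used colors onto consecutive integers per chromosome.

    Every color in a read's ``[start, end]`` interval counts as used.  The
    used colors of chromosome ``k`` are remapped, order preserved, onto
    ``k*s + base, k*s + base + 1, ...``; the ``k*s`` term is untouched.
    Returns ``(recolored reads, color_map)`` where the color map is an
    order-preserving bijection on the used colors.  A read whose interval
    spans two chromosomes' color blocks is an error.
    """
    if ref_coloring is not None:
        s = ref_coloring.s
    if s is None or s <= 0:
        raise ValueError("need a positive chromosome color spacing s")
    reads = list(colored_reads)
    used_by_chrom: dict = {}
    for r in reads:
        if r.start_color // s != r.end_color // s:
            raise ValueError(
                f"read {r.read_id!r} spans two chromosomes' color blocks "
                f"({r.start_color}..{r.end_color}, s={s})"
            )
        k = r.start_color // s
        used_by_chrom.setdefault(k, set()).update(
            range(r.start_color, r.end_color + 1)
        )
    color_map: dict = {}
    for k, used in used_by_chrom.items():
        for rank, old in enumerate(sorted(used)):
            color_map[old] = k * s + base + rank
    recolored = [
        ColoredRead(r.read_id, color_map[r.start_color], color_map[r.end_color])
        for r in reads
    ]
    n_moved = sum(1 for old, new in color_map.items() if old != new)
    logger.info(
        "color adjustment: %d used colors, %d shifted", len(color_map), n_moved
    )
    return recolored, color_map
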