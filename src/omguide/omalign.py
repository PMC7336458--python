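"""Optical map alignment by block dynamic programming.

Aligns an in silico digested contig map to a genome-wide reference map.  The
alignment is a monotone correspondence between *blocks* of fragments: a block
matches ``N`` consecutive query fragments against ``M`` consecutive
reference fragments (each side bounded by ``max_block_span``), which models
restriction-digestion errors — a cut missing from the query merges reference
fragments (M > 1), a spurious cut splits them (N > 1).

Each block is scored as

    match_bonus - ((q_kb - r_kb) / (sizing_sd_per_kb * sqrt(r_kb)))^2
                - missed_cut_penalty * (M - 1) - false_cut_penalty * (N - 1)

i.e. a fixed reward per matched cut pair minus a squared sizing deviation
normalized by the expected measurement spread of a fragment of that size,
minus per-fragment penalties for merged cuts.  The total over blocks is the
alignment's s-score: higher is better, and a perfect fragment-by-fragment
identity alignment is maximal for its query.  The query is consumed globally
(every fragment in some block) while the reference is matched locally; both
query orientations are tried.

The first and last blocks of a multi-block alignment may be forgiven a query
deficit (``fit_ends``): a contig's terminal fragments are truncated pieces of
the reference fragments they land in, so only a query *excess* is penalized
there.  Single-block alignments carry no internal matched cut and get no
forgiveness.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from .digestion import OpticalMap

logger = logging.getLogger(__name__)

_NEG = float("-inf")


@dataclass
class OMScoringParams:
    """Scoring parameters for optical map alignment.

    sizing_sd_per_kb
        Expected sizing standard deviation of a 1 kb fragment, in kb; the
        spread of an r-kb fragment is taken as ``sizing_sd_per_kb*sqrt(r)``.
    missed_cut_penalty / false_cut_penalty
        Cost per reference fragment merged into a block beyond the first /
        per query fragment merged beyond the first.
    match_bonus
        Reward per block (one matched cut pair).
    max_block_span
        Maximum fragments merged on either side of a block.
    min_s_score
        Alignments scoring below this are discarded (default 0: every
        placement with a non-negative score is used).
    """

    sizing_sd_per_kb: float = 0.75
    missed_cut_penalty: float = 3.0
    false_cut_penalty: float = 3.0
    match_bonus: float = 3.0
    max_block_span: int = 3
    min_s_score: float = 0.0
    fit_ends: bool = True
    min_frag_kb: float = 0.05

    def __post_init__(self) -> None:
        if self.sizing_sd_per_kb <= 0:
            raise ValueError("sizing_sd_per_kb must be > 0")
        if self.missed_cut_penalty < 0 or self.false_cut_penalty < 0:
            raise ValueError("cut penalties must be >= 0")
        if self.max_block_span < 1:
            raise ValueError("max_block_span must be >= 1")


@dataclass(frozen=True)
class AlignmentBlock:
    """Inclusive fragment index ranges matched as one block."""

    q_from: int
    q_to: int
    r_from: int
    r_to: int

    def __post_init__(self) -> None:
        if self.q_from > self.q_to or self.r_from > self.r_to:
            raise ValueError("alignment block ranges must be non-empty")


@dataclass
class OMAlignment:
    """A scored monotone block correspondence between two optical maps.

    For ``orientation == 'reverse'`` the block query indices refer to the
    reversed query fragment list; fragment ``i`` of the reversed list is
    fragment ``len(query)-1-i`` of the original map.
    """

    query_id: str
    ref_id: str
    orientation: str
    blocks: list
    s_score: float


def block_score(
    q_sum: float,
    r_sum: float,
    n_query: int,
    n_ref: int,
    params: OMScoringParams,
    end_forgive: bool = False,
) -> float:
    """Score one block; shared by the DP and by brute-force enumeration."""
    q_kb = q_sum / 1000.0
    r_kb = r_sum / 1000.0
    denom = params.sizing_sd_per_kb * math.sqrt(max(r_kb, params.min_frag_kb))
    diff = q_kb - r_kb
    if end_forgive and diff < 0:
        sizing = 0.0
    else:
        sizing = (diff / denom) ** 2
    return (
        params.match_bonus
        - sizing
        - params.missed_cut_penalty * (n_ref - 1)
        - params.false_cut_penalty * (n_query - 1)
    )


def _dp(qfrags, rfrags, params: OMScoringParams):
    """Global-query / local-reference block DP.

    Returns ``(score, blocks)`` for the best decomposition, or None when the
    query is empty.  ``S[i][j]`` is the best score of an alignment consuming
    query fragments ``[0, i)`` whose last block ends at reference cut ``j``.
    """
    nq, nr = len(qfrags), len(rfrags)
    if nq == 0 or nr == 0:
        return None
    span = params.max_block_span
    qcum = [0.0] * (nq + 1)
    for i, f in enumerate(qfrags):
        qcum[i + 1] = qcum[i] + f
    rcum = [0.0] * (nr + 1)
    for j, f in enumerate(rfrags):
        rcum[j + 1] = rcum[j] + f

    S = [[_NEG] * (nr + 1) for _ in range(nq + 1)]
    back: dict = {}
    for j in range(nr + 1):
        S[0][j] = 0.0
    for i in range(1, nq + 1):
        row = S[i]
        for j in range(1, nr + 1):
            best = _NEG
            best_ab = None
            for a in range(1, min(span, i) + 1):
                prev_row = S[i - a]
                first = i - a == 0
                last = i == nq
                forgive = params.fit_ends and (first or last) and not (first and last)
                for b in range(1, min(span, j) + 1):
                    prev = prev_row[j - b]
                    if prev == _NEG:
                        continue
                    sc = prev + block_score(
                        qcum[i] - qcum[i - a],
                        rcum[j] - rcum[j - b],
                        a,
                        b,
                        params,
                        end_forgive=forgive,
                    )
                    if sc > best:
                        best = sc
                        best_ab = (a, b)
            row[j] = best
            if best_ab is not None:
                back[(i, j)] = best_ab

    best_j, best_score = None, _NEG
    for j in range(1, nr + 1):
        if S[nq][j] > best_score:
            best_score = S[nq][j]
            best_j = j
    if best_j is None:
        return None

    blocks = []
    i, j = nq, best_j
    while i > 0:
        a, b = back[(i, j)]
        blocks.append(AlignmentBlock(i - a, i - 1, j - b, j - 1))
        i, j = i - a, j - b
    blocks.reverse()
    return best_score, blocks


def align_map(
    query: OpticalMap, ref: OpticalMap, params: Optional[OMScoringParams] = None
) -> Optional[OMAlignment]:
    """Best global-query / local-reference alignment, or None below threshold.

    Both query orientations are tried (reverse = reversed fragment list);
    ties prefer forward orientation, then the leftmost reference placement.
    """
    if params is None:
        params = OMScoringParams()
    for m in (query, ref):
        if len(m.fragments) == 0:
            raise ValueError(f"map {m.map_id!r} is empty")
        if any(f <= 0 for f in m.fragments):
            raise ValueError(f"map {m.map_id!r} has a non-positive fragment")

    best = None
    for orientation, qfrags in (
        ("forward", query.fragments),
        ("reverse", list(reversed(query.fragments))),
    ):
        res = _dp(qfrags, ref.fragments, params)
        if res is None:
            continue
        score, blocks = res
        key = (-score, 0 if orientation == "forward" else 1, blocks[0].r_from)
        if best is None or key < best[0]:
            best = (key, OMAlignment(query.map_id, ref.map_id, orientation, blocks, score))
    if best is None or best[1].s_score < params.min_s_score:
        return None
    return best[1]


def place_contigs(
    contig_maps, ref_maps, params: Optional[OMScoringParams] = None
) -> dict:
    """Place each contig map on its best reference chromosome.

    Returns ``{contig_id: OMAlignment}``; contigs whose best score falls
    below ``min_s_score`` are absent.  At most one placement per contig; ties
    between equal-scoring placements are broken by lowest reference id, then
    leftmost reference start, then forward orientation.
    """
    if params is None:
        params = OMScoringParams()
    ids = [m.map_id for m in contig_maps]
    if len(set(ids)) != len(ids):
        raise ValueError("contig map ids must be unique")
    rids = [m.map_id for m in ref_maps]
    if len(set(rids)) != len(rids):
        raise ValueError("reference map ids must be unique")

    placements: dict = {}
    for cm in contig_maps:
        best = None
        for rm in ref_maps:
            aln = align_map(cm, rm, params)
            if aln is None:
                continue
            key = (
                -aln.s_score,
                aln.ref_id,
                aln.blocks[0].r_from,
                0 if aln.orientation == "forward" else 1,
            )
            if best is None or key < best[0]:
                best = (key, aln)
        if best is not None:
            placements[cm.map_id] = best[1]
    logger.info("placed %d/%d contig maps", len(placements), len(contig_maps))
    return placements
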