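"""Built-in overlapper and read-to-contig mapper.

A deliberately simple exact-seed engine adequate for low-error reads: shared
fixed-length k-mers (canonicalized over both strands, deterministically
subsampled) vote for candidate read pairs and a relative diagonal; each
candidate is then verified by a banded edit-distance alignment (edlib) over
the implied overlap region and reported as a PAF record.  For real,
high-error reads the PAF input path (any external overlapper, e.g. minimap2)
is the canonical route; this module keeps the pipeline self-contained.
"""
from __future__ import annotations

import logging
from statistics import median_low
from typing import Mapping

import edlib
import numpy as np

from .digestion import reverse_complement
from .formats import PafRecord

logger = logging.getLogger(__name__)

_MIX = np.uint64(0x9E3779B97F4A7C15)

_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_profile(seq: str, k: int):
    """Canonical k-mer codes and strand flags for every position.

    Returns ``(canon, is_forward)`` arrays of length ``len(seq)-k+1``;
    ``is_forward[i]`` is True when the forward k-mer is the canonical one.
    """
    a = _encode(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        col = a[j : j + n].astype(np.uint64)
        fwd |= col << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - col) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon, fwd <= rev


def _sampled_positions(canon: np.ndarray, window: int) -> np.ndarray:
    """Deterministic 1/window subsample by a multiplicative hash."""
    if window <= 1:
        return np.arange(len(canon))
    mixed = canon * _MIX  # uint64 wrap-around is the intended mixing
    return np.flatnonzero(mixed % np.uint64(window) == 0)


def _verify(
    pattern: str, text: str, max_divergence: float
):
    """Banded infix alignment; returns (edit_distance, start, end_excl) or None."""
    if not pattern or not text:
        return None
    res = edlib.align(
        pattern, text, mode="HW", task="locations",
        k=max(1, int(max_divergence * len(pattern))),
    )
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1


def overlap_reads(
    reads: Mapping[str, str],
    *,
    k: int = 15,
    window: int = 5,
    min_seed_hits: int = 4,
    min_overlap_bp: int = 500,
    max_divergence: float = 0.15,
    max_bucket: int = 1000,
) -> list:
    """All-vs-all overlap detection, one PAF record per ordered pair found.

    Dovetail and containment overlaps are both reported (downstream graph
    construction classifies them); internal repeat matches that fail the
    banded verification are not.  Deterministic given the input read order.
    """
    ids = list(reads)
    if len(ids) < 2:
        raise ValueError("need at least two reads to overlap")
    seqs = [reads[i].upper() for i in ids]

    index: dict = {}
    for ri, seq in enumerate(seqs):
        canon, is_fwd = kmer_profile(seq, k)
        for pos in _sampled_positions(canon, window):
            index.setdefault(int(canon[pos]), []).append(
                (ri, int(pos), bool(is_fwd[pos]))
            )

    votes: dict = {}
    for occ in index.values():
        if len(occ) < 2 or len(occ) > max_bucket:
            continue
        for x in range(len(occ)):
            ri, pi, si = occ[x]
            for y in range(x + 1, len(occ)):
                rj, pj, sj = occ[y]
                if ri == rj:
                    continue
                rel = "+" if si == sj else "-"
                diag = pi - pj if rel == "+" else pi + pj
                votes.setdefault((ri, rj, rel), []).append(diag)

    records = []
    for (ri, rj, rel) in sorted(votes):
        diags = votes[(ri, rj, rel)]
        if len(diags) < min_seed_hits:
            continue
        a, b = seqs[ri], seqs[rj]
        la, lb = len(a), len(b)
        if rel == "+":
            b_oriented = b
            d = median_low(diags)
        else:
            b_oriented = reverse_complement(b)
            d = median_low(diags) - lb + k
        # A position p corresponds to oriented-B position p - d.
        qs0, qe0 = max(d, 0), min(la, d + lb)
        if qe0 - qs0 < min_overlap_bp:
            continue
        pattern = a[qs0:qe0]
        margin = 50 + len(pattern) // 20
        w0 = max(0, qs0 - d - margin)
        w1 = min(lb, qe0 - d + margin)
        hit = _verify(pattern, b_oriented[w0:w1], max_divergence)
        if hit is None:
            continue
        ed, tb, te = hit
        tb_abs, te_abs = tb + w0, te + w0
        if rel == "+":
            tstart, tend = tb_abs, te_abs
        else:
            tstart, tend = lb - te_abs, lb - tb_abs
        alnlen = max(len(pattern), te_abs - tb_abs)
        records.append(
            PafRecord(
                qname=ids[ri], qlen=la, qstart=qs0, qend=qe0, strand=rel,
                tname=ids[rj], tlen=lb, tstart=tstart, tend=tend,
                nmatch=max(0, alnlen - ed), alnlen=alnlen, mapq=255,
            )
        )
    logger.info(
        "overlapper: %d reads, %d candidate pairs, %d verified overlaps",
        len(ids), len(votes), len(records),
    )
    return records


def map_reads(
    reads: Mapping[str, str],
    contigs: Mapping[str, str],
    *,
    k: int = 15,
    window: int = 5,
    min_seed_hits: int = 3,
    max_candidates: int = 4,
    min_span: int = 200,
    max_divergence: float = 0.25,
) -> list:
    """Map each read onto the contigs; PAF records (read = query).

    Up to ``max_candidates`` (contig, strand) candidates per read, ranked by
    seed votes, are verified; reads hanging off a contig end are trimmed to
    the overlapping part so their unaligned tails appear as PAF clips.
    """
    cids = list(contigs)
    index: dict = {}
    for ci, cid in enumerate(cids):
        canon, is_fwd = kmer_profile(contigs[cid].upper(), k)
        for pos in _sampled_positions(canon, window):
            index.setdefault(int(canon[pos]), []).append(
                (ci, int(pos), bool(is_fwd[pos]))
            )

    records = []
    for rid, seq in reads.items():
        seq = seq.upper()
        lr = len(seq)
        canon, is_fwd = kmer_profile(seq, k)
        votes: dict = {}
        for pos in _sampled_positions(canon, window):
            for ci, cpos, cfwd in index.get(int(canon[pos]), ()):
                rel = "+" if bool(is_fwd[pos]) == cfwd else "-"
                rp = pos if rel == "+" else lr - pos - k
                votes.setdefault((ci, rel), []).append(cpos - rp)
        ranked = sorted(
            (key for key, ds in votes.items() if len(ds) >= min_seed_hits),
            key=lambda key: (-len(votes[key]), key),
        )
        for ci, rel in ranked[:max_candidates]:
            contig = contigs[cids[ci]].upper()
            lc = len(contig)
            d = median_low(votes[(ci, rel)])
            cs0, ce0 = max(0, d), min(lc, d + lr)
            ps0, pe0 = cs0 - d, ce0 - d
            if pe0 - ps0 < min_span:
                continue
            oriented = seq if rel == "+" else reverse_complement(seq)
            pattern = oriented[ps0:pe0]
            margin = 50 + len(pattern) // 20
            w0 = max(0, cs0 - margin)
            w1 = min(lc, ce0 + margin)
            hit = _verify(pattern, contig[w0:w1], max_divergence)
            if hit is None:
                continue
            ed, tb, te = hit
            if rel == "+":
                qs, qe = ps0, pe0
            else:
                qs, qe = lr - pe0, lr - ps0
            alnlen = max(len(pattern), te - tb)
            records.append(
                PafRecord(
                    qname=rid, qlen=lr, qstart=qs, qend=qe, strand=rel,
                    tname=cids[ci], tlen=lc, tstart=tb + w0, tend=te + w0,
                    nmatch=max(0, alnlen - ed), alnlen=alnlen, mapq=255,
                )
            )
    logger.info("mapped %d reads -> %d alignments", len(reads), len(records))
    return records
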