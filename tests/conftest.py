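"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import math

import numpy as np
import pytest

import omguide as og
from omguide.omalign import block_score


@pytest.fixture(scope="session")
def xhoi():
    return og.XHOI


def naive_cut_positions(seq: str, enzyme) -> list:
    """O(n*m) substring-scan oracle for restriction cut boundaries."""
    cuts = []
    m = enzyme.motif
    for i in range(len(seq) - len(m) + 1):
        if seq[i : i + len(m)] == m:
            b = i + enzyme.cut_offset
            if 0 < b < len(seq):
                cuts.append(b)
    return sorted(set(cuts))


def brute_force_om_score(query, ref, params) -> float:
    """Exhaustive enumeration of all monotone block decompositions.

    Independent of the DP: recursively splits the query into consecutive
    blocks mapped to consecutive reference blocks from every possible
    reference start, in both orientations, sharing only the block scoring
    function with the implementation.
    """
    span = params.max_block_span
    rfrags = ref.fragments
    nr = len(rfrags)
    best = [-math.inf]

    def recurse(qfrags, qi, rj, score):
        nq = len(qfrags)
        if qi == nq:
            if score > best[0]:
                best[0] = score
            return
        for a in range(1, min(span, nq - qi) + 1):
            first = qi == 0
            last = qi + a == nq
            forgive = params.fit_ends and (first or last) and not (first and last)
            qsum = sum(qfrags[qi : qi + a])
            for b in range(1, min(span, nr - rj) + 1):
                rsum = sum(rfrags[rj : rj + b])
                s = block_score(qsum, rsum, a, b, params, end_forgive=forgive)
                recurse(qfrags, qi + a, rj + b, score + s)

    for qfrags in (query.fragments, list(reversed(query.fragments))):
        for start_j in range(nr):
            recurse(qfrags, 0, start_j, 0.0)
    return best[0]


def random_map(rng: np.random.Generator, n_frags: int, map_id="m") -> og.OpticalMap:
    frags = [float(x) for x in rng.uniform(500, 20000, size=n_frags)]
    return og.OpticalMap(map_id, "XhoI", frags)


@pytest.fixture(scope="session")
def small_pipeline():
    """One small end-to-end run (2 x 60 kb, 15x) shared across tests."""
    cfg = og.SimulationConfig(
        seed=1, n_chromosomes=2, chromosome_length=60_000, coverage=15,
        read_length_mean=5000, read_length_sd=1500,
    )
    genome = og.simulate_genome(cfg)
    reads_l, truth = og.simulate_reads(genome, cfg)
    reads = dict(reads_l)
    ref_maps = [og.digest(seq, cfg.enzyme, map_id=name) for name, seq in genome]
    result = og.run_pipeline(reads, ref_maps)
    return {
        "cfg": cfg,
        "genome": genome,
        "reads": reads,
        "truth": {t.read_id: t for t in truth},
        "ref_maps": ref_maps,
        "result": result,
    }
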