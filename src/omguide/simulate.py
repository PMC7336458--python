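"""Synthetic genomes, long reads with ground truth, and optical-map noise.

The generator emulates the study conditions of a small-genome guided
assembly experiment: a multi-chromosome random genome with restriction sites
planted at exponential spacing, long reads drawn to a target coverage with
log-normal lengths and low per-base error rates (as after error correction),
and genome-wide in silico optical maps, optionally perturbed with sizing
noise, missed cuts and false cuts.  Every operation is a pure function of
its inputs and the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .digestion import RestrictionEnzyme, XHOI, OpticalMap, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data generator.

    Defaults model two 150 kb chromosomes with XhoI sites every ~2.5 kb on
    average, 20x coverage of ~8 kb reads (log-normal), and 0.5% total
    per-base error split between mismatches and indels — the regime of
    error-corrected long reads.  Map noise defaults to zero (error-free in
    silico maps).  ``repeat_length`` > 0 plants an exact copy of a segment
    of the first chromosome into the second, creating spurious
    cross-chromosome overlaps.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 150_000
    site_density: float = 1.0 / 2500.0  # expected cut sites per bp
    coverage: float = 20.0
    read_length_mean: float = 8000.0
    read_length_sd: float = 2500.0
    min_read_length: int = 500
    error_mismatch: float = 0.003
    error_insertion: float = 0.001
    error_deletion: float = 0.001
    map_sizing_sd: float = 0.0       # relative sd of fragment sizing noise
    map_missing_cut_prob: float = 0.0
    map_false_cut_per_kb: float = 0.0
    repeat_length: int = 0
    repeat_position_frac: float = 0.4
    enzyme_name: str = "XhoI"
    enzyme_motif: str = "CTCGAG"
    enzyme_cut_offset: int = 1

    def __post_init__(self) -> None:
        for name in ("error_mismatch", "error_insertion", "error_deletion",
                     "map_missing_cut_prob"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.chromosome_length <= 0 or self.read_length_mean <= 0:
            raise ValueError("lengths must be > 0")

    @property
    def enzyme(self) -> RestrictionEnzyme:
        return RestrictionEnzyme(
            self.enzyme_name, self.enzyme_motif, self.enzyme_cut_offset
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class ReadTruth:
    """Ground-truth placement of a simulated read (0-based, half-open)."""

    read_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid truth interval for {self.read_id!r}")


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _erase_motif(arr: np.ndarray, motif: str) -> None:
    """Mutate the middle base of every motif occurrence until none remain."""
    seq_motif = np.frombuffer(motif.encode(), dtype=np.uint8)
    m = len(seq_motif)
    while True:
        s = arr.tobytes().decode("ascii")
        pos = s.find(motif)
        if pos == -1:
            return
        mid = pos + m // 2
        cur = arr[mid]
        arr[mid] = _BASES[(int(np.where(_BASES == cur)[0][0]) + 1) % 4]


def simulate_genome(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Generate ``[(chromosome_id, sequence), ...]``.

    Background sequence is uniform random with accidental enzyme motifs
    erased, then motifs are planted at exponential spacing with mean
    ``1/site_density``, so the spacing of cut sites is controlled.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    motif = cfg.enzyme.motif
    if cfg.site_density > 0 and 1.0 / cfg.site_density < 2 * len(motif):
        raise ValueError("site_density too high: motifs cannot fit")
    chroms = []
    for k in range(cfg.n_chromosomes):
        arr = _random_dna(rng, cfg.chromosome_length)
        _erase_motif(arr, motif)
        if cfg.site_density > 0:
            pos = 0.0
            motif_arr = np.frombuffer(motif.encode(), dtype=np.uint8)
            while True:
                pos += rng.exponential(1.0 / cfg.site_density)
                p = int(pos)
                if p + len(motif) >= cfg.chromosome_length:
                    break
                arr[p : p + len(motif)] = motif_arr
        chroms.append([f"chr{k}", arr])

    if cfg.repeat_length > 0 and cfg.n_chromosomes >= 2:
        src = chroms[0][1]
        dst = chroms[1][1]
        L = cfg.repeat_length
        if L >= min(len(src), len(dst)) // 2:
            raise ValueError("repeat_length too large for the chromosomes")
        s0 = int(cfg.repeat_position_frac * (len(src) - L))
        d0 = int((1.0 - cfg.repeat_position_frac) * (len(dst) - L))
        dst[d0 : d0 + L] = src[s0 : s0 + L]

    return [(name, arr.tobytes().decode("ascii")) for name, arr in chroms]


def _apply_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Substitutions first, then indels, at uniform positions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if cfg.error_mismatch > 0:
        mask = rng.random(n) < cfg.error_mismatch
        idx = np.flatnonzero(mask)
        if len(idx):
            # shift each base to a uniformly chosen different one
            codes = np.searchsorted(_BASES, arr[idx])
            arr[idx] = _BASES[(codes + rng.integers(1, 4, size=len(idx))) % 4]
    if cfg.error_deletion > 0 or cfg.error_insertion > 0:
        keep = rng.random(n) >= cfg.error_deletion
        ins_mask = rng.random(n) < cfg.error_insertion
        pieces = []
        kept = arr[keep]
        ins_pos = np.flatnonzero(ins_mask)
        if len(ins_pos) == 0:
            arr = kept
        else:
            ins_bases = _BASES[rng.integers(0, 4, size=len(ins_pos))]
            # map insertion positions into the kept sequence
            kept_cum = np.cumsum(keep) - 1
            out = []
            prev = 0
            for p, b in zip(ins_pos, ins_bases):
                at = int(kept_cum[p]) + 1
                out.append(kept[prev:at])
                out.append(np.array([b], dtype=np.uint8))
                prev = at
            out.append(kept[prev:])
            arr = np.concatenate(out)
    return arr.tobytes().decode("ascii")


def simulate_reads(genome, cfg: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Draw reads to the target coverage; returns (reads, truth table).

    ``genome`` is ``[(chrom_id, sequence), ...]``.  Reads are sampled with
    log-normal lengths, uniform starts, random strand; truth records the
    exact sampled interval before errors are applied.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if not genome:
        raise ValueError("genome is empty")
    names = [g[0] for g in genome]
    seqs = [g[1] for g in genome]
    lengths = np.array([len(s) for s in seqs], dtype=float)
    probs = lengths / lengths.sum()
    target = cfg.coverage * lengths.sum()

    mean, sd = cfg.read_length_mean, cfg.read_length_sd
    sigma2 = float(np.log1p((sd / mean) ** 2))
    mu = float(np.log(mean) - sigma2 / 2.0)

    reads = []
    truths = []
    total = 0.0
    i = 0
    while total < target:
        ci = int(rng.choice(len(seqs), p=probs))
        L = int(rng.lognormal(mu, np.sqrt(sigma2)))
        L = max(cfg.min_read_length, L)
        if L > len(seqs[ci]):
            continue  # resample
        start = int(rng.integers(0, len(seqs[ci]) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seqs[ci][start : start + L]
        if strand == "-":
            frag = reverse_complement(frag)
        rid = f"read{i:05d}"
        reads.append((rid, _apply_errors(frag, cfg, rng)))
        truths.append(ReadTruth(rid, names[ci], start, start + L, strand))
        total += L
        i += 1
    return reads, truths


def perturb_map(
    om: OpticalMap, cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> OpticalMap:
    """Apply optical-map noise: false cuts (splits), missed cuts (merges),
    then multiplicative sizing noise.  With all noise at zero the map is
    returned unchanged (fragment identity preserved)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    frags = list(om.fragments)
    if (
        cfg.map_false_cut_per_kb == 0
        and cfg.map_missing_cut_prob == 0
        and cfg.map_sizing_sd == 0
    ):
        return OpticalMap(om.map_id, om.enzyme, frags)

    if cfg.map_false_cut_per_kb > 0:
        out = []
        for f in frags:
            n_extra = int(rng.poisson(cfg.map_false_cut_per_kb * f / 1000.0))
            if n_extra == 0:
                out.append(f)
                continue
            cuts = np.sort(rng.uniform(0, f, size=n_extra))
            bounds = np.concatenate(([0.0], cuts, [f]))
            out.extend(float(b - a) for a, b in zip(bounds, bounds[1:]) if b > a)
        frags = out

    if cfg.map_missing_cut_prob > 0 and len(frags) > 1:
        out = [frags[0]]
        for f in frags[1:]:
            if rng.random() < cfg.map_missing_cut_prob:
                out[-1] += f
            else:
                out.append(f)
        frags = out

    if cfg.map_sizing_sd > 0:
        frags = [
            max(1e-6, f * float(rng.normal(1.0, cfg.map_sizing_sd))) for f in frags
        ]

    return OpticalMap(om.map_id, om.enzyme, frags)
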