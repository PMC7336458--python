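"""In silico restriction digestion of DNA sequences into optical maps.

An optical map is the ordered list of fragment lengths obtained by cutting a
DNA molecule at every occurrence of a restriction enzyme's recognition motif.
For a sequence whose bases are known, the map is computed exactly: find every
motif occurrence, cut at the enzyme's fixed offset within the motif, and
measure the lengths between consecutive cuts (including both sequence ends).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by its recognition motif and cut offset.

    ``cut_offset`` is the number of bases after the motif start after which
    the cut occurs.  XhoI recognizes CTCGAG and cuts after the first C
    (C^TCGAG), hence ``cut_offset=1``: the cut boundary for a motif starting
    at position ``p`` falls between ``p + cut_offset - 1`` and
    ``p + cut_offset``.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"motif must be at least 4 bases, got {self.motif!r}")
        if not set(self.motif) <= set("ACGT"):
            raise ValueError(f"motif must be over ACGT, got {self.motif!r}")
        if not 0 <= self.cut_offset < len(self.motif):
            raise ValueError(
                f"cut_offset must be in [0, {len(self.motif)}), got {self.cut_offset}"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.motif) == self.motif


XHOI = RestrictionEnzyme("XhoI", "CTCGAG", 1)

ENZYMES = {XHOI.name: XHOI}


@dataclass
class OpticalMap:
    """Ordered fragment lengths of one molecule, chromosome or contig.

    Lengths are in base pairs for in silico digests (where they sum exactly
    to the source sequence length); real-valued lengths are permitted for
    perturbed maps.
    """

    map_id: str
    enzyme: str
    fragments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fragments = list(self.fragments)
        if any(f <= 0 for f in self.fragments):
            raise ValueError(f"map {self.map_id!r}: all fragment lengths must be > 0")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def total_length(self) -> float:
        return sum(self.fragments)


def find_cut_positions(
    sequence: str, enzyme: RestrictionEnzyme, both_strands: bool = False
) -> list:
    """Locate cut boundaries (0-based; a boundary b cuts between b-1 and b).

    Overlapping motif occurrences all yield a cut; duplicate boundaries are
    merged.  N never matches a motif base.  With ``both_strands`` the reverse
    strand is scanned too and its cut positions are merged in (for XhoI the
    motif is its own reverse complement, so this is redundant).
    """
    cuts: set = set()
    n = len(sequence)
    motifs = [(enzyme.motif, enzyme.cut_offset)]
    if both_strands and not enzyme.is_palindromic:
        # A reverse-strand site at forward position q cuts the duplex at the
        # mirrored offset from the motif end.
        motifs.append(
            (reverse_complement(enzyme.motif), len(enzyme.motif) - enzyme.cut_offset)
        )
    for motif, offset in motifs:
        start = sequence.find(motif)
        while start != -1:
            b = start + offset
            if 0 < b < n:
                cuts.add(b)
            start = sequence.find(motif, start + 1)
    return sorted(cuts)


def digest(
    sequence: str,
    enzyme: RestrictionEnzyme,
    map_id: str = "map",
    both_strands: bool = False,
) -> OpticalMap:
    """Digest a DNA sequence into an optical map.

    The fragment lengths are the gaps between consecutive cut boundaries,
    including both sequence ends, in 5'→3' order; their sum equals the
    sequence length.  A sequence containing no motif yields a single
    fragment.  An empty sequence is an error.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    sequence = sequence.upper()
    if not set(sequence) <= _VALID_BASES:
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"sequence contains invalid characters: {bad}")
    cuts = find_cut_positions(sequence, enzyme, both_strands=both_strands)
    bounds = [0] + cuts + [len(sequence)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return OpticalMap(map_id=map_id, enzyme=enzyme.name, fragments=fragments)


def digest_genome(
    records: Iterable,
    enzyme: RestrictionEnzyme,
    both_strands: bool = False,
) -> list:
    """Digest every record of a (multi-)FASTA into one optical map each.

    ``records`` may be a path to a FASTA file, an open handle, or an iterable
    of ``(id, sequence)`` pairs / Biopython SeqRecords.  Record order is
    preserved and ``map_id`` is the record id.  Duplicate ids are an error.
    """
    maps = []
    seen: set = set()
    for rec_id, seq in _iter_sequences(records):
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA record id: {rec_id!r}")
        seen.add(rec_id)
        maps.append(digest(seq, enzyme, map_id=rec_id, both_strands=both_strands))
    return maps


def _iter_sequences(source):
    """Yield (id, sequence) pairs from a path, handle, or pair iterable."""
    from Bio import SeqIO  # local import keeps module import light

    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        for rec in SeqIO.parse(source, "fasta"):
            yield rec.id, str(rec.seq)
        return
    for item in source:
        if hasattr(item, "seq") and hasattr(item, "id"):
            yield item.id, str(item.seq)
        else:
            rec_id, seq = item
            yield rec_id, str(seq)
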