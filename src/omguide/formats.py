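"""Readers and writers for the pipeline's interchange formats.

All on-disk formats are plain text: FASTA (sequences), a canonical optical
map format (plus a TSV dialect), PAF (alignments, minimap2's 12 mandatory
columns), TSV tables for colored reads and color maps, an alignment TSV for
optical-map placements, and GFA 1.0 for assembly graphs.  Every writer's
output round-trips through its reader.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

from .digestion import OpticalMap


def _open(path_or_handle, mode="r"):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source) -> dict:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    from Bio import SeqIO

    out: dict = {}
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record id: {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records, dest, width: int = 80) -> None:
    """Write ``{id: sequence}`` (or pairs) to FASTA."""
    handle, close = _open(dest, "w")
    try:
        items = records.items() if hasattr(records, "items") else records
        for rec_id, seq in items:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Optical map format
#
#   >map_id enzyme
#   frag frag frag ...
# ---------------------------------------------------------------------------

def _format_length(x) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_maps(maps: Iterable[OpticalMap], dest) -> None:
    handle, close = _open(dest, "w")
    try:
        for m in maps:
            handle.write(f">{m.map_id} {m.enzyme}\n")
            handle.write(" ".join(_format_length(f) for f in m.fragments) + "\n")
    finally:
        if close:
            handle.close()


def read_maps(source) -> list:
    handle, close = _open(source)
    try:
        maps = []
        header = None
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()
                if len(header) != 2:
                    raise ValueError(f"malformed map header: {line!r}")
            else:
                if header is None:
                    raise ValueError("map fragment line before any header")
                frags = [float(x) for x in line.split()]
                maps.append(OpticalMap(header[0], header[1], frags))
                header = None
        return maps
    finally:
        if close:
            handle.close()


def write_maps_tsv(maps: Iterable[OpticalMap], dest) -> None:
    """TSV dialect: map_id, enzyme, comma-joined fragment lengths."""
    handle, close = _open(dest, "w")
    try:
        for m in maps:
            frags = ",".join(_format_length(f) for f in m.fragments)
            handle.write(f"{m.map_id}\t{m.enzyme}\t{frags}\n")
    finally:
        if close:
            handle.close()


def read_maps_tsv(source) -> list:
    handle, close = _open(source)
    try:
        maps = []
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            map_id, enzyme, frags = line.split("\t")
            maps.append(OpticalMap(map_id, enzyme, [float(x) for x in frags.split(",")]))
        return maps
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# PAF (minimap2 dialect, 12 mandatory columns; tags ignored on input)
# ---------------------------------------------------------------------------

@dataclass
class PafRecord:
    """One pairwise alignment in PAF coordinates (0-based, half-open)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"invalid query interval in PAF record {self.qname!r}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"invalid target interval in PAF record {self.qname!r}")
        if self.nmatch > self.alnlen:
            raise ValueError(f"nmatch > alnlen in PAF record {self.qname!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.qname, self.qlen, self.qstart, self.qend, self.strand,
                self.tname, self.tlen, self.tstart, self.tend,
                self.nmatch, self.alnlen, self.mapq,
            )
        )

    @classmethod
    def from_line(cls, line: str) -> "PafRecord":
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ValueError(f"PAF line has {len(f)} fields, expected >= 12")
        return cls(
            f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
            f[5], int(f[6]), int(f[7]), int(f[8]),
            int(f[9]), int(f[10]), int(f[11]),
        )


def read_paf(source) -> list:
    handle, close = _open(source)
    try:
        return [PafRecord.from_line(l) for l in handle if l.strip()]
    finally:
        if close:
            handle.close()


def write_paf(records: Iterable[PafRecord], dest) -> None:
    handle, close = _open(dest, "w")
    try:
        for rec in records:
            handle.write(rec.to_line() + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Colored optical maps
#
#   >map_id
#   length:color length:color ...     ('-' marks an uncolored fragment)
# ---------------------------------------------------------------------------

def write_colored_maps(maps, dest) -> None:
    handle, close = _open(dest, "w")
    try:
        for m in maps:
            handle.write(f">{m.map_id}\n")
            handle.write(
                " ".join(
                    f"{_format_length(f.length)}:{'-' if f.color is None else f.color}"
                    for f in m.fragments
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_colored_maps(source) -> list:
    from .coloring import ColoredFragment, ColoredOpticalMap

    handle, close = _open(source)
    try:
        out = []
        map_id = None
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                map_id = line[1:].split()[0]
            else:
                if map_id is None:
                    raise ValueError("colored map fragment line before any header")
                frags = []
                for tok in line.split():
                    length, color = tok.rsplit(":", 1)
                    frags.append(
                        ColoredFragment(
                            float(length), None if color == "-" else int(color)
                        )
                    )
                out.append(ColoredOpticalMap(map_id, frags))
                map_id = None
        return out
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Colored reads / color maps
# ---------------------------------------------------------------------------

def write_colored_reads(reads, dest) -> None:
    """Write colored reads as ``read_id<TAB>start<TAB>end`` (uncolored omitted)."""
    handle, close = _open(dest, "w")
    try:
        for r in reads:
            handle.write(f"{r.read_id}\t{r.start_color}\t{r.end_color}\n")
    finally:
        if close:
            handle.close()


def read_colored_reads(source) -> list:
    from .coloring import ColoredRead

    handle, close = _open(source)
    try:
        out = []
        for line in handle:
            if not line.strip():
                continue
            rid, s, e = line.rstrip("\n").split("\t")
            out.append(ColoredRead(rid, int(s), int(e)))
        return out
    finally:
        if close:
            handle.close()


def write_color_map(color_map: dict, dest) -> None:
    handle, close = _open(dest, "w")
    try:
        for old in sorted(color_map):
            handle.write(f"{old}\t{color_map[old]}\n")
    finally:
        if close:
            handle.close()


def read_color_map(source) -> dict:
    handle, close = _open(source)
    try:
        out = {}
        for line in handle:
            if not line.strip():
                continue
            old, new = line.split()
            out[int(old)] = int(new)
        return out
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Optical map alignment TSV
# ---------------------------------------------------------------------------

def write_alignments(alignments, dest) -> None:
    """Write OMAlignments: query_id, ref_id, orientation, s_score, blocks.

    Blocks are semicolon-joined ``qf-qt:rf-rt`` inclusive index ranges.
    """
    handle, close = _open(dest, "w")
    try:
        items = alignments.values() if hasattr(alignments, "values") else alignments
        for a in items:
            blocks = ";".join(
                f"{b.q_from}-{b.q_to}:{b.r_from}-{b.r_to}" for b in a.blocks
            )
            handle.write(
                f"{a.query_id}\t{a.ref_id}\t{a.orientation}\t{a.s_score:.6g}\t{blocks}\n"
            )
    finally:
        if close:
            handle.close()


def read_alignments(source) -> list:
    from .omalign import AlignmentBlock, OMAlignment

    handle, close = _open(source)
    try:
        out = []
        for line in handle:
            if not line.strip():
                continue
            qid, rid, orient, score, blocks_s = line.rstrip("\n").split("\t")
            blocks = []
            for part in blocks_s.split(";"):
                q, r = part.split(":")
                qf, qt = (int(x) for x in q.split("-"))
                rf, rt = (int(x) for x in r.split("-"))
                blocks.append(AlignmentBlock(qf, qt, rf, rt))
            out.append(OMAlignment(qid, rid, orient, blocks, float(score)))
        return out
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def write_gfa(unitigs, dest) -> None:
    """Write unitigs as GFA 1.0: S lines with sequences, L lines between
    consecutive reads of each unitig with the overlap as ``<n>M``."""
    handle, close = _open(dest, "w")
    try:
        handle.write("H\tVN:Z:1.0\n")
        for u in unitigs:
            seq = u.sequence if u.sequence is not None else "*"
            handle.write(f"S\t{u.name}\t{seq}\tLN:i:{len(seq) if seq != '*' else 0}\n")
        for u in unitigs:
            for (a, b, olen) in u.internal_links():
                handle.write(
                    f"L\t{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{olen}M\n"
                )
    finally:
        if close:
            handle.close()


def read_gfa(source):
    """Parse GFA 1.0 into (segments: {name: seq}, links: [(a, ao, b, bo, olen)])."""
    handle, close = _open(source)
    try:
        segments: dict = {}
        links = []
        for line in handle:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "S":
                segments[f[1]] = f[2]
            elif f[0] == "L":
                olen = int(f[5][:-1]) if f[5].endswith("M") else 0
                links.append((f[1], f[2], f[3], f[4], olen))
        return segments, links
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Read ground-truth table (simulator output)
# ---------------------------------------------------------------------------

def write_truth(truths, dest) -> None:
    handle, close = _open(dest, "w")
    try:
        handle.write("read_id\tchromosome\tstart\tend\tstrand\n")
        for t in truths:
            handle.write(f"{t.read_id}\t{t.chromosome}\t{t.start}\t{t.end}\t{t.strand}\n")
    finally:
        if close:
            handle.close()


def read_truth(source) -> list:
    from .simulate import ReadTruth

    handle, close = _open(source)
    try:
        out = []
        for i, line in enumerate(handle):
            if i == 0 or not line.strip():
                continue
            rid, chrom, s, e, strand = line.rstrip("\n").split("\t")
            out.append(ReadTruth(rid, chrom, int(s), int(e), strand))
        return out
    finally:
        if close:
            handle.close()
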