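"""End-to-end guided assembly workflow.

The pipeline composes the stages: all-vs-all read overlapping → unguided
(pre-coloring) unitig assembly → in silico digestion of the contigs →
optical-map placement on the genome-wide reference map → contig coloring →
read-to-contig mapping and read coloring (with optional tail extension and
color-gap adjustment) → color-guided (post-coloring) unitig assembly.  The
unguided assembly is both the source of the contigs used for coloring and
the baseline the guided assembly is compared against.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .assembly import AssemblyResult, GuidanceParams, assemble
from .coloring import (
    ColoringOptions,
    adjust_colors,
    assign_reference_colors,
    color_contig,
    color_read,
    select_read_alignment,
)
from .digestion import RestrictionEnzyme, XHOI, digest
from .omalign import OMScoringParams, place_contigs
from .overlap import map_reads, overlap_reads

logger = logging.getLogger(__name__)

#: spacing between per-contig colors in the unicolored control run; anything
#: larger than the color-step threshold separates contigs completely.
UNICOLOR_SPACING = 10


@dataclass
class PipelineResult:
    overlaps: list
    pre_assembly: AssemblyResult
    contigs: dict
    contig_maps: list
    placements: dict
    ref_coloring: object
    colored_contigs: dict
    read_alignments: list
    colored_reads: list
    color_map: Optional[dict]
    read_colors: dict
    post_assembly: AssemblyResult
    stats: dict = field(default_factory=dict)


def run_pipeline(
    reads: Mapping[str, str],
    ref_maps,
    enzyme: RestrictionEnzyme = XHOI,
    om_params: Optional[OMScoringParams] = None,
    coloring_opts: Optional[ColoringOptions] = None,
    guidance: Optional[GuidanceParams] = None,
    coloring_mode: str = "normal",
    overlaps=None,
) -> PipelineResult:
    """Run the full guided assembly.

    ``coloring_mode='unicolored'`` replaces the optical-map coloring with
    one flat color per contig (the control experiment separating the effect
    of dropping unaligned reads from the effect of genuine location
    information).  Precomputed ``overlaps`` may be passed to reuse them
    across runs.
    """
    if om_params is None:
        om_params = OMScoringParams()
    if coloring_opts is None:
        coloring_opts = ColoringOptions()
    if guidance is None:
        guidance = GuidanceParams()
    if coloring_mode not in ("normal", "unicolored"):
        raise ValueError(f"unknown coloring_mode {coloring_mode!r}")

    if overlaps is None:
        overlaps = overlap_reads(
            reads, min_overlap_bp=guidance.min_overlap_bp
        )
    logger.info("pipeline: %d reads, %d overlap records", len(reads), len(overlaps))

    pre = assemble(reads, overlaps, None, guidance)
    contigs = {u.name: u.sequence for u in pre.unitigs}
    logger.info("pre-coloring assembly: %d contigs", len(contigs))

    contig_maps = [digest(seq, enzyme, map_id=name) for name, seq in contigs.items()]
    om = replace(om_params, min_s_score=coloring_opts.min_s_score)
    placements = place_contigs(contig_maps, ref_maps, om)

    ref_coloring = assign_reference_colors(ref_maps)
    colored_contigs = {
        cm.map_id: color_contig(cm, placements[cm.map_id], ref_coloring)
        for cm in contig_maps
        if cm.map_id in placements
    }
    logger.info(
        "contig coloring: %d/%d contigs placed and colored",
        len(colored_contigs), len(contig_maps),
    )

    read_paf = map_reads(reads, contigs)
    by_read: dict = {}
    for rec in read_paf:
        by_read.setdefault(rec.qname, []).append(rec)

    colored_reads = []
    color_map = None
    if coloring_mode == "unicolored":
        contig_color = {name: i * UNICOLOR_SPACING for i, name in enumerate(contigs)}
        from .coloring import ColoredRead

        for rid in reads:
            rec = select_read_alignment(
                by_read.get(rid, []), set(contigs), coloring_opts
            )
            if rec is not None:
                c = contig_color[rec.tname]
                colored_reads.append(ColoredRead(rid, c, c))
        final_reads = colored_reads
    else:
        for rid in reads:
            rec = select_read_alignment(
                by_read.get(rid, []), set(colored_contigs), coloring_opts
            )
            if rec is None:
                continue
            cr = color_read(rec, colored_contigs[rec.tname], coloring_opts)
            if cr is not None:
                colored_reads.append(cr)
        if coloring_opts.adjust_colors and colored_reads:
            final_reads, color_map = adjust_colors(colored_reads, ref_coloring)
        else:
            final_reads = colored_reads
    logger.info(
        "read coloring: %d/%d reads colored", len(final_reads), len(reads)
    )

    read_colors = {r.read_id: (r.start_color, r.end_color) for r in final_reads}
    post = assemble(reads, overlaps, read_colors, guidance)
    logger.info(
        "post-coloring assembly: %d unitigs (unguided: %d)",
        len(post.unitigs), len(pre.unitigs),
    )

    stats = {
        "n_reads": len(reads),
        "n_overlaps": len(overlaps),
        "n_pre_unitigs": len(pre.unitigs),
        "n_contigs_placed": len(colored_contigs),
        "n_contigs": len(contig_maps),
        "n_reads_colored": len(final_reads),
        "n_post_unitigs": len(post.unitigs),
    }
    return PipelineResult(
        overlaps=overlaps,
        pre_assembly=pre,
        contigs=contigs,
        contig_maps=contig_maps,
        placements=placements,
        ref_coloring=ref_coloring,
        colored_contigs=colored_contigs,
        read_alignments=read_paf,
        colored_reads=colored_reads,
        color_map=color_map,
        read_colors=read_colors,
        post_assembly=post,
        stats=stats,
    )
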