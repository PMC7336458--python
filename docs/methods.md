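# Methods

This note documents the models and procedures implemented in `omguide`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
show.

## In silico digestion

A restriction enzyme is a recognition motif plus a cut offset: the cut
falls after `cut_offset` bases of the motif (XhoI: `CTCGAG`, offset 1,
i.e. C^TCGAG). Digestion scans the forward strand for every (possibly
overlapping) motif occurrence, cuts at `motif_start + cut_offset`, and
reports the inter-cut fragment lengths including both sequence ends, so
fragment lengths always sum to the sequence length. `N` never matches a
motif base. XhoI's motif is its own reverse complement, so forward-only
scanning is lossless; for non-palindromic enzymes `both_strands=True`
merges the mirrored cut positions of reverse-strand sites. Cuts that would
produce an empty terminal fragment are discarded, and duplicate cut
positions are merged, keeping every fragment length positive.

## Optical map alignment

Contig maps are aligned to chromosome maps by dynamic programming over
*blocks*: `N` consecutive query fragments matched against `M` consecutive
reference fragments, `N, M ≤ max_block_span` (default 3). Merging models
digestion errors — a cut missing from one side merges fragments on the
other. The block score is

```
match_bonus − ((q − r) / (sizing_sd_per_kb · √r))² − missed_cut_penalty·(M−1) − false_cut_penalty·(N−1)
```

with `q`, `r` the summed block lengths in kb. The sizing term is a squared
deviation normalized by the expected spread of a fragment of size `r`
(`σ ∝ √length` is the usual sizing-error model for fragment measurement);
`min_frag_kb` (0.05) floors the denominator so sub-50 bp fragments do not
dominate. The per-block `match_bonus` (default 3) makes the score grow
with the number of matched cut pairs, so "higher is better" and a perfect
fragment-by-fragment alignment is the maximum attainable for its query;
without it every score would be ≤ 0 and a positive acceptance threshold
would be meaningless. Defaults (`sizing_sd_per_kb` 0.75, penalties 3.0)
were chosen once so that one missed/false cut costs about as much as one
matched pair gains, and a 2-sigma sizing error costs roughly a bonus.
Numerical agreement with any external aligner's score scale is not a goal;
the contract is the ordering.

The query is consumed globally (every fragment lies in some block), the
reference is matched locally, and both query orientations are tried
(reverse = reversed fragment list; block indices then refer to the
reversed list). Because a contig's terminal fragments are truncated pieces
of the reference fragments they land in, the first and last blocks of a
multi-block alignment are forgiven a query *deficit* (`fit_ends`): only
`q > r` is penalized there. Single-block alignments contain no matched
interior cut and get no forgiveness — this keeps one-fragment contigs from
being trivially placeable anywhere. Placement takes the best alignment
over all chromosomes and orientations, at most one per contig, discarded
below `min_s_score` (default 0, i.e. every non-negative placement is
used); ties break deterministically by lowest reference id, leftmost
reference start, forward orientation. The search was validated against
exhaustive enumeration of all monotone block decompositions on random map
pairs of up to 6 fragments.

## Coloring

Reference fragment `i` of chromosome `k` gets color `k·s + i`, with `s`
the smallest power of ten strictly greater than the largest fragment count
— colors are globally unique, ordered within chromosomes, and the
chromosome is recoverable as `color // s`.

Contig coloring replaces, per alignment block, the `N` query fragments
(total length `n`) by the `M` matched reference fragments rescaled by
`n/m`, carrying the reference colors; this covers all four block shapes
(one/many to one/many) with a single rule and conserves contig length
exactly (validated to 1e-9 relative). Fragments outside every block keep
their lengths and stay uncolored. Reverse placements yield colors in
decreasing order along the contig.

Read coloring selects one contig alignment per read — by default the
globally best one by matching bases, left uncolored if its contig is
uncolored (`only_best`; `best_colored` and `best_hiscoring` are the
alternatives) — and additionally requires the matching bases to reach
`match_fraction` (default 0.8) of the whole read length. The aligned
contig interval `[i, j)`, optionally extended by the read's unaligned tail
lengths (`i−a`, `j+b`, clamped to the contig — colors cannot extend past
existing fragments), is converted to colors by cumulative-length lookup:
the start (end) color is that of the first fragment whose cumulative
length *strictly* exceeds `i` (`j`); a boundary coordinate equal to a
cumulative sum therefore selects the next fragment, and an end coordinate
at or past the total takes the last fragment. If either endpoint lands on
an uncolored fragment the read stays uncolored. Start/end are swapped when
the contig was colored in reverse, so `start ≤ end` always holds.

Gap adjustment treats every color in a read's `[start, end]` interval as
used, and remaps the used colors of each chromosome order-preservingly
onto consecutive integers starting at `k·s + base`. The `k·s` term is
never touched; the mapping is an order-preserving bijection and
idempotent. `base` defaults to 0 to match the fragment numbering; the CLI
exposes it for 1-based color schemes.

## Guided assembly

Graph construction follows the miniasm layout recipe on PAF input: records
shorter than `min_overlap_bp` (500) are dropped; each remaining hit is
classified by its oriented overhangs (`max_overhang` 1000, ratio 0.8) as
an internal match (ignored), a containment (the contained read is removed
entirely), or a dovetail, which contributes an edge and its bidirected
mirror (two oriented vertices per read); transitive edges are removed with
offset slack `reduction_fuzz` (100 bp).

A vertex's colors are the closed interval between its read's start and end
colors — the start/end pair is a compact encoding of the contiguous set of
fragment colors the read overlaps, so the consistent-edge existence test
("some color of the target equal to or at most `d` greater than some color
of the source", `max_color_step` d = 1 by default) ranges over the two
intervals. Testing only the two endpoint colors was considered and
rejected: two correctly colored overlapping reads with shifted intervals
(say [22,28] and [24,32]) have no endpoint pair within step 1 and would be
disconnected, splitting true chains. Consistency is judged per directed
edge, so of a mirror pair only the direction that travels in
non-decreasing color order survives; the unitig walker emits candidate
paths longest-first and suppresses any path that contributes no new read,
which removes the mirror images (and mirror fragments) that the bidirected
construction implies.

With propagation disabled (the default, and the configuration that
performed best in the coloring experiments) uncolored reads are simply
dropped. With `propagation_limit` L ≥ 1 (5 mirrors the guided assembler
this design follows), an uncolored read collects the colors of colored
reads reachable within L hops through uncolored reads in either direction;
if the union of the collected intervals is contiguous the read is colored
with its (min, max), otherwise it is deleted as incoherently placed.

Unitigs are maximal non-branching paths (extend while the next vertex has
in-degree 1 and the current out-degree 1; isolated cycles are broken at
their smallest vertex). After filtering, every such path necessarily
satisfies the rainbow condition — each consecutive pair consistent with
step ≤ d — and this is re-asserted at runtime; a violation aborts the run
as a filtering bug. Sequences are laid out without consensus: the first
oriented read plus each successive read's non-overlapping suffix, so
`len(unitig) = Σ read lengths − Σ overlap lengths` and disagreements
resolve in favor of the earlier read.

The built-in overlapper is a deliberately simple exact-seed engine
(canonical 15-mers, deterministic 1-in-5 subsampling by multiplicative
hash, diagonal voting, banded edit-distance verification with edlib at
≤ 15 % divergence) adequate for low-error reads; for real high-error reads
the PAF input path with an external overlapper is canonical. Read-to-contig
mapping reuses the same machinery with up to 4 candidates per read and
reads hanging off contig ends trimmed so their tails appear as PAF clips.

## Synthetic data

The generator emulates a small-genome guided-assembly study: by default two
150 kb chromosomes of uniform random sequence with accidental XhoI motifs
erased and motifs planted at exponential spacing (mean 2.5 kb, so contigs
of a few tens of kb carry enough fragments to place); 20× coverage of
log-normal reads (mean 8 kb, sd 2.5 kb — the long-tailed regime of
corrected long reads); 0.5 % total per-base error (0.3 % mismatch, 0.1 %
insertion, 0.1 % deletion — substitutions applied before indels, positions
uniform), matching reads *after* error correction, which is outside this
package's scope. `repeat_length > 0` plants an exact copy of a segment of
chromosome 1 into chromosome 2, the canonical failure mode guidance is
meant to fix. Optical-map noise (multiplicative sizing error, missed-cut
merges, Poisson false cuts per kb) defaults to zero — the error-free
in-silico-map setting; merges and splits conserve total map length
exactly.

What this does **not** model: chimeric reads, systematic error hotspots,
real sizing-error distributions of imaging-based maps, unresolved small
fragments, or diploid variation. Passing the end-to-end checks therefore
shows the machinery is correct and the guidance logic effective under
clean conditions, not that the method's published performance on real
genomes is reproduced.

## Validation scale and numerical choices

The end-to-end checks run at desk scale, chosen to finish comfortably on
one CPU: 2 × 150 kb with a 3 kb planted repeat at 20× for the guidance
benefit (≈ 750 reads), 1 × 100 kb at 20× for the unicolored control, 200
random map pairs of ≤ 6 fragments for the alignment oracle, 100 random
colored graphs of ≤ 12 vertices (exhaustive path enumeration) for the
rainbow guarantee, and 1000 random sequences for digestion conservation.
The unicolored control colors every aligned read with one flat color per
contig: it reproduces the unguided unitig read-sets exactly, separating
the benefit of genuine location information from the side effect of
dropping unaligned reads.

Floating-point block-length bookkeeping in colored maps conserves length
to ~1e-16 relative; color lookup tolerates this because interval ends at
or past the cumulative total select the last fragment. All randomness is
routed through seeded generators; dictionaries preserve insertion order
and all remaining iteration is sorted, so every operation is a pure
function of (inputs, seed).

## Known limitations

- No consensus/polishing: unitig sequences inherit the layout's base
  errors. Scaffolding and gap estimation from the maps are future work.
- Chimeric contigs (misjoins in the pre-assembly) get at most one map
  placement; split alignments are not attempted, so their reads are either
  colored by the dominant segment or left uncolored.
- The per-directed-edge consistency test keeps both directions of an edge
  whenever the two color intervals overlap; orientation disambiguation
  then falls to the graph structure rather than the colors.
- Reads whose best alignment is to a repeat copy on the wrong chromosome
  can be miscolored; the planted-repeat validation uses a repeat shorter
  than the typical read so that such reads anchor unique sequence, which
  is the regime where guidance helps rather than harms.
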