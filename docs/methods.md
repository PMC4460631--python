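# Methods

## The problem

Nanopore long reads carry enough length to span bacterial repeats that
short-read assemblies cannot resolve, but their raw accuracy (here
modelled at ~74.5% identity for 2D reads, ~56.6% for 1D reads) makes them
unusable directly for many analyses.  This package treats each noisy long
read purely as a *recruitment scaffold*: accurate paired-end short reads
are gathered around it and locally assembled, so the final "synthetic
long read" has the span of the long read and the per-base accuracy of the
short reads.  At most one synthetic read is produced per template.

## Workflow

For one template the stages are:

1. **Seeding.**  Short reads are aligned to the template with a sampled
   word index (every 10-mer taken each 5 bases) followed by local
   Smith-Waterman extension (+1/-1/-1).  A read with a retained alignment
   (identity ≥ 0.65, ≥ 50% of the read aligned) is a *seed-read*; its
   mate joins the set with the strand implied by the innie pair geometry.
   The stringency floor is set by survival under 25-43% template error: a
   250 bp read at 25.5% error retains ~74.5% alignment identity, and on
   average ~2.6 of its ~50 sampled 10-mers are error-free, so two
   clustered exact words is the weakest anchor worth extending.
2. **Recruitment.**  Regions of the template too error-rich to seed are
   recovered indirectly: every canonical 32-mer of every seed-read is
   indexed, and any read of the full collection sharing at least three
   *non-overlapping* indexed 32-mers (greedy earliest-end scheduling,
   optimal for counting disjoint fixed-length intervals) is recruited,
   with its mate.  Recruitment is a single round.
3. **Micro-assembly.**  Seed plus recruited reads are assembled
   overlap-layout-consensus: dovetail overlaps (≥ 40 bp at ≥ 98%
   identity, candidates from winnowing minimizers k=15/w=8), Myers-style
   transitive reduction, unitig chains, column-majority consensus with
   ties broken toward the backbone read.  Branch points terminate contigs
   and are recorded as undirected adjacency edges.  Contig tips follow
   the outermost read instead of being clipped at a depth cutoff.
4. **Foreign-contig filtering.**  Seed-reads are re-aligned to the
   contigs; reads hitting more than one contig, or aligning over < 50% of
   their length, or below 90% identity, are discarded, and each contig's
   *seed coverage* is the mean per-base depth of the survivors.  The
   longest contig plus every contig with seed coverage strictly above
   `MIN_COV1 = 10` survives.  Contigs assembled from reads recruited out
   of a look-alike locus attract almost no direct seed alignments and die
   here.
5. **Graph resolution.**  The surviving contigs form an undirected graph,
   vertex-weighted by seed coverage; source and sink are the contigs
   whose seeds map nearest the template's 5' and 3' ends.  The synthetic
   read follows the maximum-weight *simple* source-to-sink path.
   Negating weights and running an all-pairs shortest-path pass is only
   well-defined on acyclic graphs, so the objective is computed exactly
   by branch-and-bound enumeration (graphs here have a handful of
   vertices; ≤ 20 vertices exhaustively), with a template-coordinate-
   ordered DAG relaxation for anything larger.  Consecutive path contigs
   are merged at their best suffix-prefix overlap (≥ 20 bp, ≥ 98%
   identity), junction bases from the higher-coverage contig.
6. **Validation.**  The merged candidate is first clipped to the
   template's physical reach (see below), then every short read is
   re-aligned to it (word size 12).  Only near-full-length alignments
   (≥ 95% of the read, ≥ 90% identity) count toward depth.  If interior
   depth ever falls below `MIN_COV2 = 10`, the longest gap-free region is
   kept (status `trimmed`); otherwise the read is `valid`.  The first and
   last `fragment_max − read_len` bases (500 bp at the defaults) are
   exempt, since physical coverage necessarily decays at the ends.

### Why validation demands near-full-length alignments

A chimeric candidate — two genomic loci joined at a false junction — is
betrayed by the absence of reads *spanning* the join.  But reads clipped
at the junction still align their near side; with a 90% query-fraction
cut, up to 25 bp of overhang is tolerated and the expected depth exactly
at the junction is `2 × 25 × coverage/read_len ≈ coverage/5` — right at
the threshold for 50× data.  At 95% the expectation drops to
`coverage/10`, robustly below `MIN_COV2`, while genuine interior reads
(whose substitution errors cost at most a couple of terminal bases under
local alignment) still pass.

### Template-reach clipping

Recruitment legitimately chains outward: border seeds pull their mates
(up to one fragment length away), mates' k-mers recruit further reads,
and those reads' mates extend again — up to roughly two fragment lengths
past the template.  Sequence that far out has no template support, so the
candidate is clipped to `fragment_max − 50` bp beyond the template's
edit-distance image in the candidate; the 50 bp slack absorbs the end
uncertainty of locating a 25-43%-error template.  Net elongation is
therefore bounded by one fragment length per side, and typically runs
600-700 bp per side at the default library geometry.

### Disconnected graphs

When the contig graph has several components (a chimeric template whose
loci assemble separately, or junction contigs lost to the seed-coverage
filter), each component is resolved independently and the merged pieces
are concatenated in template order.  If consecutive pieces share a real
suffix-prefix overlap they are spliced there; otherwise the join is blunt
and flagged, and depth validation decides whether it stands — exactly the
role of the coverage-consistency check.

## Synthetic data model

The generator emulates the study system end to end:

* **Genome** — uniform random DNA with optional scattered repeat
  families; copies of one family are byte-identical (the hardest case,
  modelled on identical rDNA clusters) and placed at non-overlapping
  loci.
* **Long reads** — log-normal lengths (truncated at 500 bp), uniform
  strand, i.i.d. per-base errors split substitutions:insertions:deletions
  = 50:25:25.  Published error rates are *edit-distance* rates, and
  independently applied edits overshoot the intended identity because the
  optimal alignment finds cheaper paths (adjacent insertion+deletion
  collapse, chance matches).  Applied rates are therefore scaled by a
  deterministic pilot-simulation secant iteration until realized edit
  distance per base matches the nominal total (0.255 for 2D-like, 0.434
  for 1D-like); the calibration uses a fixed internal seed so it never
  perturbs caller-visible determinism.
* **Short reads** — innie pairs from 650-750 bp fragments, 2×250 bp by
  default, substitution-only errors at 0.1% (MiSeq-like post-QC error;
  Illumina indel rates are orders of magnitude lower than substitutions)
  with flat Phred qualities consistent with the rate.  Total bases hit
  the requested coverage within one pair.
* **Chimeras** — concatenation of two error-mutated loci separated by
  more than a fragment length; the fixture for the validation stage.

What the generator does *not* model: GC/PCR coverage bias, quality decay
along the read, adapter contamination, structured (homopolymer) nanopore
errors, and fast5-level signal.  Passing tests therefore demonstrate the
pipeline's combinatorial and statistical correctness under idealised
sampling, not robustness to instrument-specific artefacts.

## Parameters

| name | default | meaning |
|---|---|---|
| `tile_size` / `step_size` | 10 / 5 | seeding word size and index stride |
| `min_seed_hits` | 2 | clustered exact words required to attempt extension |
| `seed_min_identity` | 0.65 | retain threshold for seed alignments |
| `seed_min_query_fraction` | 0.50 | minimum aligned fraction of a seed-read |
| `recruit_k` / `recruit_t` | 32 / 3 | recruitment word size / disjoint-word count |
| `min_overlap` / `min_overlap_identity` | 40 bp / 0.98 | assembly overlap thresholds |
| `min_cov1` | 10 | seed-coverage floor for contigs (strict >) |
| `min_cov2` | 10 | validation depth floor |
| `validate_tile` | 12 | word size for the validation alignment |
| `trim_q` / `trim_min_len` | 20 / 30 bp | short-read QC: end-trim quality / length floor |
| `fragment_max` | 750 bp | library upper fragment bound; sets reach and end margins |

## Numerical and tie-break conventions

Alignment scores are +1 match, −1 mismatch, −1 gap; equal-scoring
alignments prefer leftmost target start, then + strand.  Single-diagonal
seed clusters take a gap-free fast path (maximum-score subarray, exactly
the local DP optimum on that diagonal) and fall back to full DP whenever
the gap-free solution covers < 90% of the available extent, so indel-bearing
alignments are never silently truncated.  Consensus ties go to the
backbone read's base.  Contig ids are assigned by decreasing length for
run-to-run stability; path ties prefer fewer vertices, then lexicographic
ids.  Coordinates are 0-based half-open on the forward strand throughout.

## Problem sizes

The shipped experiments run on 30-50 kb genomes, 8-20 templates of mean
4-5 kb, and 10-50× short-read coverage — large enough that every stage
(seeding under heavy error, recruitment, branching assemblies, repeat
and chimera resolution, the coverage plateau) is exercised with clear
statistical margins, while a full run of the test suite and the
acceptance script completes on a single CPU in a few minutes.

## Known limitations

* Consensus assumes indel-free short reads (substitution-only layout
  offsets); indel-bearing short-read data would need a realignment pass.
* One round of recruitment; templates whose error-rich interior exceeds
  the reach of seed mates plus one k-mer hop can remain split (the
  component splice then reconnects genomically overlapping pieces).
* 1D-class templates (~43% error) rarely seed at the default stringency,
  matching the large 2D/1D success gap the method is known for; rescuing
  1D templates would require a more sensitive (slower) seeding stage.
* The maximum-weight-path objective is exact only up to the exhaustive
  limit (20 vertices); larger graphs use the coordinate-ordered DAG
  relaxation.
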