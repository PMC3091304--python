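# Methods

This note documents the models, conventions and defaults implemented in
`tilefuse`, the reasoning behind design choices where the underlying method
description is qualitative, and what the synthetic-data tests do and do not
demonstrate about behaviour on real data.

## Alignment contract

Reads are trimmed to their first `trim_len` bases (default 50, from 56 bp
raw reads) and aligned **ungapped, end-to-end**, reporting *every* placement
on either strand with Hamming distance ≤ `max_mismatches` (default 3). An
`N` in the read always counts as a mismatch; base qualities are ignored.
Indel-containing reads simply fail to map — consistent with the
seed-and-extend short-read aligners of the 50 bp era this pipeline models,
and (more importantly) a contract simple enough to verify exactly: the test
suite and the acceptance script compare the production aligner against a
brute-force sliding-window scan and require perfect agreement.

The implementation uses pigeonhole k-mer seeding: a read cut into
`max_mismatches + 1` disjoint segments must match the reference exactly in
at least one segment, so looking up all segments in an exact k-mer index
(seed length 12 for 50 bp reads) finds every qualifying placement; each
candidate is then verified with vectorised mismatch counting. Reads too
short for the pigeonhole argument fall back to a full scan, so the
all-placements guarantee is unconditional. Output order is deterministic
(reference id, position, strand).

Contaminant filtering (rRNA-like and adaptor sequences) removes the **whole
pair** when either mate places on a contaminant with ≤ `max_mismatches`
mismatches. Removing single mates instead would leave unpaired evidence that
no downstream stage can use.

### Read categories and locus counting

After aligning against the genome plus all *normal* splice-junction
sequences (for every consecutive exon pair of every transcript, up to
`flank = trim_len − 1` bases on each side, in transcript orientation), each
read is unaligned, unique, or multi by its number of distinct **loci** — not
raw placements. A placement lying entirely within one flank of a junction
sequence is the same locus as its genomic equivalent, and boundary-spanning
placements on junction sequences of transcripts sharing the same intron are
one locus. Without this collapse every exon-end read would be spuriously
"multi" whenever the flank exceeds the read length, and junction sequences
from alternative transcripts would shadow each other.

A unique read is assigned to a gene only when all its (locus-equivalent)
placements vote for exactly one gene: genomic placements vote for every gene
with an overlapping exon, junction placements for the junction's gene.
Intronic, intergenic and shared-exon placements therefore assign nothing —
reads in exons shared by overlapping genes are deliberately discarded as
ambiguous rather than double-counted.

## Candidate discovery and exclusion filters

Pairs whose mates are uniquely and unambiguously assigned to two different
genes accumulate into unordered gene-pair candidates. Orientation (which
partner is 5′) is *not* decided here — mate order is library-dependent — but
by the junction stage below. Candidates are excluded when:

- the genes **overlap** (genomic spans intersect, strand ignored), or are
  **adjacent**: no third gene, of any biotype, has both its start and end
  strictly inside the gap between them. Such chimeras are most plausibly
  transcriptional readthrough. Adjacency is evaluated on gene spans (not
  transcript spans) and ignores strand, the conservative reading of a rule
  whose source states neither; this may discard true fusions between
  neighbouring genes (e.g. from tandem duplication) — a known trade-off.
- the genes are listed as **paralogs** (an input two-column table; homology
  inference is out of scope) — discordant pairs between near-identical
  copies are most plausibly cross-mapping.
- fewer than `min_pair_support` pairs support them. Default 2; a depth
  scaling rule of thumb is 3 once a library exceeds roughly 8M filtered
  pairs, keeping the false-positive proportion comparable across samples.
  The threshold is never adjusted automatically.

## Junction resolution

For each candidate, junction sequences for **all** exon-exon combinations in
**both** orientations are generated (distinct exons by coordinates; identical
sequences deduplicated with merged labels), each up to `flank` bases per
side in the donor transcript's orientation. Only reads that aligned nowhere
in the first pass are placed on this database: uniquely genome-aligned reads
are never reused as junction evidence. A placement is a junction hit only if
it spans the breakpoint with ≥ `min_anchor` bases on **both** sides
(default 10). The looser reading — 10 bp on *one* side — is vacuous for
50 bp reads, so the two-sided reading is the only meaningful one; it is also
what makes short spurious overlaps at the junction improbable. A read
hitting several junction sequences keeps only its minimum-mismatch hits
(ties keep all, but a read counts once per junction).

A junction with ≥ `min_junction_reads` (default 2) distinct spanning reads
becomes a call; the supported orientation names the 5′ partner. Multiple
surviving junctions for one gene pair are all reported (alternative splicing
at the breakpoint; reciprocal A→B / B→A support is flagged for review).
Candidates below the pair-support threshold are *not* rescued by junction
reads.

## The tiling classifier

The qualitative observation being formalised: junction reads of a genuine
fusion start at positions staggered ("tiling") across the breakpoint,
whereas misalignment artifacts produce reads aligning at the exact same
position or shifted by one to two base pairs, almost exclusively anchored in
one exon. The classifier calls a junction **artifact** iff any of:

1. `max(start) − min(start) ≤ artifact_span` (default 2 bp) — the stack;
2. `distinct starts < min_distinct_starts` (default 3) — too little
   staggering to judge;
3. fewer than `min_two_sided_anchor_reads` (default 1) hits have both
   overhangs ≥ `min_anchor` — one-sided anchoring. With the default
   two-sided anchor already enforced at the hit level this sub-criterion is
   redundant, but it becomes active whenever the classifier is run with a
   stricter anchor than the aligner, and all three sub-criteria are logged
   per call either way.

The only quantitative anchors available for these defaults are the "one to
two base pairs" shift and the qualitative "almost exclusively one exon";
`min_distinct_starts = 3` is the smallest count that makes "staggered"
meaningful against a ±1 bp stack. All three are parameters.

Calls are ranked genuine before artifact, then by descending distinct
starts, junction reads, bridging pairs, with gene ids as the final
deterministic tie-break.

## Frame prediction

For every coding 5′-partner transcript containing the fused 5′ exon and
every coding 3′-partner transcript containing the fused 3′ exon, the coding
phase at the junction is `(retained CDS length) mod 3` on each side; the
fusion is **in-frame** if *any* combination matches. Junctions outside a CDS
are resolved by position rather than phase:

| 5′ junction | 3′ junction | call | rationale |
|---|---|---|---|
| after 5′ CDS | anything | in-frame | complete 5′ ORF retained, new 3′ UTR |
| mid-CDS | in 3′ gene's 3′ UTR | in-frame | truncated 5′ protein, new 3′ UTR |
| before 5′ CDS | before 3′ CDS | in-frame | promoter swap, complete 3′ ORF |
| before 5′ CDS | mid-CDS | out-of-frame | no start codon for the 3′ ORF |
| mid-CDS | mid-CDS | phase equality | standard case |

CDS length need not be a multiple of three (a stop codon may be excluded
from the annotation); only the phase relative to the CDS start is used. An
optional relaxation (`allow_exon_skip`, off by default) also accepts
combinations in which dropping any single internal exon on either side
restores phase — a concrete operationalisation of "potential splice
variants", for which no enumeration rule is given anywhere; strict mode is
the default precisely because this is an extension.

The mid-CDS case is verified against an independent oracle that builds the
fused transcript string, translates it from the annotated start codon, and
checks whether the acceptor's wild-type protein reappears downstream.

## Expression, chromosomal class, copy number, coverage

- **RPKM** = unique reads assigned to the gene / (merged exonic kb × total
  uniquely mapped reads in millions).
- **Fusion expression** = junction-read count, reported raw and RPKM-style
  normalised by junction sequence length.
- **Chromosomal class** is `intra` iff both partners share a chromosome.
- **Copy-number association** consumes an already-segmented log2-ratio
  profile (segmentation itself is out of scope). A call is *at a
  transition* when a boundary between abutting segments with |Δlog2| ≥ 0.3
  falls within either gene's span extended by `transition_window`
  (default 100 kb), and *amplified* when either gene overlaps a segment
  with log2 ≥ 1.0. These thresholds mirror common aCGH practice; the
  original calls they emulate were made by visual inspection of 1M-probe
  profiles, so they are parameters, not claims. Both flags are `None` when
  no profile covers the genes. Out-of-frame and non-amplified calls are
  reported, never suppressed.
- **Coverage** counts per-base depth of unique reads over a gene's merged
  exonic intervals (junction-reference placements are projected onto both
  exon flanks), supporting the "exclusive expression" inspection in which a
  promoter-swap acceptor shows ~zero depth upstream of the fused exon.

## Synthetic universes

The generator emulates the data regime the pipeline targets: 2–3
chromosomes of ~100–150 kb; ~12–30 genes of 3–6 exons (140–300 bp exons,
200–800 bp introns); single-transcript genes with CDS placed so planted
frame targets hold exactly; paired 56 bp reads trimmed to 50 downstream;
insert sizes from a normal distribution at a configurable median (default
200 nt, σ = 10, matching the emulated libraries' 100/200 nt medians);
independent per-base substitution errors (default 0.5%, no indels — matching
the ungapped contract); an exact `rrna_fraction` of pairs copied error-free
from rRNA-like contaminant sequences. Planted events:

- **fusions**: bridging pairs (one mate per side of the junction, never
  crossing it) plus junction-spanning reads with start offsets drawn
  uniformly over the valid anchor range (the tiling signature);
- **artifact stacks**: the same construction but with one start position
  jittered ± 1 bp and biased to hang off the 5′ exon — the observable the
  filter sees, rather than a simulation of the upstream misalignment
  mechanism that produces it in real data;
- **readthrough decoys**: chimeric transcripts across two *adjacent*
  same-strand genes, exercising the adjacency filter;
- **paralog decoys**: a gene copied at 95% identity onto another
  chromosome and entered in the paralog table; decoy bridging mates are
  drawn error-free from read windows verified to differ from the homolog at
  ≥ 5 positions, so they map uniquely and the candidate is excluded by the
  paralog table rather than dissolving into multi-mappers.

One integer seed drives a single RNG; outputs are byte-identical across
runs, and every planted event is recorded in a truth table.

**What passing these tests shows — and does not.** Closed-loop recovery
demonstrates the bookkeeping end to end: orientation, exon resolution,
frame, class, filters and the tiling decision, at realistic read counts.
It does not exercise quality-score structure, GC or coverage bias, PCR
duplication, indels, repetitive genomes, annotation errors, or junction
reads from unannotated exon boundaries — real-data phenomena the generator
deliberately omits. Performance claims are desk-scale: the flagship
universe (~3,100 pairs, ~450 kb genome, 30 genes) detects in a few seconds;
the design has no FM-index-class engineering and is not intended for
lane-scale FASTQ.

## Numerical and procedural choices

- Coordinates are 0-based half-open internally; GTF I/O is 1-based
  inclusive. Adjacency's "between" is strict containment in the open gap.
- No read deduplication: identical-start pathology is the tiling filter's
  job, and removing PCR duplicates early would also remove legitimate
  stacked evidence the classifier needs to *see* to reject.
- Detection is fully deterministic; the seed parameter only labels the run
  manifest (inputs are hashed there for reproducibility).
- Degenerate inputs: empty reference sets, non-positive trim targets,
  zero-length CDS variants, overlapping copy-number segments and malformed
  annotation lines raise typed errors naming the offending item; exons
  shorter than a flank contribute their full length without error.
- Problem sizes in the shipped tests (flagship universe, 500-replicate
  discrimination runs, 1,000-read aligner oracle, 200-pair frame oracle)
  keep the full suite around twenty seconds while leaving each check's
  statistical headroom intact.

## Known limitations

Breakpoints are resolved only at annotated exon boundaries; gapped or
quality-aware alignment, genomic (DNA-seq) breakpoint calling,
trans-splicing discrimination, nonsense-mediated-decay modelling and
database lookups of known cancer fusions are all out of scope. The initial
candidate counts reported on real libraries (hundreds per sample before
filtering) arise from real transcriptome complexity and have no synthetic
counterpart here.
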