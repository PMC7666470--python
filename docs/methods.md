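# Methods

`insertag` detects, sequence-resolves, classifies, and genotypes non-reference
insertion structural variants (> 50 bp) from short-read paired-end data. This
note documents the model behind each stage, the tunable parameters and their
defaults, the synthetic-data generator that the validation suite runs on, and
the numerical choices made where the design was genuinely open.

## Discovery

**Evidence model.** The atomic evidence unit is the discordant paired-end read
(PER): a pair in which one end (the *anchor*) maps confidently to the
reference while the other (the *overhang*) is unmapped or maps discordantly.
A pair counts as discordant when the mates are on different chromosomes, in
non-FR orientation, or the outer insert exceeds the library mean + 3 sd.
Anchors below MAPQ 20 (`min_mapq`) are discarded; secondary, supplementary,
and duplicate records are ignored. For both-ends-mapped discordant pairs,
each sufficiently confident end can act as the anchor, so such a pair can
contribute evidence at two loci. Overhang sequences are stored reoriented
into the anchor's genome-forward frame (for an FR library the overhang of a
forward anchor was sequenced from the reverse strand), which lets all
downstream assembly run on a single strand.

**Clustering.** Anchors are clustered per (chromosome, strand) by single
linkage with link distance mean insert + 2 sd; clusters below `min_support`
(default 3) PERs are dropped. Library statistics (insert mean/sd, modal read
length) are estimated from properly paired primary records.

**Local assembly.** Each cluster's anchored and overhang sequences are
assembled together in one orientation on a De Bruijn graph (default k = 31).
Graph cleaning is *relative*, not absolute: at a fork, an edge with coverage
below 0.2x its strongest sibling is cut, and a dead-end unitig shorter than
2k is clipped only when its own coverage is below 0.25x the competing branch.
There is deliberately no absolute minimum k-mer coverage (default 1): in a
discordant-only read set the k-mers spanning the breakpoint come from the few
junction reads whose reference-side overlap was too short for the mapper
(about 15-18 bp, below a typical 19 bp seed), so they may be covered once;
an absolute cutoff of 2 severs the contig exactly at the junction. Contigs
are maximal unbranched paths. Every member read is then re-placed on each
contig (edit distance <= 10%, both orientations); a contig is accepted only
if its placements are strand-consistent and chain together without an
unsupported gap larger than the read length (chimera guard).

**Breakpoint refinement.** The accepted contig is split against the local
reference (cluster span padded by the cluster window) at the phase-changing
point. Candidate reference offsets are seeded with exact 12-mers from the
contig end under test; for each offset an exhaustive scan over split points
picks the split maximizing *matches - 4 x mismatches* among splits whose
prefix mismatch fraction stays within 2% (`tol`) and whose final base
matches, with ties toward the longer flank. The score form matters: a plain
"longest flank within tolerance" rule lets the mismatch budget accumulated
over a long flank drag the split past the junction into the inserted
sequence. Both interpretations (prefix-matching = left-flank tag,
suffix-matching = right-flank tag) are tried per contig, because a cluster of
forward anchors legitimately produces a right-flank tag when the insertion is
shorter than the insert size and its overhang reads reach across into the
right flank. A tag requires >= 15 bp of flank (`min_flank`; junction contigs
cannot carry much more than the mapper's seed length, see above) and
>= 10 bp of inserted part (`min_ins_part`). Per cluster, validated contigs
are tried in read-support order and the first that yields a tag wins: the
*best-supported* contig is frequently pure flank when the graph breaks at the
junction.

**Pairing.** Left-flank tags are scanned against right-flank tags within the
insert-size window (mean + 2 sd), greedily matched one-to-one by ascending
absolute breakpoint gap. A pair is accepted only when its two breakpoints
essentially agree: gap in [-20, +100] bp (`microhomology_slack`,
`max_pair_gap`). The negative slack absorbs split jitter from target-site
microhomology; the positive cap reflects that both tags of one event describe
the same junction, and it rejects two artifact classes observed in
validation - reciprocal tags at a donor repeat locus (gap = -interval length)
and repeat-twin boundary tags paired across nearby distinct loci (gaps of
150-350 bp).

## Tracing

For each paired tag, `flank_len` = 500 bp of reference on each side of the
left-anchored breakpoint is mapped to every target genome (minimap2 short-read
preset behind a generic adapter). A flank hit is *unique* when it is the
single primary alignment with MAPQ >= 20 - MAPQ already encodes the
best/second-best score ratio, so no separate ratio threshold is kept. The two
flanks must hit the same target contig in the same orientation; the target
interval between the inner flank ends (soft-clip corrected, capped at 100
kbp) is the candidate full insertion. It is accepted when the partial
inserted sequences of both tags align to its corresponding ends at >= 90%
identity. Both flanks use the left-anchored frame, so when the two tag
breakpoints disagree the traced sequence is the left-anchored representation
of the variant; a breakpoint inside a microhomology tract therefore yields a
rotated but base-identical allele.

Candidates from several genomes are checked all-pairs at >= 90% identity over
the shorter sequence; the consensus is the candidate with the highest mean
pairwise identity (ties: longer sequence, then lexicographically smaller
genome name), and discordance is flagged but does not suppress the consensus.
Ancestral state is a pure function of the supporting genome classes: any
non-human-primate source implies the reference carries a deletion of
ancestral sequence ("retention of ancestral sequence"); otherwise any human
assembly or unmapped-contig-database source implies a novel insertion; with
no source the variant is untraced.

## Genotyping

For each sequence-resolved variant two alleles are built around the
breakpoint: the local reference allele and the insertion allele
(flank + full insertion + flank), with flank extension read length + 50 bp -
the 50 bp figure alone would not let a read lie entirely within one allele
while crossing a junction, so it is kept as the extra margin beyond the read
length. Reads fetched from the +-flank window (including unmapped mates
placed there by the aligner) are aligned to both alleles end-free in both
orientations (bit-vector edit distance). A read supports an allele when its
distance is better by >= 3 edits (`score_margin`) *and* the winning
alignment extends >= 10 bp (`min_overlap`) past a breakpoint junction; all
other reads are ambiguous and dropped. On the insertion allele both
junctions count. This choice makes heterozygote alt-ratios run above 0.5
(about 2/3 for long insertions, since the insertion allele exposes two
junctions against the reference allele's one), a deliberate mirror of the
original tool's reported lean toward homozygous calls; the thresholds are
exposed for retuning. Genotype is a pure threshold function of the supporting
ratio: depth < 4 -> ./., ratio <= 0.2 -> 0/0, >= 0.8 -> 1/1, else 0/1.
Variants not longer than max(read length, 100) bp are skipped with a reason,
as breakpoint-proximal mutations make score comparison unreliable for them.
Depth units are individual reads, not pairs.

## Mechanism classification

Fixed priority cascade, first positive wins: **VNTR** - some period p in
[2, len/2] (scan capped at 2000) covers >= 85% of the insertion by tandem
self-match at lag p and the consensus motif occurs within 4p of the insertion
site flank; **NAHR** - the longest ungapped >= 90%-identity alignment between
the two 100-bp breakpoint flanks reaches >= 50 bp; **TE** - externally
supplied repeat intervals on the insertion cover strictly more than 80% of
it (union arithmetic; majority family reported); **NH** - none of the above.
The VNTR coverage (85%) and NAHR homology (50 bp) thresholds are explicit
stand-ins where the upstream convention gives no number. Repeat annotation
is an input interface (BED-like intervals); a toy exact-motif annotator over
a user-provided library ships for testing, not a bundled repeat database.

## Synthetic data and validation protocol

The generator reproduces the benchmark conditions the discovery stage is
validated under, at desk scale:

* **Genomes**: i.i.d. background at GC 0.41 with interspersed repeats at
  density 0.2. The repeat library holds ~1200 synthetic families (300 bp-3
  kbp, log-uniform), each placed about once per genome at 0.2% copy
  divergence. The library is deterministic and shared across genomes, so an
  acceptor and a donor carry near-identical copy pairs of each family. This
  emulates recently active transposable-element copies - the regime that
  actually confounds short-read mapping: adding the donor to the mapping
  reference creates genuine multi-mapping at acceptor repeat copies, which
  is what makes the non-unique condition measurably harder than the unique
  one. With heavily diverged or genome-private repeats that hardness
  disappears and the unique/non-unique ordering inverts.
* **Implants**: 100 donor segments, log-uniform 100 bp-20 kbp, at uniform
  acceptor positions with >= 2 kbp separation (so neighboring events do not
  share discordant windows) and truth recorded on the original acceptor
  frame.
* **Reads**: 2x100 bp FR pairs at 30x, insert 350 +- 50 bp, substitution
  rate 0.002, uniform fragment starts; deterministic per seed.
* **Conditions**: reads are mapped (bwa mem) against the acceptor alone
  ("unique": implanted sequence absent from the reference) or against
  acceptor + donor ("non-unique": implant reads can also map to their donor
  locus).
* **Scoring**: a call matches a truth implant when its breakpoint gap is
  < 100 bp and >= 50% of its predicted insertion bases align locally
  (Smith-Waterman identities over predicted length) to the implanted
  segment; matching is one-to-one, greedy by gap. Sensitivity =
  matched/implanted; FDR = unmatched calls/calls. Gaps are measured against
  each implant's microhomology equivalence interval: inserting S at p and
  inserting the rotated S at p+h are the identical variant when the sequence
  ends match the flanks, so a breakpoint anywhere in that interval is exact.

What the generator does **not** emulate: real TE family structure (poly-A
tails, truncated 5' ends, subfamily hierarchies), indel sequencing errors
and quality-value structure, GC-dependent coverage bias, heterozygous
samples at the discovery stage (discovery reads are drawn from a homozygous
mutated acceptor), and assembly gaps in target genomes. Passing the suite
therefore demonstrates the pipeline's algorithmic correctness and its
behavior under mapping ambiguity, not performance on real human data.

Problem sizes used by the validation suite: the headline benchmark runs 5
Mbp acceptor/donor with 100 implants (one bwa pass per condition); the
breakpoint-precision run uses 2 Mbp / 50 implants with error-free reads; the
tracing round-trip uses 200 implants of 60 bp-10 kbp on 2 Mbp, repeat-free
(it probes the tracing machinery, not mapping ambiguity); the genotyping
panel types 50 diploid samples x 100 variants (insertions 150-800 bp, allele
frequencies 0.1-0.9) from ~30x reads around each breakpoint.

## Numerical choices and degenerate inputs

Ties in breakpoint splitting go to the longer flank; ties in tracing
consensus to the longer sequence, then the smaller genome name; ties in
top-F_ST ranking to the variant id. Empty PER input yields empty output
everywhere; a cluster whose graph supports no read yields no contig; a
contig fully matching the reference yields no tag; a variant with all
genotype calls missing gets an undefined (NaN) allele frequency; Nei F_ST of
a pooled-monomorphic variant is defined as 0. Oversized clusters are
truncated to 600 reads deterministically. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; external tools (bwa,
minimap2, samtools) run single-threaded with fixed command lines, so a fixed
seed and fixed inputs reproduce output files byte-for-byte.

## Population summaries

Allele frequency is alt-dosage over non-missing alleles (listwise per
variant, no imputation). Per-individual load is presence-based: a variant
with dosage >= 1 contributes its full length once, matching a per-individual
"variants carried" count; a dosage-weighted mode is available. Nei F_ST
between a group and the rest is (H_T - H_S)/H_T with H_S the unweighted mean
of the two groups' expected heterozygosities and H_T the expected
heterozygosity at the unweighted mean frequency; by concavity of 2p(1-p)
this is always in [0, 1].

## Known limitations

Discovery misses insertions whose junctions lack unmapped junction reads -
principally implants shorter than ~130 bp, where reads rarely lie fully
inside the insertion and junction-crossing reads are mapped as clipped
proper pairs and thus excluded by the discordant-PER definition (the
pipeline deliberately uses no split-read evidence). Insertions whose
breakpoints fall inside young, near-identical repeat copies lose anchors to
MAPQ filtering when the twin is present in the mapping reference. Tracing
requires both flanks to map uniquely, so insertions inside large repeat
tracts or near contig ends stay untraced. Genotyping assumes a biallelic
model and reports no genotype likelihoods.
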