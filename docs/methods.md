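# Methods

This note records the models, parameter choices and numerical conventions
behind `exocap`, and what the simulator does and does not emulate.

## Coordinates, alignment and divergence

All internal coordinates are 0-based half-open; 1-based coordinates appear
only when writing SAM and VCF. Local alignment is affine-gap dynamic
programming (Biopython's `PairwiseAligner` in local mode) with defaults
match +1, mismatch −2, gap open −4, gap extend −1 (a gap of length L costs
`open + (L−1)·extend`). `N` never matches anything, including itself, so
ambiguous bases inflate rather than deflate divergence — the conservative
direction for cross-species work. Divergence is mismatches over alignable
(both-sides-residue) columns; gap columns are excluded from numerator and
denominator. No published scoring scheme exists for the steps these
alignments replace, so the defaults are package choices, checked against an
exhaustive Gotoh oracle on short strings in the test suite.

## Target definition

Transcripts are annotated by six-frame translated local alignment against a
protein set; the best hit with score ≥ 50 wins. A score threshold replaces
an E-value cutoff because desk-scale search has no database-size context
that would make an E-value meaningful. CDS-completeness classes (full CDS,
partial CDS with 3′ UTR, with 5′ UTR, CDS only) are read off whether the
alignment reaches the protein's ends (2-residue slack for terminal
mismatch clipping).

Exon boundaries are transferred by aligning each reference exon to the
transcript; a placement is accepted at ≥ 80% exon coverage and ≥ 70%
identity — loose enough to tolerate several percent divergence between the
exon source and the transcript with margin, tight enough to reject
paralogous placements. Conflicting placements (overlap or order violation)
are resolved by dropping the lower-scoring exon: deterministic and
conservative. Nuclear exon targets shorter than 200 bp are dropped;
exact-sequence duplicates are removed, first occurrence kept.

## Probe design

60-bp probes tile each target at a class step (nuclear exon 4, genomic
interval 2, mito 20, SRY 1, control gene 4). A terminal probe flush with
the target end is always emitted even when the last offset is not a
multiple of the step, so no 3′ bases go uncovered. Nuclear exons get 1-bp
tiling at every offset within 30 nt of either end ("edge densification");
the 30-nt window is a package choice — half the distance at which edge
coverage profiles plateau. Soft-masking excludes any probe containing a
15-mer whose frequency on both strands of the masking reference is ≥ 50;
the threshold is deliberately stringent when the masking reference is a
transcriptome plus a draft genome rather than a finished assembly. K-mer
counting is literal per strand (no canonicalization): each window
contributes its forward k-mer and the opposite strand's reverse-complement
k-mer.

## Read filtration

The duplicate key is the exact full-length bases of both mates; the first
occurrence wins. Adapter trimming removes a 3′ adapter occurrence with
≥ 10 bp overlap and ≤ 10% mismatches; quality trimming removes the suffix
maximizing the running sum of `(20 − q)` from the 3′ end (the classic
BWA-style rule — the algorithm is a package choice, as only tools, not
algorithms, are on record for this step). Low complexity means a DUST-style
triplet score > 7 over 64-bp windows or ≥ 90% one nucleotide. Contaminant
screening flags a pair when ≥ 80% of either mate's 21-mers occur in the
contaminant k-mer table; k-mer screening replaces alignment to keep the
step dependency-free and is adequate at desk scale. Filter counts
telescope exactly (input = passed + removed per category) and the pipeline
is idempotent. Quality-score recalibration is deliberately out of scope;
the haploid-locus error estimate is the empirical check on raw qualities.

## Capture metrics

Duplicate and multi-mapped reads are excluded from every metric (MAPQ 0
marks multi-mapped in SAM input). A read is in-target if its alignment
overlaps a target span by at least one base. Sensitivity is the percentage
of targets with ≥ 1 covered base; specificity is in-target reads over all
uniquely mapped reads. Coverage threshold fractions deliberately mix
conventions — "at least 1×" is `≥`, higher thresholds are strict `>` — to
match how such results are conventionally phrased. Edge profiles pool
targets of 201–600 bp into 20-bp bins by distance from the nearer end up
to the midpoint. Reproducibility is the Pearson correlation of
log10(coverage + 1) across shared targets between library pairs.
Divergence–coverage tables bin per-target divergence (design target vs its
in-target contig, measured by local alignment) at 1%; bins with fewer than
3 targets are flagged low-support. Normalization before divergence
analysis subsamples libraries to a common read (or fragment) count; the
subsample size is configurable and defaults to desk scale.

The haploid error rate takes the per-column majority base as truth and
reports total mismatching stacked bases over total stacked bases across
columns with depth ≥ 10; the floor avoids miscalling the consensus at thin
columns and is a package choice. X-linked targets are those whose
female/male mean-coverage ratio lies in [1.9, 2.1]; targets with zero male
coverage are skipped and flagged. Females with any SRY-mapped reads are
flagged as possible cross-contamination, males with none as possible
capture failure.

## SNP calling and classification

Sites must pass depth 20–5000× and site quality ≥ 30. Site quality is
`−10·log10 P(X ≥ k)` under `X ~ Binomial(depth, e)`, where `k` is the
number of bases differing from the reference base and `e` the column's
mean base-quality error rate, capped at 2000. The null hypothesis is
"column = reference + sequencing error": a deviation count relative to the
*reference* (rather than to the column majority) is what admits fixed
inter-species differences, where every read carries the alternate allele.
A candidate is polymorphic when a second allele has ≥ 2 reads and ≥ 20% of
the column — a pooled-pileup operationalization, since individuals are
pooled per species; it is fixed when the consensus allele (≥ 90%) differs
from the reference. Functional classes translate the annotated codon in
frame (standard code), splicing CDS features across introns; positions in
no feature are unclassified and excluded from summaries. The cross-tab
summary reports per-species fixed/polymorphic counts by class, their
totals, and total-difference percentages to one decimal.

## The simulator

`exocap.simulate` generates the study conditions end to end: genes with
exon/intron/UTR structure (2–5 exons of 150–450 bp, introns 150–400 bp,
UTRs drawn then shrunk if needed to keep a viable CDS; CDS built from
sense codons so no internal stops exist by construction), species evolved
by uniform substitutions at set rates (defaults 0.6%, 1.5%, 8.8%) with
heterozygous sites at rate θ (default 0.002) between two haplotypes,
100-bp paired reads from ~N(250, 50) fragments, per-base error 4×10⁻⁴
with qualities set to the matching Phred score, PCR duplicates at 20% of
the library (byte-identical copies, as PCR duplicates are detected by
identity), contaminants at 1%, off-target background at 30%, and 7-nt
barcodes with pairwise Hamming distance ≥ 3.

Capture probability is `p(d) = min(1, exp(−32·max(0, d − 0.05)))` times a
quadratic GC penalty around 50% GC. The knee at 5% and λ = 32 are
calibrated so loci near 9% divergence lose 3–4× coverage relative to
near-identical loci. `d` is the **locus-scale** divergence — the
substitution density of the fragment's whole source contig — not the
realized mutation count of the individual fragment: hybridization responds
to regional divergence, and thinning on a 250-bp realized count would add
Poisson noise that (by Jensen's inequality, since the decay is convex)
inflates mean capture in high-divergence bins by ~15–20% and flattens the
calibrated 3–4× drop to ~2.7×. Per-target capture efficiency is a
lognormal factor (σ = 0.5) that is a fixed property of the target, shared
across samples, libraries and species — this is what makes per-target
coverage reproducible between independent captures, as observed in real
data.

What the simulator does **not** emulate: indels (off by default; an option
adds single-base indels at a fraction of the substitution rate for
stress-testing alignment-based stages only), quality decay along the read,
strand bias, PCR stochasticity beyond a flat duplicate fraction, and
paralogy/repeat structure beyond planted repeats in masking tests. Passing
tests therefore demonstrate correctness of the bookkeeping and the
statistical machinery under a clean generative model, not robustness to
every artifact of real libraries.

## Desk-scale study sizes

The bundled experiments (`exocap.workflows`) are sized for a laptop run of
seconds to tens of seconds each, chosen as the smallest sizes at which the
measured quantities are statistically stable: divergence decay uses 120
genes (~350 targets after the ≥ 200 bp filter; 40 near 0.6–1.5% and 80 at
8.8%) with 80 fragments per target and two libraries subsampled to a
common fragment count; error recovery uses a 16-kb haploid locus sequenced
to > 10⁶ stacked bases; X-linkage uses 45 genes (a third X-linked), 40
samples (half female) and 500 fragments per target, the depth at which the
F/M ratio's sampling noise is small against the 1.9–2.1 window; the
decay and dosage experiments switch off per-target efficiency variation
and the GC penalty to isolate the effect under test. Full determinism
holds throughout: one seed fixes every byte of simulator output.

## Known limitations

- The greedy cluster-then-consensus assembly merger replaces a multi-tool
  cascade; it is adequate for same-individual redundancy removal at ≥ 99%
  identity but is not a general-purpose assembler and does not scaffold.
- Reciprocal best hit is one-to-one: a contig spanning several targets
  pairs with only its best one. Capture assemblies are per-locus, so this
  matches the intended use.
- The binomial site-quality model ignores mapping error and strand
  information; it is a filter, not a genotyper, and individual-level
  genotypes are out of scope.
- Specificity counts single reads, not pairs; with one-base overlap
  in-target rules, mate placement in flanks lowers specificity slightly
  relative to a fragment-level definition.
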