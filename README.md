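# exocap

Reference-genome-free exon capture, end to end.

Hybrid-capture (target-enrichment) sequencing normally requires a sequenced
genome to design baits from. `exocap` implements the alternative workflow
used for non-model organisms: design tiling capture probes directly from a
de novo **transcriptome** assembly, enrich and sequence multiplexed genomic
libraries from several related species, and analyse the result without ever
touching a reference genome — the de novo assemblies of the captured reads
themselves become the mapping reference. The package covers:

- **Target definition** — transfer exon boundaries from a related genome's
  exons onto annotated transcripts by local alignment; keep exons ≥ 200 bp;
  add extra target classes (mitochondrial tiles, anonymous genomic
  intervals from a divergent relative, Y-linked SRY, control genes).
- **Probe design** — 60-bp oligos tiled at a class-specific step (nuclear
  exons 4 bp, genomic intervals 2 bp, mito 20 bp, SRY 1 bp), with 1-bp
  densification inside a 30-nt window at exon ends to soften the edge
  effect, and soft-masking of any probe containing a 15-mer seen ≥ 50
  times on both strands of the masking reference.
- **Read filtration** — demultiplex by 7-nt barcode, remove exact
  duplicate pairs, trim adapters and low-quality (Q < 20) tails, reject
  low-complexity reads, screen contaminants by shared 21-mers.
- **Capture evaluation** — sensitivity (% targets with ≥ 1 read),
  specificity (% uniquely mapped reads overlapping a target), per-target
  coverage and threshold fractions, within-target edge profiles, GC–
  coverage relation, between-library reproducibility, and the decay of
  normalized coverage with target divergence (1% bins).
- **Error-rate estimation** — empirical per-base error from haploid loci
  (mitochondrial contigs, X-linked targets in males, SRY), as
  mismatches / aligned bases against the per-column consensus, reported
  as a Phred score `Q = −10·log10(e)`. X-linked targets are found by a
  female/male coverage-dosage ratio in [1.9, 2.1].
- **SNP discovery** — candidate sites filtered at depth 20–5000× and
  Phred-scaled site quality ≥ 30 (binomial error model), partitioned into
  fixed differences vs polymorphic sites per species, and classified as
  synonymous / non-synonymous / intron / UTR against gene models.
- **A capture-experiment simulator** — gene-structured genomes, species
  evolved at chosen divergences with two haplotypes, fragment capture with
  probability `p(d) = min(1, exp(−λ·max(0, d − d0)))` (λ = 32, d0 = 5%
  divergence), GC penalty, per-target efficiency variation, paired 100-bp
  reads with planted error rates, PCR duplicates, contaminants and
  barcodes — with full ground truth, so every stage is verifiable.

## Worked example

Simulate a small experiment, design probes, and evaluate capture:

```
$ exocap simulate --seed 3 --out simout --n-genes 6 --samples 2
{"stage": "simulate", "species": "sp0", "divergence": 0.006, "pairs": 2918, "targets": 19}
{"stage": "simulate", "species": "sp1", "divergence": 0.015, "pairs": 2755, "targets": 19}
{"stage": "simulate", "species": "sp2", "divergence": 0.088, "pairs": 954, "targets": 19}

$ exocap design --targets simout/reference_exons.fasta \
                --mask-reference simout/transcripts.fasta --out designout
{"stage": "design", "designed": 2391, "masked": 0, "retained": 2391}

$ exocap eval --sam simout/sp0_truth.sam --targets-bed simout/targets.bed \
              --out evalout
{"stage": "eval", "reads": 5788, "targets": 19, "sensitivity": 100.0}

$ cat evalout/metrics.tsv
metric	value
sensitivity_pct	100.00
specificity_pct	55.59
targets_ge1X	1.0000
targets_gt5X	1.0000
targets_gt10X	1.0000
```

Reading the numbers: the three simulated species diverge 0.6%, 1.5% and
8.8% from the design; the 8.8% library yields about a third as many pairs
(954 vs ~2900) because fragments beyond the 5% divergence knee hybridize
poorly. All 19 targets received reads (sensitivity 100%), and 55.6% of
uniquely mapped reads overlap a target — the remainder land in flanking
introns and off-target background, which is what makes exon capture useful
for recovering intron and UTR sequence despite exon-only probes.

The same stages run as library calls; `exocap.workflows` bundles complete
desk-scale studies (divergence decay, haploid error recovery, X-linkage
detection, filtration bookkeeping).

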