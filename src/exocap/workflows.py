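"""Canned desk-scale experiments tying the simulator to the analysis stages.

Each function runs one self-contained study on synthetic data — divergence
decay, haploid error recovery, X-linkage detection by coverage dosage,
filtration bookkeeping, and headline capture metrics — and returns the
measured quantities together with the planted truth.  They are the same
entry points the reproduction script uses, and they double as worked
examples of how the pieces compose.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .capture_eval import (
    build_pileup,
    coverage_summary,
    divergence_coverage,
    haploid_error_rate,
    identify_x_linked,
    per_target_coverage,
    reproducibility,
    specificity,
)
from .readqc import quality_summary, run_filters
from .seqcore import SequenceRecord, count_kmers, local_align, percent_divergence
from .simulate import (
    SimConfig,
    Species,
    coverage_matrix_from_fragments,
    evolve_species,
    fragments_to_reads,
    random_dna,
    simulate_capture_reads,
    simulate_fragments,
    simulate_gene_space,
)

__all__ = [
    "divergence_decay_experiment",
    "haploid_error_experiment",
    "x_linkage_experiment",
    "filtration_experiment",
    "capture_metrics_experiment",
]


def _target_spans(space, min_length=200):
    return {
        t.target_id: (t.source_seq_id, t.span)
        for t in space.exon_targets(min_length=min_length)
    }


def divergence_decay_experiment(
    seed: int,
    n_close_genes: int = 40,
    n_far_genes: int = 80,
    far_divergence: float = 0.088,
    fragments_per_target: float = 80.0,
) -> dict:
    """Coverage decay across target divergence, as a binned table.

    One genome carries loci at two scales of divergence from the design:
    conspecific-like genes near 0.6-1.5% and anonymous-interval-like genes
    near 8.8%.  Two libraries are captured, fragment counts are subsampled
    to a common size per library (normalization), per-target divergence is
    *measured* by aligning each design target to its in-target locus contig,
    and mean normalized coverage is binned at 1% divergence.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_close_genes + n_far_genes
    config = SimConfig(
        seed=seed, n_genes=n_genes, off_target_fraction=0.0,
        duplicate_fraction=0.0, contaminant_fraction=0.0,
        gc_penalty_strength=0.0, target_efficiency_sd=0.0,
        mean_fragments_per_target=fragments_per_target,
    )
    space = simulate_gene_space(config, rng)
    rates = {}
    for i, gene in enumerate(space.genes):
        if i < n_close_genes:
            rates[gene.gene_id] = 0.006 if i % 2 == 0 else 0.015
        else:
            rates[gene.gene_id] = far_divergence
    species = evolve_species(space, rates, theta=0.001, rng=rng)
    spans = _target_spans(space)
    libraries = [("lib1", "F"), ("lib2", "F")]
    fragments = simulate_fragments(species, spans, libraries, config, rng)

    # normalization: equal fragment counts per library
    n_common = int(fragments.groupby("sample").size().min())
    subsampled = []
    for _, group in fragments.groupby("sample"):
        idx = rng.choice(len(group), size=n_common, replace=False)
        subsampled.append(group.iloc[np.sort(idx)])
    fragments = pd.concat(subsampled, ignore_index=True)

    cov = coverage_matrix_from_fragments(fragments, spans).mean(axis=1)

    # measured divergence: design target vs its in-target locus contig
    measured = {}
    for tid, (contig, (s, e)) in spans.items():
        target_seq = SequenceRecord(tid, space.contigs()[contig][s:e])
        locus = SequenceRecord(
            f"{tid}_locus",
            species.hap_a[contig][max(0, s - 150) : e + 150],
        )
        aln = local_align(target_seq, locus)
        if aln is not None and aln.alignable_bases >= 100:
            measured[tid] = percent_divergence(aln)
    table = divergence_coverage(measured, cov)

    close = table[table.divergence_bin <= 0.05 - 1e-9]
    far = table[(table.divergence_bin >= 0.08 - 1e-9) & (table.divergence_bin < 0.09)]
    close_cov = float(
        (close.mean_coverage * close.n_targets).sum() / close.n_targets.sum()
    )
    far_cov = float(
        (far.mean_coverage * far.n_targets).sum() / far.n_targets.sum()
    )
    return {
        "table": table,
        "coverage_le5pct": close_cov,
        "coverage_8_9pct": far_cov,
        "fold_drop": close_cov / far_cov,
        "n_targets": len(measured),
        "n_fragments": len(fragments),
    }


def haploid_error_experiment(
    seed: int,
    error_rate: float = 4e-4,
    locus_length: int = 16_000,
    n_pairs: int = 5_600,
) -> dict:
    """Recover a planted per-base error rate from a deep haploid locus.

    Emulates the mitochondrial-genome control: a single haploid contig is
    sequenced to >10^6 stacked bases and the mismatch rate against the
    per-column consensus is converted to a Phred-scaled quality.
    """
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, locus_length)
    species = Species(
        species_id="mt", divergence=0.0,
        hap_a={"mt": seq}, hap_b={"mt": seq},
        mutations={"mt": np.empty(0, dtype=int)},
        het_sites={"mt": np.empty(0, dtype=int)},
    )
    config = SimConfig(
        seed=seed, error_rate=error_rate, duplicate_fraction=0.0,
        contaminant_fraction=0.0, off_target_fraction=0.0,
        gc_penalty_strength=0.0, target_efficiency_sd=0.0,
        mean_fragments_per_target=float(n_pairs),
    )
    spans = {"mt_locus": ("mt", (0, locus_length))}
    fragments = simulate_fragments(species, spans, [("s1", "M")], config, rng)
    sim = fragments_to_reads(fragments, species, config, rng, [("s1", "M")])
    pileup = build_pileup(sim.alignments, sim.contig_lengths)
    mismatches, aligned, rate, phred = haploid_error_rate(
        pileup, [("mt", (0, locus_length))]
    )
    return {
        "planted_error_rate": error_rate,
        "mismatches": mismatches,
        "aligned_bases": aligned,
        "error_rate": rate,
        "phred": phred,
        "binomial_sd": float(np.sqrt(error_rate * (1 - error_rate) / aligned)),
    }


def x_linkage_experiment(
    seed: int,
    n_genes: int = 45,
    x_gene_fraction: float = 1 / 3,
    n_samples: int = 40,
    fragments_per_target: float = 500.0,
) -> dict:
    """Detect X-linked targets from female/male coverage dosage.

    Half the samples are female; X-linked genes carry half dosage in males.
    Targets whose female/male mean-coverage ratio falls in [1.9, 2.1] are
    called X-linked; recall on planted X targets and the false-positive
    rate on autosomal targets are reported.  Per-target efficiency
    variation is held fixed here: it cancels in the female/male ratio of
    the same target but would lower the effective depth of weak targets,
    so switching it off isolates the dosage signal being tested.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        seed=seed, n_genes=n_genes, x_fraction=x_gene_fraction,
        off_target_fraction=0.0, duplicate_fraction=0.0,
        contaminant_fraction=0.0, gc_penalty_strength=0.0,
        target_efficiency_sd=0.0,
        mean_fragments_per_target=fragments_per_target,
    )
    space = simulate_gene_space(config, rng)
    species = evolve_species(space, 0.0, 0.001, rng)
    spans = _target_spans(space)
    x_genes = {g.gene_id for g in space.genes if g.is_x_linked}
    x_targets = frozenset(t for t in spans if t.split("|")[0] in x_genes)
    samples = [(f"f{i:02d}", "F") for i in range(n_samples // 2)] + \
              [(f"m{i:02d}", "M") for i in range(n_samples - n_samples // 2)]
    fragments = simulate_fragments(species, spans, samples, config, rng,
                                   x_targets=x_targets)
    cov = coverage_matrix_from_fragments(fragments, spans)
    sexes = dict(samples)
    result = identify_x_linked(cov, sexes)
    called = set(result.index[result.x_linked])
    autosomal = set(spans) - set(x_targets)
    recall = len(called & set(x_targets)) / len(x_targets)
    fpr = len(called & autosomal) / len(autosomal)
    return {
        "n_x_targets": len(x_targets),
        "n_autosomal": len(autosomal),
        "recall": recall,
        "false_positive_rate": fpr,
        "n_samples": n_samples,
    }


def filtration_experiment(
    seed: int,
    duplicate_fraction: float = 0.20,
    contaminant_fraction: float = 0.02,
) -> dict:
    """Plant duplicate and contaminant fractions and recover them.

    Truth labels give the planted fractions exactly; the filtration
    pipeline's counts are checked against them and the telescoping report
    is returned.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        seed=seed, n_genes=10, duplicate_fraction=duplicate_fraction,
        contaminant_fraction=contaminant_fraction,
        mean_fragments_per_target=30.0,
    )
    space = simulate_gene_space(config, rng)
    species = evolve_species(space, 0.006, 0.001, rng)
    contaminant = random_dna(rng, 30_000)
    sim = simulate_capture_reads(
        species, _target_spans(space), [("s1", "F")], config, rng,
        contaminant=contaminant,
    )
    table = count_kmers([contaminant], 21)
    survivors, report = run_filters(sim.pairs, ["AGATCGGAAGAGC"],
                                    contaminant_kmers=table)
    n = len(sim.pairs)
    truth_dup = float(sim.truth.duplicate_of.notna().mean())
    truth_cont = float(sim.truth.contaminant.mean())
    report.check_telescoping()
    return {
        "n_pairs": n,
        "planted_duplicate_fraction": truth_dup,
        "planted_contaminant_fraction": truth_cont,
        "recovered_duplicates": report.duplicates,
        "truth_duplicates": int(sim.truth.duplicate_of.notna().sum()),
        "recovered_contaminants": report.contaminant,
        "truth_contaminants": int(sim.truth.contaminant.sum()),
        "fraction_passed": report.fraction_passed,
        "report": report,
    }


def capture_metrics_experiment(seed: int, n_genes: int = 20) -> dict:
    """Headline capture metrics on a close-divergence simulated experiment:
    sensitivity, specificity, per-target coverage and between-library
    reproducibility, from the truth alignments."""
    rng = np.random.default_rng(seed)
    config = SimConfig(seed=seed, n_genes=n_genes,
                       mean_fragments_per_target=30.0)
    space = simulate_gene_space(config, rng)
    species = evolve_species(space, 0.006, 0.002, rng)
    spans = _target_spans(space)
    samples = [("lib1", "F"), ("lib2", "M")]
    sim = simulate_capture_reads(species, spans, samples, config, rng)
    pileup = build_pileup(sim.alignments, sim.contig_lengths)
    metrics = coverage_summary(pileup, spans, records=sim.alignments)
    per_lib = {}
    for lib, _ in samples:
        recs = [r for r in sim.alignments if r.sample_id == lib]
        per_lib[lib] = per_target_coverage(
            build_pileup(recs, sim.contig_lengths), spans
        )
    repro = reproducibility(pd.DataFrame(per_lib))
    mates = [m for p in sim.pairs for m in (p.mate1, p.mate2)]
    mean_q, frac_q30 = quality_summary(mates)
    return {
        "sensitivity_pct": metrics.sensitivity_pct,
        "specificity_pct": metrics.specificity_pct,
        "mean_target_coverage": float(
            metrics.per_target_mean_coverage.mean()
        ),
        "threshold_fractions": metrics.threshold_fractions,
        "reproducibility_r": float(repro.iloc[0]),
        "mean_base_quality": mean_q,
        "n_targets": len(spans),
        "n_pairs": len(sim.pairs),
    }
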