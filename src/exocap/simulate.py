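"""Capture-experiment simulator with recorded ground truth.

Generates everything the pipeline consumes at desk scale: an ancestral gene
space (exon/intron/UTR structure, spliced transcripts, translated proteins,
reference exon sets), species genomes evolved at stated divergences with
two haplotypes per species, and multiplexed paired capture reads with
divergence- and GC-dependent capture probability, per-base sequencing
error, PCR duplicates, contaminant reads, and 7-nt sample barcodes.  Every
read is traceable to its source span, so filtration fractions, capture
metrics and SNP calls can be checked against planted values.

The capture-decay model is ``p(d) = min(1, exp(-lambda * max(0, d - d0)))``
with a knee at ``d0 = 5%`` divergence and ``lambda = 32``, calibrated so
that targets near 9% divergence lose 3-4x coverage relative to near-zero
divergence; ``d`` is the locus-scale (contig-wide) divergence of the
fragment's source region from the design sequence, and GC enters as a
quadratic penalty around 50% GC.  Substitutions
are placed uniformly (no back-mutation correction; negligible below ~20%
divergence), heterozygous sites separate the two haplotypes at rate theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .capture_eval import AlignmentRecord
from .readqc import ReadPair
from .seqcore import SequenceRecord, gc_fraction, revcomp
from .targets import ExonTarget
from .variants import GeneFeature, GeneModel

__all__ = [
    "SimConfig",
    "SimGene",
    "GeneSpace",
    "Species",
    "SimReads",
    "DEFAULT_BARCODES",
    "simulate_gene_space",
    "evolve_species",
    "simulate_fragments",
    "fragments_to_reads",
    "simulate_capture_reads",
    "coverage_matrix_from_fragments",
    "fragment_assemblies",
    "random_dna",
    "write_multiplexed_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

#: 7-nt sample barcodes, pairwise Hamming distance >= 3
DEFAULT_BARCODES = (
    "AACCGTT", "CCAATGG", "GGTTACC", "TTGGCAA", "ACGTACG", "CATGCAT",
    "GTACGTA", "TGCATGC", "AAGGTCC", "CCTTAGG", "GGAACTT", "TTCCGAA",
    "AGCTTGA", "CTAGGAT", "GATCCTA", "TCGAACT", "ATTGCGC", "CGGATAT",
    "GCCTATA", "TAACGCG", "ACACTCT", "CACAGAG", "GTGTCTC", "TGTGAGA",
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated capture experiment.

    Defaults mirror the system being emulated: 100-bp paired reads from
    ~250-bp fragments, per-base error around 0.04%, ~20% PCR duplicates in
    deeply sequenced libraries, species divergences near 0.6%, 1.5% and 9%,
    and a capture-efficiency knee at 5% divergence.
    """

    seed: int
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (150, 450)
    intron_length: tuple[int, int] = (150, 400)
    utr5_length: tuple[int, int] = (60, 150)
    utr3_length: tuple[int, int] = (100, 300)
    intergenic_pad: int = 300
    divergences: tuple[float, ...] = (0.006, 0.015, 0.088)
    heterozygosity: float = 0.002
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    error_rate: float = 4e-4
    duplicate_fraction: float = 0.20
    contaminant_fraction: float = 0.01
    off_target_fraction: float = 0.30
    capture_d0: float = 0.05
    capture_lambda: float = 32.0
    gc_penalty_strength: float = 1.0
    target_efficiency_sd: float = 0.5   # lognormal sigma of per-target efficiency
    x_fraction: float = 0.0
    mean_fragments_per_target: float = 40.0
    indel_fraction: float = 0.0     # indels at this fraction of the sub rate

    def __post_init__(self) -> None:
        for frac in (
            self.heterozygosity, self.duplicate_fraction,
            self.contaminant_fraction, self.off_target_fraction,
            self.x_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if list(self.divergences) != sorted(self.divergences):
            raise ValueError("divergences must be sorted")
        if self.exon_length[0] <= 0 or self.exon_length[0] > self.exon_length[1]:
            raise ValueError("bad exon length range")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class SimGene:
    gene_id: str
    genomic: SequenceRecord
    model: GeneModel
    exons: list[SequenceRecord]       # genomic exon slices, gene order
    exon_spans: list[tuple[int, int]]
    transcript: SequenceRecord
    protein: SequenceRecord
    is_x_linked: bool = False


@dataclass
class GeneSpace:
    config: SimConfig
    genes: list[SimGene]

    def contigs(self) -> dict[str, str]:
        return {g.gene_id: g.genomic.bases for g in self.genes}

    def contig_lengths(self) -> dict[str, int]:
        return {g.gene_id: len(g.genomic) for g in self.genes}

    def exon_targets(self, min_length: int = 0) -> list[ExonTarget]:
        """One capture target per exon (genomic coordinates)."""
        out = []
        for gene in self.genes:
            for k, (span, exon) in enumerate(zip(gene.exon_spans, gene.exons)):
                if span[1] - span[0] < min_length:
                    continue
                out.append(
                    ExonTarget(
                        target_id=f"{gene.gene_id}|exon_{k}",
                        source_seq_id=gene.gene_id,
                        span=span,
                        sequence=gene.genomic.bases[span[0] : span[1]],
                    )
                )
        return out


@dataclass
class Species:
    species_id: str
    divergence: float
    hap_a: dict[str, str]             # consensus haplotype per contig
    hap_b: dict[str, str]
    mutations: dict[str, np.ndarray]  # substituted positions vs ancestor (hap_a)
    het_sites: dict[str, np.ndarray]  # positions where hap_b differs from hap_a
    realized_divergence: float = 0.0

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.hap_a.items()}


def simulate_gene_space(config: SimConfig, rng: np.random.Generator | None = None) -> GeneSpace:
    """Ancestral genes with exon/intron/UTR structure, transcripts, proteins."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes: list[SimGene] = []
    n_x = round(config.x_fraction * config.n_genes)
    for gi in range(config.n_genes):
        gene_id = f"gene{gi:03d}"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_exons
        )
        total = int(exon_lens.sum())
        utr5 = min(int(rng.integers(*config.utr5_length)), int(exon_lens[0]) - 30)
        utr3 = min(int(rng.integers(*config.utr3_length)), int(exon_lens[-1]) - 30)
        # keep a viable CDS: shrink UTR draws before giving up on the geometry
        while total - utr5 - utr3 < 90 and (utr5 > 10 or utr3 > 10):
            if utr3 > 10:
                utr3 = max(10, utr3 - 30)
            else:
                utr5 = max(10, utr5 - 30)
        if total - utr5 - utr3 < 90:
            raise ValueError(f"{gene_id}: impossible geometry (CDS too short)")
        cds_len = total - utr5 - utr3
        utr3 += cds_len % 3
        cds_len -= cds_len % 3

        n_codons = cds_len // 3
        codon_idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
        cds = (
            "ATG"
            + "".join(SENSE_CODONS[i] for i in codon_idx)
            + ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        )
        transcript_bases = random_dna(rng, utr5) + cds + random_dna(rng, utr3)
        assert len(transcript_bases) == total

        # split the transcript into exons, then interleave introns
        bounds = np.concatenate([[0], np.cumsum(exon_lens)])
        pad = config.intergenic_pad
        pieces = [random_dna(rng, pad)]
        exon_spans: list[tuple[int, int]] = []
        pos = pad
        for k in range(n_exons):
            exon_seq = transcript_bases[bounds[k] : bounds[k + 1]]
            exon_spans.append((pos, pos + len(exon_seq)))
            pieces.append(exon_seq)
            pos += len(exon_seq)
            if k < n_exons - 1:
                intron = random_dna(rng, int(rng.integers(*config.intron_length)))
                pieces.append(intron)
                pos += len(intron)
        pieces.append(random_dna(rng, pad))
        genomic = "".join(pieces)

        model = GeneModel(gene_id, "+")
        cds_start_t = utr5                      # transcript coords
        cds_end_t = utr5 + cds_len
        running_cds = 0
        for k, (gstart, gend) in enumerate(exon_spans):
            t0, t1 = int(bounds[k]), int(bounds[k + 1])
            # UTR5 part
            if t0 < cds_start_t:
                u_end = min(t1, cds_start_t)
                model.features.append(
                    GeneFeature("utr5", (gstart, gstart + (u_end - t0)))
                )
            # CDS part
            c0, c1 = max(t0, cds_start_t), min(t1, cds_end_t)
            if c0 < c1:
                g0 = gstart + (c0 - t0)
                model.features.append(
                    GeneFeature("cds", (g0, g0 + (c1 - c0)), frame=running_cds % 3)
                )
                running_cds += c1 - c0
            # UTR3 part
            if t1 > cds_end_t:
                u0 = max(t0, cds_end_t)
                g0 = gstart + (u0 - t0)
                model.features.append(GeneFeature("utr3", (g0, gstart + (t1 - t0))))
            if k < n_exons - 1:
                next_start = exon_spans[k + 1][0]
                model.features.append(GeneFeature("intron", (gend, next_start)))

        protein = str_translate(cds[:-3])
        genes.append(
            SimGene(
                gene_id=gene_id,
                genomic=SequenceRecord(gene_id, genomic),
                model=model,
                exons=[
                    SequenceRecord(f"{gene_id}|exon_{k}", genomic[s:e])
                    for k, (s, e) in enumerate(exon_spans)
                ],
                exon_spans=exon_spans,
                transcript=SequenceRecord(f"{gene_id}_t", transcript_bases),
                protein=SequenceRecord(f"{gene_id}|p", protein),
                is_x_linked=gi < n_x,
            )
        )
    return GeneSpace(config=config, genes=genes)


def str_translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def _mutate(bases: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(bases.encode(), dtype="S1").astype("U1").copy()
    for pos in positions:
        current = arr[pos]
        choices = [b for b in "ACGT" if b != current]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def evolve_species(
    space: GeneSpace,
    divergence: float | Mapping[str, float],
    theta: float,
    rng: np.random.Generator,
    species_id: str | None = None,
) -> Species:
    """Evolve the ancestor: substitutions at rate ``divergence`` (uniform,
    Jukes-Cantor-like, no back mutation), heterozygous sites at rate
    ``theta`` between the two haplotypes.

    ``divergence`` may be a per-gene mapping, emulating a design that mixes
    targets of very different divergence from the captured genome (e.g.
    close conspecific exons alongside anonymous intervals from a distant
    relative).
    """
    rates = (
        divergence
        if isinstance(divergence, Mapping)
        else {g.gene_id: float(divergence) for g in space.genes}
    )
    if not all(0 <= r <= 0.2 for r in rates.values()):
        raise ValueError("divergence must be in [0, 0.2]")
    hap_a: dict[str, str] = {}
    hap_b: dict[str, str] = {}
    mutations: dict[str, np.ndarray] = {}
    het_sites: dict[str, np.ndarray] = {}
    mutated = 0
    total = 0
    for gene in space.genes:
        bases = gene.genomic.bases
        length = len(bases)
        total += length
        sub_pos = np.nonzero(rng.random(length) < rates[gene.gene_id])[0]
        consensus = _mutate(bases, sub_pos, rng) if len(sub_pos) else bases
        if space.config.indel_fraction > 0:
            consensus = _apply_indels(
                consensus, divergence * space.config.indel_fraction, rng
            )
        het_pos = np.nonzero(rng.random(len(consensus)) < theta)[0]
        other = _mutate(consensus, het_pos, rng) if len(het_pos) else consensus
        hap_a[gene.gene_id] = consensus
        hap_b[gene.gene_id] = other
        mutations[gene.gene_id] = sub_pos
        het_sites[gene.gene_id] = het_pos
        mutated += len(sub_pos)
    mean_rate = float(np.mean(list(rates.values())))
    return Species(
        species_id=species_id or f"sp_d{mean_rate:g}",
        divergence=mean_rate,
        hap_a=hap_a,
        hap_b=hap_b,
        mutations=mutations,
        het_sites=het_sites,
        realized_divergence=mutated / total if total else 0.0,
    )


def _apply_indels(bases: str, rate: float, rng: np.random.Generator) -> str:
    """Single-base insertions/deletions for stress tests (coordinates shift)."""
    out = []
    for ch in bases:
        r = rng.random()
        if r < rate / 2:
            continue                          # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(_BASES[int(rng.integers(0, 4))])  # insertion
    return "".join(out)


# ---------------------------------------------------------------------------
# fragments

def _gc_penalty(gc: float, strength: float) -> float:
    return float(np.clip(1.0 - strength * (gc - 0.5) ** 2, 0.05, 1.0))


def simulate_fragments(
    species: Species,
    target_spans: Mapping[str, tuple[str, tuple[int, int]]],
    samples: Sequence[tuple[str, str]],            # (sample_id, sex)
    config: SimConfig,
    rng: np.random.Generator,
    design_gc: Mapping[str, float] | None = None,
    x_targets: frozenset | set = frozenset(),
) -> pd.DataFrame:
    """Captured fragment spans per sample, before read emission.

    Fragment counts per target are Poisson with mean
    ``mean_fragments_per_target`` scaled by sex dosage (males carry one X),
    thinned by the divergence/GC capture probability; off-target background
    fragments (never overlapping a target) are added at the configured
    fraction of the library.
    """
    if not target_spans:
        raise ValueError("no targets to capture")
    contig_lengths = species.contig_lengths()
    rows = []
    tids = list(target_spans)
    gc_by_target = design_gc or {}
    # per-target capture efficiency: a fixed property of the probe/target,
    # shared by every sample, library and species (the reproducibility signal)
    import zlib

    efficiency = {}
    for tid in tids:
        if config.target_efficiency_sd > 0:
            tid_rng = np.random.default_rng(
                (zlib.crc32(tid.encode()) ^ (config.seed * 0x9E3779B1)) & 0x7FFFFFFF
            )
            efficiency[tid] = float(
                tid_rng.lognormal(0.0, config.target_efficiency_sd)
            )
        else:
            efficiency[tid] = 1.0
    for sample_id, sex in samples:
        n_on = 0
        for tid in tids:
            contig, (t0, t1) = target_spans[tid]
            dosage = 0.5 if (tid in x_targets and sex == "M") else 1.0
            n = rng.poisson(
                config.mean_fragments_per_target * dosage * efficiency[tid]
            )
            if n == 0:
                continue
            lengths = np.clip(
                rng.normal(config.fragment_mean, config.fragment_sd, size=n),
                config.read_length + 20, 500,
            ).astype(int)
            starts = rng.integers(
                t0 - lengths + 30, t1 - 30, size=n
            )
            starts = np.clip(starts, 0, None)
            ends = np.minimum(starts + lengths, contig_lengths[contig])
            viable = ends - starts >= config.read_length
            starts, ends, lengths = starts[viable], ends[viable], lengths[viable]
            n = len(starts)
            if n == 0:
                continue
            # hybridization efficiency responds to the locus-scale divergence:
            # the contig-wide substitution density, not the Poisson-noisy
            # per-fragment mutation count (a short window would conflate
            # sampling noise with chemistry and flatten the decay curve)
            mut = species.mutations.get(contig, np.empty(0, dtype=int))
            d_locus = len(mut) / contig_lengths[contig]
            d_frag = np.full(len(starts), d_locus)
            p = np.minimum(
                1.0,
                np.exp(-config.capture_lambda * np.maximum(0.0, d_frag - config.capture_d0)),
            )
            if tid in gc_by_target:
                p = p * _gc_penalty(gc_by_target[tid], config.gc_penalty_strength)
            keep = rng.random(n) < p
            haps = rng.integers(0, 2, size=n)
            if tid in x_targets and sex == "M":
                haps[:] = 0                    # single X haplotype in males
            for s, e, d, h in zip(starts[keep], ends[keep], d_frag[keep], haps[keep]):
                rows.append((sample_id, contig, int(s), int(e), tid, float(d), int(h), True))
                n_on += 1
        # off-target background, placed to avoid every target span
        f = config.off_target_fraction
        n_off = round(f / (1 - f) * n_on) if f < 1 else 0
        spans_by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, span in target_spans.values():
            spans_by_contig.setdefault(contig, []).append(span)
        contigs = list(contig_lengths)
        emitted = 0
        attempts = 0
        while emitted < n_off and attempts < 50 * max(1, n_off):
            attempts += 1
            contig = contigs[int(rng.integers(0, len(contigs)))]
            length = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                                 config.read_length + 20, 500))
            if contig_lengths[contig] <= length:
                continue
            s = int(rng.integers(0, contig_lengths[contig] - length))
            e = s + length
            if any(s < b and a < e for a, b in spans_by_contig.get(contig, [])):
                continue
            rows.append((sample_id, contig, s, e, None, 0.0, int(rng.integers(0, 2)), False))
            emitted += 1
    return pd.DataFrame(
        rows,
        columns=["sample", "contig", "start", "end", "target_id", "d_frag", "hap", "in_target"],
    )


def coverage_matrix_from_fragments(
    fragments: pd.DataFrame,
    target_spans: Mapping[str, tuple[str, tuple[int, int]]],
) -> pd.DataFrame:
    """Per-target x per-sample mean base coverage from fragment spans."""
    samples = sorted(fragments["sample"].unique())
    out = pd.DataFrame(0.0, index=sorted(target_spans), columns=samples)
    grouped = fragments.groupby(["sample", "target_id"], dropna=True)
    for (sample, tid), grp in grouped:
        if tid not in target_spans:
            continue
        contig, (t0, t1) = target_spans[tid]
        overlap = (
            np.minimum(grp["end"].to_numpy(), t1)
            - np.maximum(grp["start"].to_numpy(), t0)
        ).clip(min=0)
        out.loc[tid, sample] = overlap.sum() / (t1 - t0)
    return out


# ---------------------------------------------------------------------------
# reads

@dataclass
class SimReads:
    pairs: list[ReadPair]
    alignments: list[AlignmentRecord]
    truth: pd.DataFrame
    contig_lengths: dict[str, int]
    barcode_map: dict[str, str] = field(default_factory=dict)


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> tuple[str, int]:
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if len(hits) == 0:
        return seq, 0
    arr = list(seq)
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return "".join(arr), len(hits)


def fragments_to_reads(
    fragments: pd.DataFrame,
    species: Species,
    config: SimConfig,
    rng: np.random.Generator,
    samples: Sequence[tuple[str, str]],
    contaminant: str | None = None,
) -> SimReads:
    """Emit paired reads (with errors, duplicates, contaminants, barcodes)
    plus truth alignments for every captured fragment."""
    rl = config.read_length
    qual = int(round(-10 * np.log10(config.error_rate)))
    barcode_map = {
        sample: DEFAULT_BARCODES[i % len(DEFAULT_BARCODES)]
        for i, (sample, _) in enumerate(samples)
    }
    if contaminant is None and config.contaminant_fraction > 0:
        contaminant = random_dna(rng, 20_000)

    pairs: list[ReadPair] = []
    alignments: list[AlignmentRecord] = []
    truth_rows = []
    quals = np.full(rl, qual, dtype=np.int32)

    def emit(pair_id, sample, contig, start, end, hap, tid, in_target,
             duplicate_of=None, contaminant_flag=False, bases=None):
        if bases is None:
            source = (species.hap_a if hap == 0 else species.hap_b)[contig]
            m1, _ = _apply_errors(source[start : start + rl], rng, config.error_rate)
            m2_fwd, _ = _apply_errors(source[end - rl : end], rng, config.error_rate)
            m2 = revcomp(m2_fwd)
        else:
            m1, m2 = bases
        pair = ReadPair(
            pair_id,
            SequenceRecord(f"{pair_id}/1", m1, quals.copy()),
            SequenceRecord(f"{pair_id}/2", m2, quals.copy()),
            barcode=barcode_map[sample],
            sample_id=sample,
        )
        pairs.append(pair)
        is_dup = duplicate_of is not None
        if not contaminant_flag:
            alignments.append(AlignmentRecord(
                f"{pair_id}/1", contig, start, m1, quals.copy(),
                is_unique=True, is_duplicate=is_dup, sample_id=sample,
            ))
            alignments.append(AlignmentRecord(
                f"{pair_id}/2", contig, end - rl, revcomp(m2), quals.copy(),
                is_unique=True, is_duplicate=is_dup, sample_id=sample,
            ))
        truth_rows.append((
            pair_id, sample, contig if not contaminant_flag else None,
            start, end, tid, in_target, duplicate_of, contaminant_flag,
        ))
        return pair

    serial = 0
    by_sample = dict(tuple(fragments.groupby("sample")))
    for sample, _sex in samples:
        sub = by_sample.get(sample)
        sample_pairs: list[tuple] = []
        if sub is not None:
            for row in sub.itertuples(index=False):
                pair_id = f"{sample}_{serial:07d}"
                serial += 1
                tid = None if pd.isna(row.target_id) else row.target_id
                pair = emit(pair_id, sample, row.contig, row.start, row.end,
                            row.hap, tid, bool(row.in_target))
                sample_pairs.append(
                    (pair, row.contig, row.start, row.end, row.hap, tid, bool(row.in_target))
                )
        # PCR duplicates: byte-identical re-emissions of captured pairs
        n_unique = len(sample_pairs)
        if config.duplicate_fraction > 0 and n_unique:
            f = config.duplicate_fraction
            n_dup = round(f / (1 - f) * n_unique)
            src_idx = rng.integers(0, n_unique, size=n_dup)
            for si in src_idx:
                src, contig, start, end, hap, tid, it = sample_pairs[si]
                pair_id = f"{sample}_{serial:07d}"
                serial += 1
                emit(pair_id, sample, contig, start, end, hap, tid, it,
                     duplicate_of=src.pair_id,
                     bases=(src.mate1.bases, src.mate2.bases))
        # contaminant pairs
        if config.contaminant_fraction > 0 and contaminant and n_unique:
            f = config.contaminant_fraction
            n_cont = round(f / (1 - f) * n_unique)
            for _ in range(n_cont):
                length = int(np.clip(
                    rng.normal(config.fragment_mean, config.fragment_sd), rl + 20, 500
                ))
                s = int(rng.integers(0, len(contaminant) - length))
                frag = contaminant[s : s + length]
                m1, _ = _apply_errors(frag[:rl], rng, config.error_rate)
                m2, _ = _apply_errors(revcomp(frag[-rl:]), rng, config.error_rate)
                pair_id = f"{sample}_{serial:07d}"
                serial += 1
                emit(pair_id, sample, None, -1, -1, 0, None, False,
                     contaminant_flag=True, bases=(m1, m2))

    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "sample", "contig", "start", "end",
                 "target_id", "in_target", "duplicate_of", "contaminant"],
    )
    return SimReads(
        pairs=pairs,
        alignments=alignments,
        truth=truth,
        contig_lengths=species.contig_lengths(),
        barcode_map=barcode_map,
    )


def simulate_capture_reads(
    species: Species,
    target_spans: Mapping[str, tuple[str, tuple[int, int]]],
    samples: Sequence[tuple[str, str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    design_gc: Mapping[str, float] | None = None,
    x_targets: frozenset | set = frozenset(),
    contaminant: str | None = None,
) -> SimReads:
    """Full read simulation: fragments -> paired reads + truth alignments."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fragments = simulate_fragments(
        species, target_spans, samples, config, rng,
        design_gc=design_gc, x_targets=x_targets,
    )
    return fragments_to_reads(fragments, species, config, rng, samples, contaminant)


def fragment_assemblies(
    species: Species,
    rng: np.random.Generator,
    n_assemblies: int = 2,
    chunk: int = 800,
    overlap: int = 200,
) -> list[list]:
    """Emulate multi-parameter raw assemblies by slicing each contig into
    overlapping chunks with assembly-specific phase offsets."""
    from .assembly import Contig

    out = []
    for ai in range(n_assemblies):
        contigs = []
        offset = int(rng.integers(0, overlap)) if ai else 0
        for cid, bases in species.hap_a.items():
            start = 0 if ai == 0 else offset
            idx = 0
            while start < len(bases):
                end = min(start + chunk, len(bases))
                if end - start >= 100:
                    contigs.append(
                        Contig(f"{cid}_a{ai}_c{idx}", bases[start:end], source=f"asm{ai}")
                    )
                idx += 1
                if end == len(bases):
                    break
                start = end - overlap
        out.append(contigs)
    return out


def write_multiplexed_fastq(sim: SimReads, path1, path2) -> None:
    """FASTQ with the 7-nt barcode inlined at the start of mate 1."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in sim.pairs:
            bc = pair.barcode or ""
            m1 = bc + pair.mate1.bases
            q1 = "".join(chr(q + 33) for q in
                         np.concatenate([np.full(len(bc), 40, dtype=int),
                                         pair.mate1.quals]))
            q2 = "".join(chr(q + 33) for q in pair.mate2.quals)
            f1.write(f"@{pair.pair_id}/1\n{m1}\n+\n{q1}\n")
            f2.write(f"@{pair.pair_id}/2\n{pair.mate2.bases}\n+\n{q2}\n")
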