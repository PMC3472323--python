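"""Filtered SNP detection and functional classification across species.

Reads of every species are aligned to one shared reference (the reference
species' in-target assemblies); candidate variant columns pass a depth
window (20–5000X) and a Phred-scaled site quality of at least 30.  Site
quality is computed from an explicit binomial error model: the probability
that all bases deviating from the reference arise from sequencing error at
the column's mean base-quality error rate.  Candidates are partitioned into
fixed differences (species consensus differs from the reference) and
polymorphic sites (two alleles segregating in the pooled species pileup),
then classified as synonymous / non-synonymous / intron / UTR against a
gene model with CDS reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import binom

from .capture_eval import Pileup
from .seqcore import revcomp

__all__ = [
    "CandidateSite",
    "SNPRecord",
    "GeneFeature",
    "GeneModel",
    "SNPSummary",
    "call_sites",
    "classify_zygosity",
    "classify_function",
    "summarize",
    "shared_orthologs",
    "write_vcf",
    "read_gene_models",
    "write_gene_models",
]

FUNC_CLASSES = ("synonymous", "non_synonymous", "intron", "utr")
STATUSES = ("fixed", "polymorphic")
MAX_SITE_QUALITY = 2000.0
_BASES = "ACGT"


@dataclass
class CandidateSite:
    contig_id: str
    position: int
    depth: int
    base_counts: np.ndarray        # A,C,G,T
    site_quality: float
    ref: str

    @property
    def consensus(self) -> str:
        return _BASES[int(np.argmax(self.base_counts))]


@dataclass
class SNPRecord:
    contig_id: str
    position: int
    ref: str
    alt: str
    species: str
    status: str                    # fixed | polymorphic
    func_class: str | None         # None = unclassified, excluded from summary
    depth: int
    site_quality: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")


@dataclass(frozen=True)
class GeneFeature:
    kind: str                      # cds | intron | utr5 | utr3
    span: tuple[int, int]
    frame: int = 0                 # codon offset of span start within the CDS


@dataclass
class GeneModel:
    """Exon/intron/UTR annotation of one contig (single transcript)."""

    contig_id: str
    strand: str
    features: list[GeneFeature] = field(default_factory=list)

    def cds_features(self) -> list[GeneFeature]:
        feats = [f for f in self.features if f.kind == "cds"]
        return sorted(feats, key=lambda f: f.span[0], reverse=self.strand == "-")

    def feature_at(self, position: int) -> GeneFeature | None:
        for f in self.features:
            if f.span[0] <= position < f.span[1]:
                return f
        return None


def call_sites(
    pileup: Pileup,
    reference: Mapping[str, str],
    min_depth: int = 20,
    max_depth: int = 5000,
    min_site_quality: float = 30.0,
) -> list[CandidateSite]:
    """Candidate variant columns passing depth and site-quality filters.

    Site quality is −10·log10 of the binomial tail probability of seeing at
    least the observed number of non-reference bases by sequencing error
    alone, at the column's mean base-quality error rate (capped at 2000).
    Pileups must already be restricted to uniquely mapped reads.
    """
    out: list[CandidateSite] = []
    for contig, counts in pileup.base_counts.items():
        refseq = reference.get(contig)
        if refseq is None:
            continue
        acgt = counts[:4]
        depth = acgt.sum(axis=0)
        err = pileup.err_sum.get(contig)
        candidates = np.nonzero((depth >= min_depth) & (depth <= max_depth))[0]
        for pos in candidates:
            ref_base = refseq[pos].upper()
            if ref_base not in _BASES:
                continue
            d = int(depth[pos])
            col = acgt[:, pos]
            k = d - int(col[_BASES.index(ref_base)])
            if k == 0:
                continue
            e = float(err[pos]) / d if err is not None and err[pos] > 0 else None
            if e is None or e <= 0:
                e = 1e-3
            tail = float(binom.sf(k - 1, d, min(e, 0.75)))
            quality = MAX_SITE_QUALITY if tail <= 0 else min(
                MAX_SITE_QUALITY, -10.0 * np.log10(tail)
            )
            if quality >= min_site_quality:
                out.append(
                    CandidateSite(
                        contig_id=contig,
                        position=int(pos),
                        depth=d,
                        base_counts=col.copy(),
                        site_quality=quality,
                        ref=ref_base,
                    )
                )
    return out


def classify_zygosity(
    site: CandidateSite,
    alt_frac_poly: float = 0.2,
    consensus_frac: float = 0.9,
) -> str:
    """Partition a candidate column: polymorphic, fixed, or invariant.

    Polymorphic when a second allele reaches >= 2 reads and >=
    ``alt_frac_poly`` of the column; fixed when the species consensus
    allele (>= ``consensus_frac``) differs from the reference base.
    """
    counts = np.sort(site.base_counts)[::-1]
    second = int(counts[1])
    if second >= 2 and second >= alt_frac_poly * site.depth:
        return "polymorphic"
    top = int(counts[0])
    if top >= consensus_frac * site.depth and site.consensus != site.ref:
        return "fixed"
    return "invariant"


def site_alt(site: CandidateSite) -> str:
    """The alternate allele: the top non-reference base of the column."""
    order = np.argsort(site.base_counts)[::-1]
    for idx in order:
        if _BASES[idx] != site.ref:
            return _BASES[idx]
    raise ValueError("no non-reference allele")


def classify_function(
    contig_seq: str,
    position: int,
    ref: str,
    alt: str,
    model: GeneModel,
) -> str | None:
    """synonymous / non_synonymous / intron / utr by the gene model.

    CDS positions are translated in the annotated frame with the standard
    genetic code, substituting ``alt`` for ``ref``; identical amino acids
    are synonymous.  Positions in no feature return ``None``.
    """
    feature = model.feature_at(position)
    if feature is None:
        return None
    if feature.kind == "intron":
        return "intron"
    if feature.kind in ("utr5", "utr3"):
        return "utr"

    cds_feats = model.cds_features()
    cds_offset = None
    running = 0
    for f in cds_feats:
        span_len = f.span[1] - f.span[0]
        if f.span[0] <= position < f.span[1]:
            if model.strand == "+":
                cds_offset = running + (position - f.span[0])
            else:
                cds_offset = running + (f.span[1] - 1 - position)
            break
        running += span_len
    if cds_offset is None:
        return None

    def spliced(seq: str) -> str:
        parts = [seq[f.span[0] : f.span[1]] for f in cds_feats] \
            if model.strand == "+" else \
            [revcomp(seq[f.span[0] : f.span[1]]) for f in cds_feats]
        return "".join(parts)

    ref_base = ref if model.strand == "+" else revcomp(ref)
    alt_base = alt if model.strand == "+" else revcomp(alt)
    cds = spliced(contig_seq)
    if cds_offset >= len(cds):
        return None
    codon_start = 3 * (cds_offset // 3)
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3:
        return None
    within = cds_offset - codon_start
    if codon[within].upper() != ref_base.upper():
        # tolerate reference disagreement but substitute anyway
        pass
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "non_synonymous"


@dataclass
class SNPSummary:
    """Cross-tab of SNP counts: status x functional class, per species."""

    counts: pd.DataFrame   # index (species, status), columns FUNC_CLASSES

    @classmethod
    def from_counts(
        cls, per_species: Mapping[str, Mapping[str, Mapping[str, int]]]
    ) -> "SNPSummary":
        """Build from nested {species: {status: {func_class: count}}}."""
        rows = {}
        for species, statuses in per_species.items():
            for status in STATUSES:
                cells = statuses.get(status, {})
                rows[(species, status)] = [
                    int(cells.get(fc, 0)) for fc in FUNC_CLASSES
                ]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=FUNC_CLASSES)
        df.index = pd.MultiIndex.from_tuples(df.index, names=["species", "status"])
        return cls(df.sort_index())

    def status_total(self, species: str, status: str) -> int:
        return int(self.counts.loc[(species, status)].sum())

    def total_difference(self, species: str) -> pd.Series:
        """Fixed + polymorphic per functional class."""
        sub = self.counts.loc[species]
        return sub.sum(axis=0)

    def grand_total(self, species: str) -> int:
        return int(self.total_difference(species).sum())

    def percentages(self, species: str) -> pd.Series:
        """Total-difference percentages per class, 1 decimal place."""
        td = self.total_difference(species)
        total = td.sum()
        return (100.0 * td / total).round(1) if total else td * 0.0

    def to_table(self) -> pd.DataFrame:
        """Long-format table mirroring the per-species SNP summary layout."""
        rows = []
        for species in self.counts.index.get_level_values(0).unique():
            for status in STATUSES:
                for fc in FUNC_CLASSES:
                    rows.append(
                        (species, status, fc, int(self.counts.loc[(species, status), fc]))
                    )
                rows.append((species, status, "total", self.status_total(species, status)))
            pct = self.percentages(species)
            for fc in FUNC_CLASSES:
                rows.append((species, "total_difference", f"{fc}_pct", float(pct[fc])))
            rows.append((species, "total_difference", "total", self.grand_total(species)))
        return pd.DataFrame(rows, columns=["species", "status", "class", "value"])


def summarize(records: Iterable[SNPRecord]) -> SNPSummary:
    """Cross-tab classified SNP records into a summary table."""
    nested: dict[str, dict[str, dict[str, int]]] = {}
    for rec in records:
        if rec.func_class is None:
            continue
        cell = nested.setdefault(rec.species, {}).setdefault(rec.status, {})
        cell[rec.func_class] = cell.get(rec.func_class, 0) + 1
    return SNPSummary.from_counts(nested)


def shared_orthologs(in_target_maps: Mapping[str, object]) -> list[str]:
    """Targets present in every species' in-target map (set intersection).

    Each map is an :class:`~exocap.assembly.InTargetAssembly` (or anything
    exposing target ids via ``hits`` or iteration).
    """
    if len(in_target_maps) < 2:
        raise ValueError("need at least two species")
    sets = []
    for mapping in in_target_maps.values():
        ids = set(mapping.hits) if hasattr(mapping, "hits") else set(mapping)
        sets.append(ids)
    shared = set.intersection(*sets)
    return sorted(shared)


# ---------------------------------------------------------------------------
# I/O

def write_vcf(records: Sequence[SNPRecord], path: str | Path) -> None:
    """Minimal single-species VCFv4.2; INFO carries status and class."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="fixed or polymorphic">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="functional class">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.contig_id, r.position)):
            info = (
                f"STATUS={rec.status};CLASS={rec.func_class or 'unclassified'};"
                f"DP={rec.depth}"
            )
            fh.write(
                f"{rec.contig_id}\t{rec.position + 1}\t.\t{rec.ref}\t{rec.alt}\t"
                f"{rec.site_quality:.1f}\tPASS\t{info}\n"
            )


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """GFF-like TSV: contig, kind, start, end, strand, frame."""
    with open(path, "w") as fh:
        fh.write("contig_id\tkind\tstart\tend\tstrand\tframe\n")
        for model in models:
            for f in model.features:
                fh.write(
                    f"{model.contig_id}\t{f.kind}\t{f.span[0]}\t{f.span[1]}\t"
                    f"{model.strand}\t{f.frame}\n"
                )


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            contig, kind, start, end, strand, frame = line.rstrip("\n").split("\t")
            model = models.setdefault(contig, GeneModel(contig, strand))
            model.features.append(
                GeneFeature(kind, (int(start), int(end)), int(frame))
            )
    return models
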