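"""Capture-target definition from annotated transcripts.

Transcript contigs from a de novo transcriptome are annotated by translated
local alignment against a reference protein set, exon boundaries are
transferred onto each transcript by aligning reference exon sequences to it,
and the accepted exons (plus extra target classes: mitochondrial tiles,
anonymous genomic intervals, SRY, control genes) are assembled into the
target set the probe designer tiles.  The module also computes transcriptome
QC statistics: CDS-completeness classes, premature stop codons, and chimeric
contigs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio.Seq import Seq

from .seqcore import (
    AlignScoring,
    PairwiseAlignment,
    SequenceRecord,
    local_align,
    revcomp,
)

__all__ = [
    "TranscriptAnnotation",
    "ExonTarget",
    "TargetSet",
    "CLASS_TILING_STEP",
    "COMPLETENESS_CLASSES",
    "annotate_transcript",
    "transfer_exon_boundaries",
    "build_target_set",
    "detect_premature_stop",
    "detect_chimeric_contig",
    "write_targets_bed",
    "write_qc_table",
]

COMPLETENESS_CLASSES = (
    "full_cds",
    "partial_cds_3utr",
    "partial_cds_5utr",
    "partial_cds_only",
)

#: default tiling step (bp between probe starts) per target class
CLASS_TILING_STEP = {
    "nuclear_exon": 4,
    "mito": 20,
    "genomic_interval": 2,
    "sry": 1,
    "control_gene": 4,
}

CLASS_CODES = {name: i for i, name in enumerate(CLASS_TILING_STEP)}

# identity-based protein scoring for translated search
PROTEIN_SCORING = AlignScoring(match=1.0, mismatch=-2.0, gap_open=-6.0, gap_extend=-1.0)


@dataclass
class TranscriptAnnotation:
    """Best protein hit of a transcript plus the derived CDS geometry."""

    transcript_id: str
    best_protein_id: str
    frame: int                      # 0-2 on the (possibly reversed) transcript
    strand: str                     # '+' or '-'
    cds_span: tuple[int, int]       # half-open, forward-strand transcript coords
    completeness: str
    score: float

    def __post_init__(self) -> None:
        if self.completeness not in COMPLETENESS_CLASSES:
            raise ValueError(f"unknown completeness class {self.completeness!r}")


@dataclass
class ExonTarget:
    """A capture target: a slice of a source sequence plus its class."""

    target_id: str
    source_seq_id: str
    span: tuple[int, int]
    sequence: str
    target_class: str = "nuclear_exon"

    def __post_init__(self) -> None:
        if self.target_class not in CLASS_TILING_STEP:
            raise ValueError(f"unknown target class {self.target_class!r}")
        if len(self.sequence) != self.span[1] - self.span[0]:
            raise ValueError(f"{self.target_id}: sequence length != span length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def tiling_step(self) -> int:
        return CLASS_TILING_STEP[self.target_class]


@dataclass
class TargetSet:
    """Ordered targets with design-provenance counters."""

    targets: list[ExonTarget]
    min_length: int = 200
    dropped_short: int = 0
    dropped_duplicate: int = 0

    def __post_init__(self) -> None:
        ids = [t.target_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target_id in TargetSet")

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(self.targets)

    def by_class(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.targets:
            counts[t.target_class] = counts.get(t.target_class, 0) + 1
        return counts


def _protein_hit(
    contig: SequenceRecord,
    protein: SequenceRecord,
    scoring: AlignScoring,
) -> tuple[PairwiseAlignment, int, str] | None:
    """Best translated hit of a contig vs one protein over all six frames."""
    from .seqcore import iter_translations

    best: tuple[PairwiseAlignment, int, str] | None = None
    for frame, strand, aa in iter_translations(contig.bases):
        if not aa:
            continue
        aln = local_align(
            SequenceRecord(f"{contig.id}|{strand}{frame}", aa),
            protein,
            scoring,
            protein=True,
        )
        if aln is None:
            continue
        if best is None or aln.score > best[0].score:
            best = (aln, frame, strand)
    return best


def _cds_span_on_transcript(
    aln: PairwiseAlignment, frame: int, strand: str, transcript_len: int
) -> tuple[int, int]:
    """Map an amino-acid alignment span back to forward-strand nt coords."""
    aa_start, aa_end = aln.query_span
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return transcript_len - nt_end, transcript_len - nt_start


def _classify_completeness(
    aln: PairwiseAlignment, protein_len: int, end_slack: int = 2
) -> str:
    p_start, p_end = aln.ref_span
    has_start = p_start <= end_slack
    has_end = p_end >= protein_len - end_slack
    if has_start and has_end:
        return "full_cds"
    if has_end:
        return "partial_cds_3utr"   # stop reached; truncated 5' side
    if has_start:
        return "partial_cds_5utr"   # start reached; truncated 3' side
    return "partial_cds_only"


def annotate_transcript(
    contig: SequenceRecord,
    proteins: Sequence[SequenceRecord],
    min_score: float = 50.0,
    scoring: AlignScoring = PROTEIN_SCORING,
) -> TranscriptAnnotation | None:
    """Annotate a transcript by six-frame translated search against proteins.

    The best-scoring protein above ``min_score`` wins (ties: first protein
    in input order).  Returns ``None`` when nothing scores high enough.
    """
    if not proteins:
        raise ValueError("protein set must be non-empty")
    best: tuple[PairwiseAlignment, int, str, SequenceRecord] | None = None
    for protein in proteins:
        hit = _protein_hit(contig, protein, scoring)
        if hit is None:
            continue
        aln, frame, strand = hit
        if aln.score >= min_score and (best is None or aln.score > best[0].score):
            best = (aln, frame, strand, protein)
    if best is None:
        return None
    aln, frame, strand, protein = best
    return TranscriptAnnotation(
        transcript_id=contig.id,
        best_protein_id=protein.id,
        frame=frame,
        strand=strand,
        cds_span=_cds_span_on_transcript(aln, frame, strand, len(contig)),
        completeness=_classify_completeness(aln, len(protein)),
        score=aln.score,
    )


def transfer_exon_boundaries(
    transcript: SequenceRecord,
    reference_exons: Sequence[SequenceRecord],
    min_coverage: float = 0.8,
    min_identity: float = 0.7,
    scoring: AlignScoring = AlignScoring(),
) -> list[ExonTarget]:
    """Place reference exon boundaries onto a transcript by local alignment.

    Each reference exon (given in gene order) is aligned to the transcript
    and accepted when the alignment covers ``min_coverage`` of the exon at
    ``min_identity``.  Accepted spans must be non-overlapping and colinear
    with exon order; conflicts are resolved by dropping the lower-scoring
    exon.  Unplaced exons are silently omitted (e.g. a truncated transcript).
    """
    candidates: list[tuple[float, int, tuple[int, int], SequenceRecord]] = []
    for idx, exon in enumerate(reference_exons):
        aln = local_align(transcript, exon, scoring)
        if aln is None:
            continue
        coverage = aln.alignable_bases / len(exon)
        if coverage >= min_coverage and aln.identity >= min_identity:
            candidates.append((aln.score, idx, aln.query_span, exon))

    kept: list[tuple[int, tuple[int, int], SequenceRecord]] = []
    for score, idx, span, exon in sorted(candidates, key=lambda c: (-c[0], c[1])):
        compatible = all(
            (span[1] <= k_span[0] or span[0] >= k_span[1])  # non-overlapping
            and ((idx < k_idx) == (span[0] < k_span[0]))    # colinear
            for k_idx, k_span, _ in kept
        )
        if compatible:
            kept.append((idx, span, exon))

    kept.sort(key=lambda k: k[1][0])
    out = []
    for idx, span, exon in kept:
        out.append(
            ExonTarget(
                target_id=f"{transcript.id}|{exon.id}",
                source_seq_id=transcript.id,
                span=span,
                sequence=transcript.bases[span[0] : span[1]],
            )
        )
    starts = [t.span for t in out]
    if any(a[1] > b[0] for a, b in zip(starts, starts[1:])):
        raise RuntimeError("overlapping exon spans after conflict resolution")
    return out


def build_target_set(
    exon_lists: Iterable[Sequence[ExonTarget]],
    extra_targets: Sequence[ExonTarget] = (),
    min_length: int = 200,
) -> TargetSet:
    """Assemble the multi-class target set for array design.

    Nuclear exons shorter than ``min_length`` are dropped (counted); extra
    classes pass unfiltered; exact-sequence duplicates are removed, first
    occurrence kept.
    """
    dropped_short = 0
    dropped_dup = 0
    seen_seqs: set[str] = set()
    seen_ids: set[str] = set()
    out: list[ExonTarget] = []

    def admit(t: ExonTarget) -> None:
        nonlocal dropped_dup
        if t.target_id in seen_ids:
            raise ValueError(f"duplicate target_id {t.target_id!r}")
        seen_ids.add(t.target_id)
        if t.sequence in seen_seqs:
            dropped_dup += 1
            return
        seen_seqs.add(t.sequence)
        out.append(t)

    for exons in exon_lists:
        for t in exons:
            if len(t) < min_length:
                dropped_short += 1
            else:
                admit(t)
    for t in extra_targets:
        admit(t)

    return TargetSet(
        targets=out,
        min_length=min_length,
        dropped_short=dropped_short,
        dropped_duplicate=dropped_dup,
    )


def detect_premature_stop(
    transcript: SequenceRecord, annotation: TranscriptAnnotation
) -> bool:
    """True iff an in-frame stop occurs strictly before the final CDS codon."""
    start, end = annotation.cds_span
    if end - start < 3:
        raise ValueError("CDS span shorter than one codon")
    cds = transcript.bases[start:end]
    if annotation.strand == "-":
        cds = revcomp(cds)
    cds = cds[: 3 * (len(cds) // 3)]
    aa = str(Seq(cds).translate())
    return "*" in aa[:-1]


def detect_chimeric_contig(
    contig: SequenceRecord,
    proteins: Sequence[SequenceRecord],
    min_score: float = 50.0,
    gene_of: Callable[[str], str] = lambda pid: pid.split("|")[0],
    max_overlap_frac: float = 0.1,
    scoring: AlignScoring = PROTEIN_SCORING,
) -> bool:
    """True iff two different genes hit non-overlapping spans of the contig.

    All protein hits above ``min_score`` are kept; two hits from different
    genes whose contig spans overlap by less than ``max_overlap_frac`` of
    the shorter span mark the contig as chimeric (spuriously merged).
    """
    hits: list[tuple[str, tuple[int, int]]] = []
    for protein in proteins:
        hit = _protein_hit(contig, protein, scoring)
        if hit is None or hit[0].score < min_score:
            continue
        aln, frame, strand = hit
        span = _cds_span_on_transcript(aln, frame, strand, len(contig))
        hits.append((gene_of(protein.id), span))
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            (ga, sa), (gb, sb) = hits[i], hits[j]
            if ga == gb:
                continue
            overlap = max(0, min(sa[1], sb[1]) - max(sa[0], sb[0]))
            shorter = min(sa[1] - sa[0], sb[1] - sb[0])
            if shorter > 0 and overlap < max_overlap_frac * shorter:
                return True
    return False


# ---------------------------------------------------------------------------
# tabular output

def write_targets_bed(target_set: TargetSet, path: str | Path) -> None:
    """Targets as 0-based half-open BED; score column carries the class code."""
    with open(path, "w") as fh:
        for t in target_set:
            fh.write(
                f"{t.source_seq_id}\t{t.span[0]}\t{t.span[1]}\t"
                f"{t.target_id}\t{CLASS_CODES[t.target_class]}\t+\n"
            )


def write_qc_table(
    rows: Iterable[dict], path: str | Path
) -> None:
    """Per-transcript QC TSV: completeness, premature-stop and chimera flags."""
    rows = list(rows)
    fields = ["transcript_id", "completeness", "premature_stop", "chimeric"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in fields})
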