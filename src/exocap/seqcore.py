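"""Shared sequence primitives for the exon-capture toolkit.

Everything downstream — probe tiling, read cleanup, in-target assembly
identification, capture metrics, SNP calling — is built on a small set of
operations defined here: affine-gap local alignment, pairwise divergence,
double-stranded k-mer counting, GC content, and Phred conversions.

Alignment runs on :class:`Bio.Align.PairwiseAligner` in local mode with a
substitution matrix over ``ACGTN`` in which ``N`` never matches anything
(including itself): treating ambiguous bases as mismatches keeps divergence
estimates conservative.  Coordinates are 0-based half-open throughout; the
1-based convention appears only at SAM/VCF boundaries.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "AlignScoring",
    "PairwiseAlignment",
    "KmerTable",
    "UndefinedDivergenceError",
    "UndefinedGCError",
    "local_align",
    "percent_divergence",
    "count_kmers",
    "gc_fraction",
    "phred_from_error",
    "error_from_phred",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "iter_translations",
]

GAP = "-"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


class UndefinedDivergenceError(ValueError):
    """Divergence requested for an alignment with zero alignable bases."""


class UndefinedGCError(ValueError):
    """GC fraction requested for a sequence with no unambiguous bases."""


@dataclass
class SequenceRecord:
    """A named DNA (or protein) sequence with optional Phred qualities."""

    id: str
    bases: str
    quals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.quals is not None:
            self.quals = np.asarray(self.quals, dtype=np.int32)
            if len(self.quals) != len(self.bases):
                raise ValueError(
                    f"{self.id}: {len(self.quals)} qualities for "
                    f"{len(self.bases)} bases"
                )
            if (self.quals < 0).any():
                raise ValueError(f"{self.id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int, id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(
            id or f"{self.id}[{start}:{end}]",
            self.bases[start:end],
            None if self.quals is None else self.quals[start:end],
        )

    def reverse_complement(self, id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(
            id or self.id,
            revcomp(self.bases),
            None if self.quals is None else self.quals[::-1],
        )


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring; defaults are BLAST-like (1/−2, open −4, extend −1).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("require match>0, mismatch<0, gap penalties<0")


@dataclass
class PairwiseAlignment:
    """A gapped local alignment between a query and a reference sequence.

    ``columns`` lists ``(query_base, ref_base)`` pairs where either side may
    be the gap character ``-``.  Alignable columns are those with a residue
    on both sides; gap columns are excluded from both the mismatch count and
    the divergence denominator.
    """

    query_id: str
    ref_id: str
    columns: list[tuple[str, str]]
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    score: float

    @property
    def alignable_bases(self) -> int:
        return sum(1 for q, r in self.columns if q != GAP and r != GAP)

    @property
    def mismatches(self) -> int:
        # N never matches, including against itself
        return sum(
            1
            for q, r in self.columns
            if q != GAP and r != GAP and (q != r or q == "N")
        )

    @property
    def identity(self) -> float:
        ab = self.alignable_bases
        return (ab - self.mismatches) / ab if ab else 0.0

    @property
    def length(self) -> int:
        return len(self.columns)

    def swapped(self) -> "PairwiseAlignment":
        """The same alignment with query and reference roles exchanged."""
        return PairwiseAlignment(
            query_id=self.ref_id,
            ref_id=self.query_id,
            columns=[(r, q) for q, r in self.columns],
            query_span=self.ref_span,
            ref_span=self.query_span,
            score=self.score,
        )

    def pretty(self, width: int = 60) -> str:
        q = "".join(c[0] for c in self.columns)
        r = "".join(c[1] for c in self.columns)
        m = "".join(
            "|" if a == b and a != GAP and a != "N" else " " for a, b in zip(q, r)
        )
        out = [f"{self.query_id} vs {self.ref_id}  score={self.score:g}"]
        for i in range(0, len(q), width):
            out += [q[i : i + width], m[i : i + width], r[i : i + width], ""]
        return "\n".join(out)

    def to_row(self) -> dict:
        return {
            "query": self.query_id,
            "ref": self.ref_id,
            "query_start": self.query_span[0],
            "query_end": self.query_span[1],
            "ref_start": self.ref_span[0],
            "ref_end": self.ref_span[1],
            "mismatches": self.mismatches,
            "alignable": self.alignable_bases,
            "divergence": percent_divergence(self),
            "score": self.score,
        }


def _dna_matrix(scoring: AlignScoring) -> Align.substitution_matrices.Array:
    alphabet = "ACGTN"
    m = Align.substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                m[a, b] = scoring.match
            else:
                m[a, b] = scoring.mismatch
    return m


def _make_aligner(scoring: AlignScoring, protein: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if protein:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        aligner.wildcard = None
    else:
        aligner.substitution_matrix = _dna_matrix(scoring)
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _gapped_strings(alignment) -> tuple[str, str]:
    # alignment[0] is the gapped target (our query a), alignment[1] the query b
    return str(alignment[0]), str(alignment[1])


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignScoring = AlignScoring(),
    protein: bool = False,
) -> PairwiseAlignment | None:
    """Best-scoring affine-gap local alignment of ``a`` (query) vs ``b`` (ref).

    Returns ``None`` when no positive-scoring local alignment exists.
    Ties are broken deterministically (the aligner enumerates co-optimal
    alignments in a fixed order; the first is taken).
    """
    if isinstance(a, str):
        a = SequenceRecord("a", a)
    if isinstance(b, str):
        b = SequenceRecord("b", b)
    if not a.bases or not b.bases:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(scoring, protein)
    score = aligner.score(a.bases, b.bases)
    if score <= 0:
        return None
    aln = aligner.align(a.bases, b.bases)[0]
    qs, rs = _gapped_strings(aln)
    columns = [(x, y) for x, y in zip(qs, rs)]
    # trim leading/trailing all-gap columns if any (defensive; local should not)
    (astart, aend) = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    (bstart, bend) = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    return PairwiseAlignment(
        query_id=a.id,
        ref_id=b.id,
        columns=columns,
        query_span=(astart, aend),
        ref_span=(bstart, bend),
        score=float(score),
    )


def percent_divergence(aln: PairwiseAlignment) -> float:
    """Mismatches divided by alignable bases; gap columns excluded from both."""
    ab = aln.alignable_bases
    if ab == 0:
        raise UndefinedDivergenceError(
            f"{aln.query_id} vs {aln.ref_id}: no alignable bases"
        )
    return aln.mismatches / ab


@dataclass
class KmerTable:
    """Occurrence counts of all k-mers on both strands of a sequence set.

    Each window contributes its literal forward k-mer and the reverse
    complement k-mer from the opposite strand (no canonicalization).
    Windows containing ``N`` are skipped and tallied in ``skipped``.
    """

    k: int
    counts: Counter = field(default_factory=Counter)
    skipped: int = 0

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def frequency(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_kmers(seqs: Iterable[SequenceRecord | str], k: int) -> KmerTable:
    """Count all k-mers on both strands of every sequence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    table = KmerTable(k=k)
    for seq in seqs:
        bases = seq if isinstance(seq, str) else seq.bases
        for strand in (bases.upper(), revcomp(bases.upper())):
            for i in range(len(strand) - k + 1):
                kmer = strand[i : i + k]
                if "N" in kmer:
                    table.skipped += 1
                else:
                    table.counts[kmer] += 1
    return table


def gc_fraction(seq: SequenceRecord | str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator."""
    bases = (seq if isinstance(seq, str) else seq.bases).upper()
    if not bases:
        raise ValueError("empty sequence")
    counts = Counter(bases)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise UndefinedGCError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def phred_from_error(e: float) -> float:
    """Phred quality Q = −10·log10(e) for an error probability e in (0, 1]."""
    if not 0 < e <= 1:
        raise ValueError(f"error probability must be in (0, 1], got {e}")
    return -10.0 * math.log10(e)


def error_from_phred(q: float) -> float:
    """Error probability 10^(−Q/10) for a quality score Q ≥ 0."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed, wrapped at 60 columns)

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), 60):
                fh.write(rec.bases[i : i + 60] + "\n")


def iter_translations(bases: str) -> Iterator[tuple[int, str, str]]:
    """Six-frame translations as (frame 0-2, strand '+'/'-', amino acids)."""
    for strand, seq in (("+", bases), ("-", revcomp(bases))):
        for frame in range(3):
            sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            if sub:
                yield frame, strand, str(Seq(sub).translate())
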