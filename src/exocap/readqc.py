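"""Pre-analysis filtration of multiplexed capture reads.

Stages, in pipeline order: demultiplex by 7-nt inline barcode, remove exact
PCR duplicates (identical forward AND reverse read), trim adapters and
low-quality 3' tails, reject low-complexity reads, screen against
contaminant genomes by shared 21-mers.  Counts telescope through a
:class:`FilterReport` so the fraction of raw reads surviving all filters is
directly comparable between libraries.

No quality-score recalibration is performed; the empirical error rate from
haploid loci (see :mod:`exocap.capture_eval`) is the intended check on raw
qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .seqcore import KmerTable, SequenceRecord

__all__ = [
    "ReadPair",
    "FilterReport",
    "demultiplex",
    "remove_exact_duplicates",
    "clean_read_pair",
    "contaminant_screen",
    "quality_summary",
    "subsample_pairs",
    "run_filters",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_barcode_map",
]

BARCODE_LENGTH = 7


@dataclass
class ReadPair:
    """A paired read; the unit of all filtration."""

    pair_id: str
    mate1: SequenceRecord
    mate2: SequenceRecord
    barcode: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.barcode is not None and len(self.barcode) != BARCODE_LENGTH:
            raise ValueError(f"{self.pair_id}: barcode must be {BARCODE_LENGTH} nt")

    def key(self) -> tuple[str, str]:
        return (self.mate1.bases, self.mate2.bases)


@dataclass
class FilterReport:
    """Telescoping per-stage read-pair counts."""

    input: int = 0
    duplicates: int = 0
    adapter_trimmed: int = 0      # informational; trimmed pairs still pass
    quality_trimmed: int = 0      # informational
    too_short: int = 0
    low_complexity: int = 0
    contaminant: int = 0
    passed: int = 0

    @property
    def removed(self) -> int:
        return self.duplicates + self.too_short + self.low_complexity + self.contaminant

    @property
    def fraction_passed(self) -> float:
        return self.passed / self.input if self.input else 0.0

    def check_telescoping(self) -> None:
        if self.input != self.passed + self.removed:
            raise AssertionError("filter counts do not telescope")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for name in (
                "input", "duplicates", "adapter_trimmed", "quality_trimmed",
                "too_short", "low_complexity", "contaminant", "passed",
            ):
                fh.write(f"{name}\t{getattr(self, name)}\n")
            fh.write(f"fraction_passed\t{self.fraction_passed:.4f}\n")


def _hamming(a: str, b: str) -> int:
    # N never matches a barcode base
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def demultiplex(
    pairs: Iterable[ReadPair],
    barcode_map: dict[str, str],
    max_mismatch: int = 0,
    inline: bool = True,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign pairs to samples by their 7-nt barcode.

    With ``inline=True`` the barcode is read from (and stripped off) the
    first 7 bases of mate 1.  A pair is assigned only when exactly one
    sample barcode matches within ``max_mismatch``; otherwise it lands in
    the unassigned pool.  Barcodes that could collide under the allowed
    mismatch count are a configuration error.
    """
    barcodes = list(barcode_map.items())
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            if _hamming(barcodes[i][1], barcodes[j][1]) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes {barcodes[i][1]} and {barcodes[j][1]} collide "
                    f"at max_mismatch={max_mismatch}"
                )
    assigned: dict[str, list[ReadPair]] = {s: [] for s in barcode_map}
    unassigned: list[ReadPair] = []
    for pair in pairs:
        observed = pair.barcode
        if observed is None:
            observed = pair.mate1.bases[:BARCODE_LENGTH]
        matches = [
            sample
            for sample, bc in barcodes
            if _hamming(observed, bc) <= max_mismatch
        ]
        if len(matches) != 1:
            unassigned.append(pair)
            continue
        sample = matches[0]
        if inline and pair.barcode is None:
            pair = ReadPair(
                pair.pair_id,
                pair.mate1.slice(BARCODE_LENGTH, len(pair.mate1), id=pair.mate1.id),
                pair.mate2,
                barcode=observed,
            )
        else:
            pair.barcode = observed
        pair.sample_id = sample
        assigned[sample].append(pair)
    return assigned, unassigned


def remove_exact_duplicates(
    pairs: Sequence[ReadPair],
) -> tuple[list[ReadPair], int]:
    """Collapse pairs with identical forward AND reverse bases.

    The first occurrence in input order is kept; order is preserved.
    """
    seen: set[tuple[str, str]] = set()
    unique: list[ReadPair] = []
    duplicates = 0
    for pair in pairs:
        key = pair.key()
        if key in seen:
            duplicates += 1
        else:
            seen.add(key)
            unique.append(pair)
    return unique, duplicates


def _find_adapter(bases: str, adapter: str, min_overlap: int = 10,
                  max_mismatch_frac: float = 0.10) -> int | None:
    """Leftmost position where a 3' adapter occurrence starts, or None.

    An occurrence is a prefix of the adapter matching the read suffix with
    at least ``min_overlap`` bases and at most 10% mismatches.
    """
    n = len(bases)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        window = bases[i : i + overlap]
        mism = sum(1 for a, b in zip(window, adapter) if a != b)
        if mism <= max_mismatch_frac * overlap:
            return i
    return None


def _quality_trim_point(quals: np.ndarray, min_q: int) -> int:
    """3' trim point by BWA-style running sum of (min_q - q) from the end.

    Returns the length to keep: the position maximizing the badness sum
    from there to the end, or the full length when no suffix is bad.
    """
    deficit = min_q - quals[::-1].astype(np.int64)
    sums = np.cumsum(deficit)
    best = int(np.max(sums))
    if best <= 0:
        return len(quals)
    cut = int(np.argmax(sums)) + 1
    return len(quals) - cut


def _dust_score(bases: str, window: int = 64) -> float:
    """Maximum DUST-style triplet score over sliding windows."""
    best = 0.0
    n = len(bases)
    step = max(1, window // 2)
    starts = range(0, max(1, n - 2), step) if n <= window else range(0, n - window + 1, step)
    for s in starts:
        chunk = bases[s : s + window]
        if len(chunk) < 3:
            continue
        counts: dict[str, int] = {}
        for i in range(len(chunk) - 2):
            t = chunk[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = sum(c * (c - 1) / 2 for c in counts.values()) / max(1, len(chunk) - 3)
        best = max(best, score)
    return best


def _is_low_complexity(bases: str, dust_threshold: float = 7.0,
                       mono_frac: float = 0.9) -> bool:
    if not bases:
        return True
    top = max(bases.count(b) for b in "ACGT")
    if top >= mono_frac * len(bases):
        return True
    return _dust_score(bases) > dust_threshold


@dataclass
class CleanResult:
    pair: ReadPair | None
    adapter_trimmed: bool = False
    quality_trimmed: bool = False
    rejected: str | None = None   # "too_short" | "low_complexity"


def clean_read_pair(
    pair: ReadPair,
    adapters: Sequence[str],
    min_q: int = 20,
    min_len: int = 36,
) -> CleanResult:
    """Adapter-trim, quality-trim and complexity-screen one pair.

    The pair is rejected when either mate falls below ``min_len`` after
    trimming, or when either mate is low-complexity (DUST-style triplet
    score over 64-bp windows, or >=90% a single nucleotide).
    """
    if not adapters:
        raise ValueError("adapter list must be non-empty")
    mates = []
    adapter_trimmed = quality_trimmed = False
    for mate in (pair.mate1, pair.mate2):
        bases, quals = mate.bases, mate.quals
        for adapter in adapters:
            pos = _find_adapter(bases, adapter)
            if pos is not None:
                bases = bases[:pos]
                quals = None if quals is None else quals[:pos]
                adapter_trimmed = True
        if quals is not None and len(quals):
            keep = _quality_trim_point(quals, min_q)
            if keep < len(bases):
                bases, quals = bases[:keep], quals[:keep]
                quality_trimmed = True
        if len(bases) < min_len:
            return CleanResult(None, adapter_trimmed, quality_trimmed, "too_short")
        if _is_low_complexity(bases):
            return CleanResult(None, adapter_trimmed, quality_trimmed, "low_complexity")
        mates.append(SequenceRecord(mate.id, bases, quals))
    cleaned = ReadPair(pair.pair_id, mates[0], mates[1],
                       barcode=pair.barcode, sample_id=pair.sample_id)
    return CleanResult(cleaned, adapter_trimmed, quality_trimmed, None)


def contaminant_screen(
    pair: ReadPair, contaminant_kmers: KmerTable, frac: float = 0.8
) -> bool:
    """True (flag as contaminant) iff >= ``frac`` of either mate's k-mers
    occur in the contaminant table (k=21 by convention)."""
    k = contaminant_kmers.k
    for mate in (pair.mate1, pair.mate2):
        n = len(mate.bases) - k + 1
        if n <= 0:
            continue
        hits = sum(
            1 for i in range(n) if mate.bases[i : i + k] in contaminant_kmers
        )
        if hits >= frac * n:
            return True
    return False


def quality_summary(reads: Iterable[SequenceRecord]) -> tuple[float, float]:
    """(mean Phred quality, fraction of bases with Q >= 30) over all bases."""
    total = 0
    qsum = 0
    q30 = 0
    for read in reads:
        if read.quals is None:
            raise ValueError(f"{read.id}: missing qualities")
        total += len(read.quals)
        qsum += int(read.quals.sum())
        q30 += int((read.quals >= 30).sum())
    if total == 0:
        raise ValueError("no bases")
    return qsum / total, q30 / total


def subsample_pairs(
    pairs: Sequence[ReadPair], n: int, seed: int
) -> list[ReadPair]:
    """Uniform subsample without replacement, stable in input order."""
    if n > len(pairs):
        raise ValueError(f"cannot subsample {n} of {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    return [pairs[i] for i in sorted(idx)]


def run_filters(
    pairs: Sequence[ReadPair],
    adapters: Sequence[str],
    contaminant_kmers: KmerTable | None = None,
    min_q: int = 20,
    min_len: int = 36,
    contaminant_frac: float = 0.8,
) -> tuple[list[ReadPair], FilterReport]:
    """Run dedup -> clean -> contaminant screen; return survivors + report."""
    report = FilterReport(input=len(pairs))
    unique, report.duplicates = remove_exact_duplicates(pairs)
    survivors: list[ReadPair] = []
    for pair in unique:
        result = clean_read_pair(pair, adapters, min_q=min_q, min_len=min_len)
        report.adapter_trimmed += result.adapter_trimmed
        report.quality_trimmed += result.quality_trimmed
        if result.rejected == "too_short":
            report.too_short += 1
            continue
        if result.rejected == "low_complexity":
            report.low_complexity += 1
            continue
        pair = result.pair
        if contaminant_kmers is not None and contaminant_screen(
            pair, contaminant_kmers, contaminant_frac
        ):
            report.contaminant += 1
            continue
        survivors.append(pair)
    report.passed = len(survivors)
    report.check_telescoping()
    return survivors, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33 via Biopython)

def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        pid = r1.id.removesuffix("/1")
        pairs.append(
            ReadPair(
                pid,
                SequenceRecord(r1.id, str(r1.seq),
                               np.array(r1.letter_annotations["phred_quality"])),
                SequenceRecord(r2.id, str(r2.seq),
                               np.array(r2.letter_annotations["phred_quality"])),
            )
        )
    return pairs


def write_fastq_pairs(
    pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in pairs:
            for mate, fh, tag in ((pair.mate1, f1, "/1"), (pair.mate2, f2, "/2")):
                quals = mate.quals
                if quals is None:
                    quals = np.full(len(mate.bases), 40, dtype=int)
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{pair.pair_id}{tag}\n{mate.bases}\n+\n{qstr}\n")


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """TSV of (sample_id, barcode)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("sample"):
                continue
            sample, barcode = line.split("\t")[:2]
            out[sample] = barcode
    return out
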