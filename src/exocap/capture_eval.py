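"""Capture-performance evaluation from read alignments.

Implements the five standard target-enrichment metrics — sensitivity
(fraction of targets hit by any read), specificity (on-target fraction of
uniquely mapped reads), per-target base coverage, uniformity (coverage
threshold fractions and within-target edge profiles), and reproducibility
(between-library correlation of per-target coverage) — plus the
divergence-vs-coverage decay analysis and empirical error-rate estimation
from haploid loci (mitochondrial contigs, X-linked targets in males, SRY).

Duplicate and multi-mapped reads are excluded from every metric; pileups
are built only from uniquely mapped, non-duplicate reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .seqcore import error_from_phred, phred_from_error

__all__ = [
    "AlignmentRecord",
    "Pileup",
    "CaptureMetrics",
    "read_sam",
    "write_sam",
    "build_pileup",
    "sensitivity",
    "specificity",
    "per_target_coverage",
    "coverage_summary",
    "edge_profile",
    "gc_coverage_relation",
    "reproducibility",
    "divergence_coverage",
    "haploid_error_rate",
    "identify_x_linked",
    "sry_check",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}


@dataclass
class AlignmentRecord:
    """A read placement on a contig (0-based, gapless M-only footprint)."""

    read_id: str
    contig_id: str
    pos: int
    seq: str
    quals: np.ndarray | None = None
    is_unique: bool = True
    is_duplicate: bool = False
    sample_id: str | None = None

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)


@dataclass
class Pileup:
    """Per-contig stacked base counts from unique, non-duplicate reads."""

    depth: dict[str, np.ndarray] = field(default_factory=dict)
    base_counts: dict[str, np.ndarray] = field(default_factory=dict)  # 5 x L
    err_sum: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_depth(self, contig_id: str, span: tuple[int, int]) -> float:
        d = self.depth.get(contig_id)
        if d is None:
            return 0.0
        return float(d[span[0] : span[1]].mean()) if span[1] > span[0] else 0.0

    def covered_bases(self, contig_id: str, span: tuple[int, int]) -> int:
        d = self.depth.get(contig_id)
        if d is None:
            return 0
        return int((d[span[0] : span[1]] > 0).sum())


@dataclass
class CaptureMetrics:
    sensitivity_pct: float
    specificity_pct: float | None
    per_target_mean_coverage: pd.Series
    threshold_fractions: dict[str, float]


# ---------------------------------------------------------------------------
# SAM I/O (pysam; text SAM, minimal fields)

def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Read a SAM file into alignment records plus contig lengths.

    MAPQ 0 marks a non-uniquely mapped read; flag 0x400 a duplicate.
    Only M/=/X CIGAR ops are expected (soft clips are trimmed).
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence or ""
            quals = aln.query_qualities
            if aln.cigartuples:
                start = 0
                end = len(seq)
                ops = aln.cigartuples
                if ops[0][0] == 4:      # leading soft clip
                    start = ops[0][1]
                if ops[-1][0] == 4:     # trailing soft clip
                    end -= ops[-1][1]
                seq = seq[start:end]
                quals = None if quals is None else quals[start:end]
            sample = None
            if aln.has_tag("RG"):
                sample = aln.get_tag("RG")
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    pos=aln.reference_start,
                    seq=seq,
                    quals=None if quals is None else np.asarray(quals),
                    is_unique=aln.mapping_quality > 0,
                    is_duplicate=aln.is_duplicate,
                    sample_id=sample,
                )
            )
    return records, lengths


def write_sam(
    records: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    unmapped: Iterable[tuple[str, str]] = (),
) -> None:
    """Write gapless alignments as text SAM (plus optional unmapped reads)."""
    names = list(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(contig_lengths[n])} for n in names],
    }
    index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            a.reference_id = index[rec.contig_id]
            a.reference_start = rec.pos
            a.mapping_quality = 60 if rec.is_unique else 0
            a.cigartuples = [(0, len(rec.seq))]
            a.flag = 0x400 if rec.is_duplicate else 0
            if rec.quals is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(q) + 33) for q in rec.quals)
                )
            if rec.sample_id is not None:
                a.set_tag("RG", rec.sample_id)
            out.write(a)
        for read_id, seq in unmapped:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read_id
            a.query_sequence = seq
            a.flag = 4
            out.write(a)


# ---------------------------------------------------------------------------
# pileup

def _usable(records: Iterable[AlignmentRecord]) -> Iterable[AlignmentRecord]:
    return (r for r in records if r.is_unique and not r.is_duplicate)


def build_pileup(
    records: Sequence[AlignmentRecord],
    contig_lengths: Mapping[str, int],
) -> Pileup:
    """Stack unique, non-duplicate reads into per-base counts.

    Raises on alignments extending beyond the contig end.
    """
    pile = Pileup()
    for contig, length in contig_lengths.items():
        pile.depth[contig] = np.zeros(length, dtype=np.int64)
        pile.base_counts[contig] = np.zeros((5, length), dtype=np.int64)
        pile.err_sum[contig] = np.zeros(length, dtype=np.float64)
    for rec in _usable(records):
        if rec.contig_id not in pile.depth:
            raise ValueError(f"{rec.read_id}: unknown contig {rec.contig_id}")
        if rec.end > len(pile.depth[rec.contig_id]) or rec.pos < 0:
            raise ValueError(
                f"{rec.read_id}: alignment [{rec.pos},{rec.end}) beyond "
                f"contig {rec.contig_id}"
            )
        positions = np.arange(rec.pos, rec.end)
        pile.depth[rec.contig_id][rec.pos : rec.end] += 1
        base_idx = np.fromiter(
            (_BASE_INDEX.get(b, 4) for b in rec.seq), dtype=np.int64,
            count=len(rec.seq),
        )
        np.add.at(pile.base_counts[rec.contig_id], (base_idx, positions), 1)
        if rec.quals is not None:
            errs = np.power(10.0, -np.asarray(rec.quals, dtype=float) / 10.0)
            pile.err_sum[rec.contig_id][rec.pos : rec.end] += errs
    return pile


# ---------------------------------------------------------------------------
# core metrics

TargetSpans = Mapping[str, tuple[str, tuple[int, int]]]
"""target_id -> (contig_id, (start, end)) on the mapping reference."""


def _spans_from_in_target(in_target) -> dict[str, tuple[str, tuple[int, int]]]:
    return {
        tid: (hit.contig_id, hit.contig_span)
        for tid, hit in in_target.hits.items()
    }


def sensitivity(target_spans: TargetSpans, pileup: Pileup) -> float:
    """Percentage of targets with at least one covered base."""
    if not target_spans:
        raise ValueError("no targets")
    hit = sum(
        1
        for contig, span in target_spans.values()
        if pileup.covered_bases(contig, span) > 0
    )
    return 100.0 * hit / len(target_spans)


def specificity(
    records: Sequence[AlignmentRecord], target_spans: TargetSpans
) -> float | None:
    """Percentage of uniquely mapped reads whose span overlaps any target.

    A read is in-target when its alignment overlaps a target span by at
    least one base.  Returns ``None`` when no reads are aligned.
    """
    masks: dict[str, np.ndarray] = {}
    for contig, span in target_spans.values():
        if contig not in masks:
            masks[contig] = np.zeros(0, dtype=bool)
        if len(masks[contig]) < span[1]:
            grown = np.zeros(span[1], dtype=bool)
            grown[: len(masks[contig])] = masks[contig]
            masks[contig] = grown
        masks[contig][span[0] : span[1]] = True
    prefix = {c: np.concatenate([[0], np.cumsum(m)]) for c, m in masks.items()}

    total = 0
    in_target = 0
    for rec in _usable(records):
        total += 1
        p = prefix.get(rec.contig_id)
        if p is None:
            continue
        lo = min(rec.pos, len(p) - 1)
        hi = min(rec.end, len(p) - 1)
        if p[hi] - p[lo] > 0:
            in_target += 1
    if total == 0:
        return None
    return 100.0 * in_target / total


def per_target_coverage(pileup: Pileup, target_spans: TargetSpans) -> pd.Series:
    """Mean base coverage over each target's span."""
    return pd.Series(
        {
            tid: pileup.mean_depth(contig, span)
            for tid, (contig, span) in target_spans.items()
        },
        name="mean_coverage",
    ).sort_index()


def coverage_summary(
    pileup: Pileup,
    target_spans: TargetSpans,
    thresholds: Sequence[int] = (1, 5, 10),
    records: Sequence[AlignmentRecord] | None = None,
) -> CaptureMetrics:
    """Sensitivity, specificity, per-target coverage and threshold fractions.

    The 1X fraction counts targets with mean coverage >= 1 ("at least 1X");
    higher thresholds use strict > ("greater than 5X").
    """
    cov = per_target_coverage(pileup, target_spans)
    fractions = {}
    for t in thresholds:
        if t == 1:
            fractions["ge1X"] = float((cov >= 1).mean())
        else:
            fractions[f"gt{t}X"] = float((cov > t).mean())
    spec = specificity(records, target_spans) if records is not None else None
    return CaptureMetrics(
        sensitivity_pct=sensitivity(target_spans, pileup),
        specificity_pct=spec,
        per_target_mean_coverage=cov,
        threshold_fractions=fractions,
    )


def edge_profile(
    pileup: Pileup,
    target_spans: TargetSpans,
    bin_size: int = 20,
    length_range: tuple[int, int] = (201, 600),
) -> pd.Series:
    """Mean coverage by distance-from-nearer-end bin, pooled over targets.

    Only targets whose length falls in ``length_range`` (inclusive) are
    used; each position contributes to the bin of its distance from the
    nearer target end, up to the midpoint.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    used = 0
    for contig, (start, end) in (
        (c, s) for c, s in target_spans.values()
    ):
        length = end - start
        if not (length_range[0] <= length <= length_range[1]):
            continue
        d = pileup.depth.get(contig)
        if d is None:
            continue
        used += 1
        depths = d[start:end]
        offsets = np.arange(length)
        dist = np.minimum(offsets, length - 1 - offsets)
        bins = dist // bin_size
        for b in np.unique(bins):
            sel = bins == b
            sums[int(b)] = sums.get(int(b), 0.0) + float(depths[sel].sum())
            counts[int(b)] = counts.get(int(b), 0) + int(sel.sum())
    if used == 0:
        raise ValueError(
            f"no targets with length in {length_range}"
        )
    return pd.Series(
        {b: sums[b] / counts[b] for b in sorted(sums)}, name="mean_coverage"
    )


def gc_coverage_relation(
    target_gc: Mapping[str, float],
    coverage: pd.Series,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Mean coverage and target count per GC bin (empty bins omitted)."""
    rows = []
    for tid, gc in target_gc.items():
        if tid in coverage.index:
            rows.append((np.floor(gc / bin_width) * bin_width, coverage[tid]))
    df = pd.DataFrame(rows, columns=["gc_bin", "coverage"])
    out = df.groupby("gc_bin")["coverage"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_coverage", "count": "n_targets"})


def reproducibility(
    coverage_by_library: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.Series:
    """Pearson r of log10(coverage + 1) across shared targets per library pair."""
    libs = list(coverage_by_library.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(libs) for b in libs[i + 1 :]]
    logcov = np.log10(coverage_by_library + 1.0)
    out = {}
    for a, b in pairs:
        x, y = logcov[a].dropna(), logcov[b].dropna()
        shared = x.index.intersection(y.index)
        if len(shared) < 3:
            raise ValueError(f"{a} vs {b}: fewer than 3 shared targets")
        xv, yv = x[shared].to_numpy(), y[shared].to_numpy()
        if xv.std() == 0 or yv.std() == 0:
            out[(a, b)] = np.nan
        else:
            out[(a, b)] = float(np.corrcoef(xv, yv)[0, 1])
    return pd.Series(out, name="pearson_r")


def divergence_coverage(
    target_divergence: Mapping[str, float],
    normalized_coverage: pd.Series,
    bin_width: float = 0.01,
    min_support: int = 3,
) -> pd.DataFrame:
    """Mean normalized coverage per 1% divergence bin.

    ``target_divergence`` holds the per-target divergence between the design
    sequence and its in-target contig (fraction).  Bins with fewer than
    ``min_support`` targets are flagged low-support.
    """
    rows = []
    for tid, d in target_divergence.items():
        if tid in normalized_coverage.index:
            rows.append((np.floor(d / bin_width) * bin_width, normalized_coverage[tid]))
    df = pd.DataFrame(rows, columns=["divergence_bin", "coverage"])
    out = (
        df.groupby("divergence_bin")["coverage"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_coverage", "count": "n_targets"})
    )
    out["low_support"] = out["n_targets"] < min_support
    return out


# ---------------------------------------------------------------------------
# haploid error rate and sex-linked controls

def haploid_error_rate(
    pileup: Pileup,
    haploid_spans: Sequence[tuple[str, tuple[int, int]]],
    min_depth: int = 10,
) -> tuple[int, int, float, float]:
    """Empirical sequencing error from haploid loci.

    The per-column consensus (majority) base is taken as truth; the rate is
    total mismatching stacked bases over total stacked bases across columns
    with depth >= ``min_depth``.  Returns (mismatches, aligned_bases, rate,
    Phred-scaled rate).
    """
    mismatches = 0
    aligned = 0
    for contig, (start, end) in haploid_spans:
        counts = pileup.base_counts.get(contig)
        if counts is None:
            continue
        window = counts[:4, start:end]          # N never counts as consensus
        depth = window.sum(axis=0)
        keep = depth >= min_depth
        if not keep.any():
            continue
        major = window[:, keep].max(axis=0)
        aligned += int(depth[keep].sum())
        mismatches += int((depth[keep] - major).sum())
    if aligned == 0:
        raise ValueError("no stacked bases at or above the depth floor")
    rate = mismatches / aligned
    phred = phred_from_error(rate) if rate > 0 else float("inf")
    return mismatches, aligned, rate, phred


def identify_x_linked(
    coverage_by_sample: pd.DataFrame,
    sexes: Mapping[str, str],
    ratio_window: tuple[float, float] = (1.9, 2.1),
) -> pd.DataFrame:
    """Putatively X-linked targets by female/male coverage dosage.

    For each target the ratio of mean female coverage to mean male coverage
    is computed; targets inside ``ratio_window`` are selected.  Targets with
    zero male coverage are skipped and flagged.
    """
    females = [s for s in coverage_by_sample.columns if sexes.get(s) == "F"]
    males = [s for s in coverage_by_sample.columns if sexes.get(s) == "M"]
    if not females or not males:
        raise ValueError("need at least one male and one female sample")
    f_mean = coverage_by_sample[females].mean(axis=1)
    m_mean = coverage_by_sample[males].mean(axis=1)
    ratio = f_mean / m_mean.replace(0, np.nan)
    out = pd.DataFrame(
        {
            "female_mean": f_mean,
            "male_mean": m_mean,
            "fm_ratio": ratio,
            "skipped_zero_male": m_mean == 0,
        }
    )
    out["x_linked"] = ratio.between(*ratio_window).fillna(False)
    return out


def sry_check(
    sry_read_counts: Mapping[str, int], sexes: Mapping[str, str]
) -> pd.DataFrame:
    """Flag females with any SRY reads (cross-contamination) and males with
    none (capture failure)."""
    rows = []
    for sample, count in sry_read_counts.items():
        sex = sexes[sample]
        if sex == "F":
            flag = "possible_contamination" if count > 0 else "pass"
        else:
            flag = "possible_capture_failure" if count == 0 else "pass"
        rows.append((sample, sex, count, flag))
    return pd.DataFrame(rows, columns=["sample", "sex", "sry_reads", "flag"])
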