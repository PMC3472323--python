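"""Assembly merging, summary statistics, and in-target identification.

The toolkit does not assemble reads itself; it consumes contig sets from
external assemblers (or from the simulator, which fragments ground-truth
loci).  Multi-parameter assemblies are merged into a low-redundancy
consensus by greedy clustering at high identity; the merged contigs are
then associated with designed targets by reciprocal best hit (RBH), giving
the "in-target assemblies" used as the mapping reference in place of a
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqcore import (
    AlignScoring,
    PairwiseAlignment,
    SequenceRecord,
    local_align,
)
from .targets import TargetSet

__all__ = [
    "Contig",
    "AssemblyStats",
    "InTargetHit",
    "InTargetAssembly",
    "merge_assemblies",
    "assembly_stats",
    "reciprocal_best_hit",
    "identify_in_target",
    "write_in_target_table",
]


@dataclass
class Contig:
    contig_id: str
    bases: str
    source: str = "merged"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"{self.contig_id}: empty contig")

    def __len__(self) -> int:
        return len(self.bases)

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(self.contig_id, self.bases)


@dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    mean_length: float
    median_length: float
    n50: int


@dataclass
class InTargetHit:
    target_id: str
    contig_id: str
    contig_span: tuple[int, int]   # target footprint on the contig
    identity: float
    left_flank: int
    right_flank: int
    alignment: PairwiseAlignment | None = None


@dataclass
class InTargetAssembly:
    """target_id -> best reciprocal contig hit."""

    hits: dict[str, InTargetHit] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hits)

    def __contains__(self, target_id: str) -> bool:
        return target_id in self.hits

    def target_spans_by_contig(self) -> dict[str, list[tuple[int, int, str]]]:
        out: dict[str, list[tuple[int, int, str]]] = {}
        for hit in self.hits.values():
            out.setdefault(hit.contig_id, []).append(
                (hit.contig_span[0], hit.contig_span[1], hit.target_id)
            )
        for spans in out.values():
            spans.sort()
        return out


# ---------------------------------------------------------------------------
# k-mer prefilter: avoid all-vs-all alignment where no seed is shared

def _kmer_index(seqs: Sequence[SequenceRecord], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, seq in enumerate(seqs):
        for j in range(len(seq.bases) - k + 1):
            index.setdefault(seq.bases[j : j + k], set()).add(i)
    return index


def _candidates(
    queries: Sequence[SequenceRecord], subjects: Sequence[SequenceRecord], k: int = 11
) -> dict[int, set[int]]:
    """query index -> subject indices sharing at least one k-mer (either strand)."""
    index = _kmer_index(subjects, k)
    from .seqcore import revcomp

    out: dict[int, set[int]] = {}
    for qi, q in enumerate(queries):
        hits: set[int] = set()
        for bases in (q.bases, revcomp(q.bases)):
            for j in range(len(bases) - k + 1):
                hits |= index.get(bases[j : j + k], set())
        out[qi] = hits
    return out


def _best_oriented_alignment(
    a: SequenceRecord, b: SequenceRecord, scoring: AlignScoring
) -> PairwiseAlignment | None:
    """Best local alignment of a vs b, trying both orientations of a."""
    fwd = local_align(a, b, scoring)
    rev = local_align(a.reverse_complement(), b, scoring)
    if fwd is None:
        return rev
    if rev is None or fwd.score >= rev.score:
        return fwd
    return rev


def merge_assemblies(
    assemblies: Iterable[Sequence[Contig]],
    id_threshold: float = 0.99,
    min_overlap: int = 40,
    scoring: AlignScoring = AlignScoring(),
) -> list[Contig]:
    """Greedily cluster-and-merge contigs from several assemblies.

    Contigs are processed longest first.  A contig joining an existing
    merged contig at >= ``id_threshold`` identity over >= ``min_overlap``
    aligned bases is merged in: containment collapses to the container,
    a dovetail overlap extends the merged contig, and overlap columns take
    the majority base with ties resolved toward the longest member.
    """
    pool: list[Contig] = []
    for assembly in assemblies:
        pool.extend(assembly)
    if not pool:
        return []
    pool.sort(key=lambda c: (-len(c), c.contig_id))

    from .seqcore import revcomp

    k = 15
    index: dict[str, set[int]] = {}

    def index_contig(mi: int, bases: str) -> None:
        for j in range(len(bases) - k + 1):
            index.setdefault(bases[j : j + k], set()).add(mi)

    merged: list[Contig] = []
    for contig in pool:
        candidates: set[int] = set()
        for bases in (contig.bases, revcomp(contig.bases)):
            for j in range(len(bases) - k + 1):
                candidates |= index.get(bases[j : j + k], set())
        placed = False
        for mi in sorted(candidates):
            existing = merged[mi]
            aln = _best_oriented_alignment(
                contig.as_record(), existing.as_record(), scoring
            )
            if aln is None:
                continue
            if aln.alignable_bases < min_overlap or aln.identity < id_threshold:
                continue
            merged[mi] = _merge_pair(existing, contig, aln)
            index_contig(mi, merged[mi].bases)
            placed = True
            break
        if not placed:
            merged.append(Contig(contig.contig_id, contig.bases, source="merged"))
            index_contig(len(merged) - 1, contig.bases)
    return merged


def _merge_pair(existing: Contig, new: Contig, aln: PairwiseAlignment) -> Contig:
    """Merge ``new`` into ``existing`` given new-vs-existing alignment.

    ``aln.query_id`` may carry the reverse-complemented orientation of
    ``new``; coordinates refer to the oriented query string.
    """
    from .seqcore import revcomp

    new_bases = new.bases
    # detect orientation: the alignment was computed on fwd or rc of new
    q_fwd = "".join(q for q, r in aln.columns if q != "-")
    if q_fwd not in new_bases:
        new_bases = revcomp(new_bases)
    qs, qe = aln.query_span
    rs, re_ = aln.ref_span

    # consensus across the overlap: majority of 2 -> base of longest member
    longer_is_existing = len(existing) >= len(new_bases)
    overlap = []
    for q, r in aln.columns:
        if q == "-" :
            overlap.append(r)
        elif r == "-":
            overlap.append(q)
        elif q == r:
            overlap.append(q)
        else:
            overlap.append(r if longer_is_existing else q)
    overlap_seq = "".join(overlap)

    left = existing.bases[:rs] if rs >= qs else new_bases[:qs]
    right_existing = existing.bases[re_:]
    right_new = new_bases[qe:]
    right = right_existing if len(right_existing) >= len(right_new) else right_new
    merged_bases = left + overlap_seq + right
    # containment: keep the container verbatim
    if len(merged_bases) <= len(existing):
        return existing
    return Contig(existing.contig_id, merged_bases, source="merged")


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """Contig count, total/mean/median length, and N50."""
    if not contigs:
        raise ValueError("empty assembly")
    lengths = np.array(sorted((len(c) for c in contigs), reverse=True))
    total = int(lengths.sum())
    cumulative = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cumulative, total / 2)])
    return AssemblyStats(
        n_contigs=len(contigs),
        total_length=total,
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        n50=n50,
    )


def reciprocal_best_hit(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    min_identity: float = 0.8,
    min_len: int = 60,
    scoring: AlignScoring = AlignScoring(),
    prefilter_k: int | None = 11,
) -> list[tuple[str, str, PairwiseAlignment]]:
    """Reciprocal best hits between two sequence sets.

    A hit qualifies when its alignment spans >= ``min_len`` alignable bases
    at >= ``min_identity``; (a, b) is returned iff b is a's best-scoring
    qualifying hit and vice versa.  Ties break on (score, alignment length,
    lexicographic id).  ``prefilter_k`` restricts alignment to pairs sharing
    a k-mer; set to ``None`` for exhaustive all-vs-all.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    if prefilter_k:
        cand = _candidates(set_a, set_b, prefilter_k)
    else:
        cand = {i: set(range(len(set_b))) for i in range(len(set_a))}

    hits: dict[tuple[int, int], PairwiseAlignment] = {}
    for ai, bis in cand.items():
        for bi in bis:
            aln = _best_oriented_alignment(set_a[ai], set_b[bi], scoring)
            if aln is None:
                continue
            if aln.alignable_bases < min_len or aln.identity < min_identity:
                continue
            hits[(ai, bi)] = aln

    def best_of(keyed: dict[int, list[tuple[int, PairwiseAlignment]]], other_ids):
        best = {}
        for idx, items in keyed.items():
            items.sort(
                key=lambda t: (-t[1].score, -t[1].length, other_ids[t[0]])
            )
            best[idx] = items[0][0]
        return best

    by_a: dict[int, list[tuple[int, PairwiseAlignment]]] = {}
    by_b: dict[int, list[tuple[int, PairwiseAlignment]]] = {}
    for (ai, bi), aln in hits.items():
        by_a.setdefault(ai, []).append((bi, aln))
        by_b.setdefault(bi, []).append((ai, aln))
    a_ids = [s.id for s in set_a]
    b_ids = [s.id for s in set_b]
    best_a = best_of(by_a, b_ids)
    best_b = best_of(by_b, a_ids)

    out = []
    for ai, bi in sorted(best_a.items()):
        if best_b.get(bi) == ai:
            out.append((a_ids[ai], b_ids[bi], hits[(ai, bi)]))
    return out


def identify_in_target(
    contigs: Sequence[Contig],
    target_set: TargetSet,
    min_identity: float = 0.8,
    min_len: int = 60,
) -> InTargetAssembly:
    """Associate each target with its reciprocal-best consensus contig.

    Records the target's footprint on the contig and the flanking spans
    (intronic/UTR sequence recovered beyond the exon boundaries).
    """
    target_records = [
        SequenceRecord(t.target_id, t.sequence) for t in target_set
    ]
    contig_records = [c.as_record() for c in contigs]
    pairs = reciprocal_best_hit(
        target_records, contig_records, min_identity=min_identity, min_len=min_len
    )
    contig_len = {c.contig_id: len(c) for c in contigs}
    result = InTargetAssembly()
    for target_id, contig_id, aln in pairs:
        span = aln.ref_span
        result.hits[target_id] = InTargetHit(
            target_id=target_id,
            contig_id=contig_id,
            contig_span=span,
            identity=aln.identity,
            left_flank=span[0],
            right_flank=contig_len[contig_id] - span[1],
            alignment=aln,
        )
    return result


def write_in_target_table(assembly: InTargetAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "target_id\tcontig_id\tcontig_start\tcontig_end\t"
            "identity\tleft_flank\tright_flank\n"
        )
        for tid in sorted(assembly.hits):
            h = assembly.hits[tid]
            fh.write(
                f"{h.target_id}\t{h.contig_id}\t{h.contig_span[0]}\t"
                f"{h.contig_span[1]}\t{h.identity:.4f}\t{h.left_flank}\t"
                f"{h.right_flank}\n"
            )
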