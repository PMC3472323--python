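"""Independent brute-force oracles used to check the fast implementations.

These stay deliberately naive: exhaustive dynamic programming, per-k-mer
rescans, all-vs-all best-hit search, and direct codon translation.  They
must never import the code paths they verify.
"""

from __future__ import annotations

from Bio.Seq import Seq


def gotoh_local_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Exhaustive affine-gap local alignment score (Gotoh recurrences).

    A gap of length L costs gap_open + (L - 1) * gap_extend.  N never
    matches, including against itself.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + s)
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


def brute_force_masked(probe_seq: str, reference_seqs: list[str], k: int,
                       threshold: int) -> bool:
    """Rescan the reference for every probe k-mer, counting both strands."""
    from collections import Counter

    comp = str.maketrans("ACGTN", "TGCAN")
    counts: Counter = Counter()
    for ref in reference_seqs:
        for strand in (ref, ref.translate(comp)[::-1]):
            for i in range(len(strand) - k + 1):
                kmer = strand[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
    for i in range(len(probe_seq) - k + 1):
        if counts[probe_seq[i : i + k]] >= threshold:
            return True
    return False


def all_vs_all_rbh(set_a, set_b, score_fn, qualifies_fn):
    """Reciprocal best hits by exhaustive scoring of every pair.

    ``score_fn(a, b)`` returns (score, length) or None; ``qualifies_fn``
    filters hits.  Tie-break: (score, length, lexicographic id).
    """
    hits = {}
    for a in set_a:
        for b in set_b:
            result = score_fn(a, b)
            if result is not None and qualifies_fn(result):
                hits[(a.id, b.id)] = result

    def best(items, other_id):
        items = sorted(items, key=lambda t: (-t[1][0], -t[1][1], other_id(t[0])))
        return items[0][0] if items else None

    best_a = {}
    for a in set_a:
        items = [(b.id, hits[(a.id, b.id)]) for b in set_b if (a.id, b.id) in hits]
        best_a[a.id] = best(items, lambda x: x)
    best_b = {}
    for b in set_b:
        items = [(a.id, hits[(a.id, b.id)]) for a in set_a if (a.id, b.id) in hits]
        best_b[b.id] = best(items, lambda x: x)
    return sorted(
        (a_id, b_id)
        for a_id, b_id in ((a.id, best_a[a.id]) for a in set_a)
        if b_id is not None and best_b[b_id] == a_id
    )


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def tiling_offsets_oracle(length: int, probe_len: int, step: int,
                          edge: bool, edge_window: int, edge_step: int) -> list[int]:
    """Set-union enumeration of probe offsets."""
    last = length - probe_len
    offsets = set(range(0, last + 1, step)) | {last}
    if edge and last > 0:
        offsets |= set(range(0, min(edge_window, last + 1), edge_step))
        offsets |= set(range(max(0, last - edge_window + 1), last + 1, edge_step))
    return sorted(offsets)
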