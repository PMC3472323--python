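"""Tiling probe design with k-mer repeat soft-masking.

60-bp probes are tiled across each target at a class-specific step (nuclear
exons every 4 bp, anonymous genomic intervals every 2 bp, mitochondrial
tiles every 20 bp, SRY every 1 bp, control genes every 4 bp).  Because the
design comes from a transcriptome, no probes can extend past exon–intron
boundaries; instead nuclear-exon targets get 1-bp tiling inside an edge
window at both ends to mitigate the coverage drop at target edges.  Probes
containing any 15-mer that is over-represented in the masking reference
(frequency >= 50 by default) are excluded, a soft-masking proxy for
repetitive elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqcore import KmerTable, SequenceRecord, count_kmers, gc_fraction
from .targets import CLASS_TILING_STEP, ExonTarget, TargetSet

__all__ = [
    "Probe",
    "ProbeSet",
    "DesignConfig",
    "DesignError",
    "tile_offsets",
    "tile_target",
    "soft_mask_probes",
    "design_array",
    "write_probe_fasta",
    "write_probe_table",
]


class DesignError(RuntimeError):
    """Array design failed (e.g. capacity exceeded)."""


@dataclass(frozen=True)
class DesignConfig:
    probe_length: int = 60
    edge_step: int = 1
    edge_window: int = 30
    mask_k: int = 15
    mask_threshold: int = 50
    capacity: int = 1_000_000
    class_steps: dict = field(default_factory=lambda: dict(CLASS_TILING_STEP))


@dataclass
class Probe:
    """One tiled oligo on a target."""

    probe_id: str
    target_id: str
    offset: int
    sequence: str
    gc: float | None = None
    masked: bool = False
    tiling_origin: str = "interior"     # "interior" or "edge"


@dataclass
class ProbeSet:
    """Designed probes with per-target grouping and design bookkeeping."""

    probes: list[Probe]
    config: DesignConfig
    skipped_targets: list[str] = field(default_factory=list)

    @property
    def designed(self) -> int:
        return len(self.probes)

    @property
    def masked(self) -> int:
        return sum(p.masked for p in self.probes)

    @property
    def retained(self) -> int:
        return self.designed - self.masked

    def retained_probes(self) -> list[Probe]:
        return [p for p in self.probes if not p.masked]

    def per_class_counts(self, target_set: TargetSet) -> dict[str, dict[str, int]]:
        cls_of = {t.target_id: t.target_class for t in target_set}
        out: dict[str, dict[str, int]] = {}
        for p in self.probes:
            cls = cls_of.get(p.target_id, "?")
            row = out.setdefault(cls, {"designed": 0, "masked": 0, "retained": 0})
            row["designed"] += 1
            row["masked"] += p.masked
            row["retained"] += not p.masked
        return out


def tile_offsets(
    target_length: int,
    probe_length: int = 60,
    step: int = 4,
    edge_densify: bool = False,
    edge_step: int = 1,
    edge_window: int = 30,
) -> list[tuple[int, str]]:
    """Sorted (offset, origin) placements for one target.

    Interior offsets are 0, step, 2*step, ...; a terminal probe flush with
    the target end is always included.  With edge densification every
    offset in ``[0, edge_window)`` and ``(last - edge_window, last]`` is
    added at ``edge_step`` spacing (origin "edge").
    """
    last = target_length - probe_length
    if last < 0:
        raise ValueError("target shorter than probe")
    interior = set(range(0, last + 1, step))
    interior.add(last)
    edge: set[int] = set()
    if edge_densify and last > 0:
        edge.update(range(0, min(edge_window, last + 1), edge_step))
        edge.update(range(max(0, last - edge_window + 1), last + 1, edge_step))
    edge -= interior
    placements = [(off, "interior") for off in interior]
    placements += [(off, "edge") for off in edge]
    placements.sort()
    return placements


def tile_target(
    target: ExonTarget,
    probe_length: int = 60,
    step: int | None = None,
    edge_step: int = 1,
    edge_window: int = 30,
) -> list[Probe]:
    """Tile one target; nuclear exons get 1-bp edge densification."""
    if len(target) < probe_length:
        raise ValueError(
            f"{target.target_id}: length {len(target)} < probe length {probe_length}"
        )
    if step is None:
        step = target.tiling_step
    placements = tile_offsets(
        len(target),
        probe_length,
        step,
        edge_densify=(target.target_class == "nuclear_exon"),
        edge_step=edge_step,
        edge_window=edge_window,
    )
    return [
        Probe(
            probe_id=f"{target.target_id}|{off}",
            target_id=target.target_id,
            offset=off,
            sequence=target.sequence[off : off + probe_length],
            tiling_origin=origin,
        )
        for off, origin in placements
    ]


def soft_mask_probes(
    probes: Iterable[Probe], table: KmerTable, threshold: int = 50
) -> tuple[list[Probe], list[Probe]]:
    """Partition probes into (retained, masked) by over-represented k-mers.

    A probe is masked iff any of its k-mers occurs in ``table`` with
    frequency >= ``threshold``.  The ``masked`` flag is set in place.
    """
    retained, masked = [], []
    k = table.k
    for probe in probes:
        seq = probe.sequence.upper()
        hit = any(
            table.frequency(seq[i : i + k]) >= threshold
            for i in range(len(seq) - k + 1)
        )
        probe.masked = hit
        (masked if hit else retained).append(probe)
    return retained, masked


def design_array(
    target_set: TargetSet,
    reference_for_masking: Sequence[SequenceRecord] = (),
    config: DesignConfig = DesignConfig(),
) -> ProbeSet:
    """Tile every target, soft-mask against the reference, check capacity.

    The masking reference is typically the design transcriptome concatenated
    with any auxiliary genome.  Raises :class:`DesignError` when retained
    probes exceed array capacity; targets shorter than the probe length are
    skipped and recorded.
    """
    if len(target_set) == 0:
        raise ValueError("empty target set")
    if config.capacity <= 0:
        raise ValueError("capacity must be positive")
    probes: list[Probe] = []
    skipped: list[str] = []
    for target in target_set:
        if len(target) < config.probe_length:
            skipped.append(target.target_id)
            continue
        step = config.class_steps.get(target.target_class, target.tiling_step)
        probes.extend(
            tile_target(
                target,
                probe_length=config.probe_length,
                step=step,
                edge_step=config.edge_step,
                edge_window=config.edge_window,
            )
        )
    if reference_for_masking:
        table = count_kmers(reference_for_masking, config.mask_k)
        soft_mask_probes(probes, table, config.mask_threshold)
    for probe in probes:
        probe.gc = gc_fraction(probe.sequence)
    probe_set = ProbeSet(probes=probes, config=config, skipped_targets=skipped)
    if probe_set.retained > config.capacity:
        raise DesignError(
            f"retained {probe_set.retained} probes exceed capacity "
            f"{config.capacity} (overflow {probe_set.retained - config.capacity})"
        )
    return probe_set


def write_probe_fasta(probe_set: ProbeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probe_set.retained_probes():
            fh.write(f">{p.probe_id}\n{p.sequence}\n")


def write_probe_table(probe_set: ProbeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\ttarget_id\toffset\tgc\tmasked\ttiling_origin\n")
        for p in probe_set.probes:
            gc = "" if p.gc is None else f"{p.gc:.4f}"
            fh.write(
                f"{p.probe_id}\t{p.target_id}\t{p.offset}\t{gc}\t"
                f"{int(p.masked)}\t{p.tiling_origin}\n"
            )
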