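import numpy as np
import pytest

from exocap.readqc import (
    ReadPair,
    clean_read_pair,
    contaminant_screen,
    demultiplex,
    quality_summary,
    read_fastq_pairs,
    remove_exact_duplicates,
    run_filters,
    subsample_pairs,
    write_fastq_pairs,
)
from exocap.seqcore import SequenceRecord, count_kmers
from exocap.simulate import (
    DEFAULT_BARCODES,
    SimConfig,
    random_dna,
    simulate_capture_reads,
)

Q40 = lambda n: np.full(n, 40, dtype=int)


def _pair(pid, b1, b2, q1=None, q2=None, barcode=None):
    return ReadPair(
        pid,
        SequenceRecord(f"{pid}/1", b1, Q40(len(b1)) if q1 is None else q1),
        SequenceRecord(f"{pid}/2", b2, Q40(len(b2)) if q2 is None else q2),
        barcode=barcode,
    )


def _random_pair(pid, rng, length=100, barcode=None):
    return _pair(pid, random_dna(rng, length), random_dna(rng, length),
                 barcode=barcode)


class TestDemultiplex:
    BCS = {"s1": DEFAULT_BARCODES[0], "s2": DEFAULT_BARCODES[1],
           "s3": DEFAULT_BARCODES[2]}

    def test_exact_match_pool_fully_assigned(self, rng):
        pairs = [
            _random_pair(f"p{i}", rng, barcode=self.BCS[f"s{i % 3 + 1}"])
            for i in range(30)
        ]
        assigned, unassigned = demultiplex(pairs, self.BCS)
        assert not unassigned
        assert sum(len(v) for v in assigned.values()) == 30

    def test_one_mismatch_assigned_when_allowed(self, rng):
        bc = list(self.BCS["s1"])
        bc[3] = "A" if bc[3] != "A" else "C"
        pair = _random_pair("p", rng, barcode="".join(bc))
        assigned, unassigned = demultiplex([pair], self.BCS, max_mismatch=1)
        assert assigned["s1"] == [pair]

    def test_all_n_barcode_unassigned(self, rng):
        pair = _random_pair("p", rng, barcode="NNNNNNN")
        assigned, unassigned = demultiplex([pair], self.BCS)
        assert unassigned == [pair]

    def test_colliding_barcodes_rejected(self):
        close = {"a": "AAAAAAA", "b": "AAAAAAT"}
        with pytest.raises(ValueError):
            demultiplex([], close, max_mismatch=1)

    def test_inline_barcode_stripped_from_mate1(self, rng):
        insert = random_dna(rng, 93)
        pair = _pair("p", self.BCS["s2"] + insert, random_dna(rng, 100))
        assigned, _ = demultiplex([pair], self.BCS, inline=True)
        out = assigned["s2"][0]
        assert out.mate1.bases == insert
        assert out.barcode == self.BCS["s2"]


class TestDeduplication:
    def test_identical_pair_collapsed_first_kept(self, rng):
        a = _random_pair("a", rng)
        b = _pair("b", a.mate1.bases, a.mate2.bases)
        unique, dups = remove_exact_duplicates([a, b])
        assert unique == [a] and dups == 1

    def test_mate1_only_match_not_duplicate(self, rng):
        a = _random_pair("a", rng)
        b = _pair("b", a.mate1.bases, random_dna(rng, 100))
        unique, dups = remove_exact_duplicates([a, b])
        assert len(unique) == 2 and dups == 0

    def test_planted_duplicate_fraction_recovered_exactly(self):
        config = SimConfig(seed=21, n_genes=6, duplicate_fraction=0.20,
                           contaminant_fraction=0.0)
        rng = np.random.default_rng(21)
        from exocap.simulate import evolve_species, simulate_gene_space

        space = simulate_gene_space(config, rng)
        species = evolve_species(space, 0.01, 0.001, rng)
        spans = {t.target_id: (t.source_seq_id, t.span)
                 for t in space.exon_targets(min_length=200)}
        sim = simulate_capture_reads(species, spans, [("s1", "F")], config, rng)
        planted = int(sim.truth.duplicate_of.notna().sum())
        _, recovered = remove_exact_duplicates(sim.pairs)
        # dedupe finds every planted duplicate; coincidentally identical
        # fragments may add a few extra
        assert recovered >= planted
        assert recovered - planted <= 0.005 * len(sim.pairs)
        assert planted / len(sim.pairs) == pytest.approx(0.20, abs=0.01)


class TestCleaning:
    ADAPTER = "AGATCGGAAGAGCACACGT"

    def test_planted_adapter_suffix_removed(self, rng):
        insert = random_dna(rng, 70)
        read = insert + self.ADAPTER[:30]
        pair = _pair("p", read, random_dna(rng, 100))
        result = clean_read_pair(pair, [self.ADAPTER])
        assert result.adapter_trimmed
        assert result.pair.mate1.bases == insert

    def test_high_quality_read_unchanged(self, rng):
        pair = _random_pair("p", rng)
        result = clean_read_pair(pair, [self.ADAPTER])
        assert result.pair.mate1.bases == pair.mate1.bases
        assert not result.quality_trimmed

    def test_low_quality_tail_trimmed(self, rng):
        quals = np.concatenate([Q40(60), np.full(40, 2, dtype=int)])
        pair = _pair("p", random_dna(rng, 100), random_dna(rng, 100), q1=quals)
        result = clean_read_pair(pair, [self.ADAPTER], min_q=20)
        assert result.quality_trimmed
        assert len(result.pair.mate1.bases) == 60

    def test_homopolymer_rejected_low_complexity(self, rng):
        pair = _pair("p", "A" * 100, random_dna(rng, 100))
        result = clean_read_pair(pair, [self.ADAPTER])
        assert result.rejected == "low_complexity"

    def test_short_after_trim_rejected(self, rng):
        quals = np.concatenate([Q40(20), np.full(80, 2, dtype=int)])
        pair = _pair("p", random_dna(rng, 100), random_dna(rng, 100), q1=quals)
        result = clean_read_pair(pair, [self.ADAPTER], min_len=36)
        assert result.rejected == "too_short"

    def test_clean_then_dedupe_idempotent(self, rng):
        pairs = [_random_pair(f"p{i}", rng) for i in range(40)]
        pairs += [_pair("d", pairs[0].mate1.bases, pairs[0].mate2.bases)]
        once, report1 = run_filters(pairs, [self.ADAPTER])
        twice, report2 = run_filters(once, [self.ADAPTER])
        assert [p.pair_id for p in twice] == [p.pair_id for p in once]
        assert [p.mate1.bases for p in twice] == [p.mate1.bases for p in once]


class TestContaminantScreen:
    def test_contaminant_copy_flagged(self, rng):
        genome = random_dna(rng, 50_000)
        table = count_kmers([genome], 21)
        pair = _pair("p", genome[100:200], genome[300:400])
        assert contaminant_screen(pair, table) is True

    def test_unrelated_read_kept(self, rng):
        table = count_kmers([random_dna(rng, 50_000)], 21)
        pair = _random_pair("p", rng)
        assert contaminant_screen(pair, table) is False

    def test_half_chimeric_read_below_threshold_kept(self, rng):
        genome = random_dna(rng, 50_000)
        table = count_kmers([genome], 21)
        half = genome[500:550] + random_dna(rng, 50)
        pair = _pair("p", half, random_dna(rng, 100))
        assert contaminant_screen(pair, table, frac=0.8) is False


class TestQualityAndSubsampling:
    def test_uniform_q30(self):
        reads = [SequenceRecord("r", "ACGT" * 10, np.full(40, 30))]
        mean_q, frac = quality_summary(reads)
        assert mean_q == 30.0 and frac == 1.0

    def test_split_qualities(self):
        reads = [
            SequenceRecord("a", "ACGT", np.full(4, 20)),
            SequenceRecord("b", "ACGT", np.full(4, 40)),
        ]
        mean_q, frac = quality_summary(reads)
        assert mean_q == 30.0 and frac == 0.5

    def test_missing_quals_is_error(self):
        with pytest.raises(ValueError):
            quality_summary([SequenceRecord("r", "ACGT")])

    def test_subsample_identity_empty_and_determinism(self, rng):
        pairs = [_random_pair(f"p{i}", rng) for i in range(100)]
        assert subsample_pairs(pairs, 100, seed=1) == pairs
        assert subsample_pairs(pairs, 0, seed=1) == []
        first = [p.pair_id for p in subsample_pairs(pairs, 10, seed=5)]
        second = [p.pair_id for p in subsample_pairs(pairs, 10, seed=5)]
        assert first == second
        with pytest.raises(ValueError):
            subsample_pairs(pairs, 101, seed=1)


class TestPipelineBookkeeping:
    def test_report_telescopes_with_planted_contaminants(self, rng):
        contaminant = random_dna(rng, 30_000)
        table = count_kmers([contaminant], 21)
        pairs = [_random_pair(f"p{i}", rng) for i in range(60)]
        for i in range(10):  # planted contaminants
            s = int(rng.integers(0, 29_000))
            pairs.append(_pair(f"c{i}", contaminant[s : s + 100],
                               contaminant[s + 150 : s + 250]))
        pairs.append(_pair("dup", pairs[0].mate1.bases, pairs[0].mate2.bases))
        survivors, report = run_filters(pairs, ["AGATCGGAAGAGC"],
                                        contaminant_kmers=table)
        assert report.input == 71
        assert report.duplicates == 1
        assert report.contaminant == 10
        assert report.passed == len(survivors) == 60
        report.check_telescoping()

    def test_fastq_round_trip(self, rng, tmp_path):
        pairs = [_random_pair(f"p{i}", rng) for i in range(5)]
        write_fastq_pairs(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        back = read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert [p.mate1.bases for p in back] == [p.mate1.bases for p in pairs]
        assert all(
            (a.mate2.quals == b.mate2.quals).all() for a, b in zip(back, pairs)
        )
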