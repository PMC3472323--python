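import itertools

import numpy as np
import pandas as pd
import pytest

from exocap.capture_eval import AlignmentRecord, build_pileup
from exocap.simulate import random_dna
from exocap.variants import (
    FUNC_CLASSES,
    GeneFeature,
    GeneModel,
    SNPRecord,
    SNPSummary,
    call_sites,
    classify_function,
    classify_zygosity,
    shared_orthologs,
    site_alt,
    summarize,
    write_vcf,
)

from oracles import translate_codon


def _stack(contig_seq, reads, quals=34):
    """reads: list of (pos, bases); returns pileup over one contig."""
    recs = [
        AlignmentRecord(f"r{i}", "c", pos, bases,
                        quals=np.full(len(bases), quals))
        for i, (pos, bases) in enumerate(reads)
    ]
    return build_pileup(recs, {"c": len(contig_seq)})


class TestCallSites:
    def test_depth_below_floor_excluded(self, rng):
        seq = random_dna(rng, 100)
        alt_read = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        pile = _stack(seq, [(0, alt_read)] * 19)
        assert call_sites(pile, {"c": seq}) == []

    def test_balanced_alleles_high_quality(self, rng):
        seq = random_dna(rng, 100)
        alt = "A" if seq[50] != "A" else "C"
        alt_read = seq[:50] + alt + seq[51:]
        pile = _stack(seq, [(0, seq)] * 50 + [(0, alt_read)] * 50, quals=30)
        sites = call_sites(pile, {"c": seq})
        assert len(sites) == 1
        site = sites[0]
        assert site.position == 50 and site.depth == 100
        assert site.site_quality > 100

    def test_single_low_quality_discordant_base_not_candidate(self, rng):
        seq = random_dna(rng, 100)
        alt = "A" if seq[50] != "A" else "C"
        alt_read = seq[:50] + alt + seq[51:]
        pile = _stack(seq, [(0, seq)] * 29 + [(0, alt_read)], quals=20)
        # binomial tail: P(X>=1 | n=30, p=0.01) ~ 0.26 -> quality ~ 5.9 < 30
        assert call_sites(pile, {"c": seq}) == []

    def test_fixed_difference_is_candidate(self, rng):
        seq = random_dna(rng, 100)
        alt = "A" if seq[50] != "A" else "C"
        alt_read = seq[:50] + alt + seq[51:]
        pile = _stack(seq, [(0, alt_read)] * 30)
        sites = call_sites(pile, {"c": seq})
        assert len(sites) == 1
        assert sites[0].site_quality >= 30

    def test_depth_ceiling_and_monotonicity(self, rng):
        seq = random_dna(rng, 60)
        alt = "A" if seq[30] != "A" else "C"
        alt_read = seq[:30] + alt + seq[31:]
        pile = _stack(seq, [(0, seq)] * 15 + [(0, alt_read)] * 15)
        for lo, hi in [(20, 5000), (25, 5000), (31, 5000), (20, 29)]:
            sites = call_sites(pile, {"c": seq}, min_depth=lo, max_depth=hi)
            expected = 1 if lo <= 30 <= hi else 0
            assert len(sites) == expected
        # raising min_depth never increases calls
        n_calls = [
            len(call_sites(pile, {"c": seq}, min_depth=d)) for d in (20, 25, 31)
        ]
        assert n_calls == sorted(n_calls, reverse=True)


class TestZygosity:
    def _site(self, counts, ref):
        from exocap.variants import CandidateSite

        counts = np.array(counts)
        return CandidateSite("c", 0, int(counts.sum()), counts, 100.0, ref)

    def test_all_alt_is_fixed(self):
        assert classify_zygosity(self._site([40, 0, 0, 0], ref="C")) == "fixed"

    def test_balanced_is_polymorphic(self):
        assert classify_zygosity(self._site([20, 20, 0, 0], ref="A")) == "polymorphic"

    def test_rare_second_allele_below_fraction_is_invariant(self):
        # 38 ref / 2 alt at depth 40: fraction 0.05 < 0.2
        assert classify_zygosity(self._site([38, 2, 0, 0], ref="A")) == "invariant"

    def test_site_alt_is_top_nonreference(self):
        site = self._site([5, 30, 5, 0], ref="A")
        assert site_alt(site) == "C"


class TestClassifyFunction:
    def _single_cds_model(self, length):
        return GeneModel("c", "+", [GeneFeature("cds", (0, length), 0)])

    def test_third_position_gat_gac_synonymous(self):
        model = self._single_cds_model(3)
        assert classify_function("GAT", 2, "T", "C", model) == "synonymous"

    def test_second_position_gat_gct_non_synonymous(self):
        model = self._single_cds_model(3)
        assert classify_function("GAT", 1, "A", "C", model) == "non_synonymous"

    def test_intron_and_utr_labels(self):
        model = GeneModel("c", "+", [
            GeneFeature("utr5", (0, 10)),
            GeneFeature("cds", (10, 19), 0),
            GeneFeature("intron", (19, 30)),
            GeneFeature("utr3", (30, 40)),
        ])
        seq = "A" * 40
        assert classify_function(seq, 5, "A", "G", model) == "utr"
        assert classify_function(seq, 25, "A", "G", model) == "intron"
        assert classify_function(seq, 35, "A", "G", model) == "utr"

    def test_position_outside_features_unclassified(self):
        model = self._single_cds_model(3)
        assert classify_function("GATAAA", 5, "A", "G", model) is None

    def test_cds_spanning_exons_translates_spliced(self):
        # CDS split 2 + 1 across an intron; codon = GA|T
        model = GeneModel("c", "+", [
            GeneFeature("cds", (0, 2), 0),
            GeneFeature("intron", (2, 12)),
            GeneFeature("cds", (12, 13), 2),
        ])
        seq = "GA" + "C" * 10 + "T"
        assert classify_function(seq, 12, "T", "C", model) == "synonymous"

    def test_exhaustive_single_base_codon_changes_match_translation_oracle(self):
        """All 576 single-base changes of all codons agree with the oracle."""
        cases = 0
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            model = self._single_cds_model(3)
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    got = classify_function(codon, pos, codon[pos], alt, model)
                    alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                    expected = (
                        "synonymous"
                        if translate_codon(codon) == translate_codon(alt_codon)
                        else "non_synonymous"
                    )
                    assert got == expected, (codon, pos, alt)
                    cases += 1
        assert cases == 576

    def test_minus_strand_codon(self):
        # contig has revcomp of GAT = ATC; CDS on '-' strand
        model = GeneModel("c", "-", [GeneFeature("cds", (0, 3), 0)])
        # genomic pos 0 is the 3rd codon position (T of GAT on - strand)
        assert classify_function("ATC", 0, "A", "G", model) == "synonymous"


class TestSummary:
    ALPINUS_POLY = {"synonymous": 880, "non_synonymous": 512,
                    "intron": 636, "utr": 173}
    AMOENUS_FIXED = {"synonymous": 5812, "non_synonymous": 1617,
                     "intron": 2286, "utr": 523}

    def test_percentage_arithmetic(self):
        summary = SNPSummary.from_counts({"alpinus": {"polymorphic": self.ALPINUS_POLY}})
        assert summary.status_total("alpinus", "polymorphic") == 2201
        assert summary.percentages("alpinus")["synonymous"] == 40.0

    def test_fixed_total(self):
        summary = SNPSummary.from_counts({"amoenus": {"fixed": self.AMOENUS_FIXED}})
        assert summary.status_total("amoenus", "fixed") == 10238

    def test_conservation_and_empty(self):
        summary = SNPSummary.from_counts({
            "sp": {"fixed": self.AMOENUS_FIXED, "polymorphic": self.ALPINUS_POLY}
        })
        assert summary.grand_total("sp") == 10238 + 2201
        td = summary.total_difference("sp")
        assert int(td.sum()) == summary.grand_total("sp")
        empty = summarize([])
        assert empty.counts.empty

    def test_summarize_records_roundtrip(self):
        records = []
        for i, fc in enumerate(FUNC_CLASSES):
            for _ in range(i + 1):
                records.append(SNPRecord("c", i, "A", "G", "sp", "fixed",
                                         fc, 30, 100.0))
        summary = summarize(records)
        assert summary.counts.loc[("sp", "fixed")].tolist() == [1, 2, 3, 4]
        assert summary.status_total("sp", "fixed") == 10


class TestSharedOrthologs:
    def test_intersection(self):
        maps = {"a": {"t1", "t2", "t3"}, "b": {"t2", "t3"}, "c": {"t3", "t2"}}
        assert shared_orthologs(maps) == ["t2", "t3"]

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            shared_orthologs({"a": {"t1"}})

    def test_planted_dropout_matches_binomial_expectation(self):
        rng = np.random.default_rng(19)
        loci = [f"L{i}" for i in range(100)]
        maps = {
            f"sp{s}": {l for l in loci if rng.random() > 0.05}
            for s in range(4)
        }
        shared = shared_orthologs(maps)
        expected = 100 * 0.95 ** 4
        sd = np.sqrt(100 * 0.95 ** 4 * (1 - 0.95 ** 4))
        assert abs(len(shared) - expected) < 3 * sd


class TestVCF:
    def test_vcf_written_sorted_one_based(self, tmp_path):
        records = [
            SNPRecord("c2", 5, "A", "G", "sp", "fixed", "synonymous", 30, 99.0),
            SNPRecord("c1", 9, "T", "C", "sp", "polymorphic", "intron", 25, 45.0),
        ]
        path = tmp_path / "out.vcf"
        write_vcf(records, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert lines[0].startswith("c1\t10\t.\tT\tC")
        assert "STATUS=fixed" in lines[1] and "CLASS=synonymous" in lines[1]
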