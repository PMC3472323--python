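import numpy as np
import pandas as pd
import pytest

from exocap.capture_eval import (
    AlignmentRecord,
    build_pileup,
    coverage_summary,
    divergence_coverage,
    edge_profile,
    gc_coverage_relation,
    haploid_error_rate,
    identify_x_linked,
    per_target_coverage,
    read_sam,
    reproducibility,
    sensitivity,
    specificity,
    sry_check,
    write_sam,
)
from exocap.simulate import random_dna


def _rec(read_id, contig, pos, seq, **kw):
    return AlignmentRecord(read_id, contig, pos, seq, **kw)


class TestPileup:
    def test_full_coverage_stack(self):
        recs = [_rec(f"r{i}", "c", 0, "ACGTACGTAC") for i in range(3)]
        pile = build_pileup(recs, {"c": 10})
        assert (pile.depth["c"] == 3).all()
        assert pile.base_counts["c"][0, 0] == 3  # all A at position 0

    def test_staggered_reads_hand_stacked(self):
        recs = [
            _rec("r1", "c", 0, "AAAA"),
            _rec("r2", "c", 2, "AAAA"),
            _rec("r3", "c", 5, "AAA"),
        ]
        pile = build_pileup(recs, {"c": 10})
        assert pile.depth["c"].tolist() == [1, 1, 2, 2, 1, 2, 1, 1, 0, 0]

    def test_no_reads_all_zero(self):
        pile = build_pileup([], {"c": 5})
        assert pile.depth["c"].sum() == 0

    def test_duplicates_and_multimapped_excluded(self):
        recs = [
            _rec("u", "c", 0, "AAAA"),
            _rec("d", "c", 0, "AAAA", is_duplicate=True),
            _rec("m", "c", 0, "AAAA", is_unique=False),
        ]
        pile = build_pileup(recs, {"c": 4})
        assert (pile.depth["c"] == 1).all()

    def test_out_of_bounds_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_pileup([_rec("r", "c", 8, "AAAA")], {"c": 10})

    def test_sam_round_trip(self, tmp_path, rng):
        recs = [
            _rec("r1", "c", 3, random_dna(rng, 20),
                 quals=np.full(20, 34), sample_id="s1"),
            _rec("r2", "c", 10, random_dna(rng, 20), is_duplicate=True),
            _rec("r3", "c", 0, random_dna(rng, 20), is_unique=False),
        ]
        path = tmp_path / "x.sam"
        write_sam(recs, {"c": 50}, path)
        back, lengths = read_sam(path)
        assert lengths == {"c": 50}
        assert [(r.read_id, r.pos, r.seq) for r in back] == \
            [(r.read_id, r.pos, r.seq) for r in recs]
        assert back[1].is_duplicate and not back[2].is_unique
        assert back[0].sample_id == "s1"


class TestSensitivitySpecificity:
    SPANS = {f"t{i}": ("c", (i * 100, i * 100 + 50)) for i in range(4)}

    def test_all_targets_covered(self):
        recs = [_rec(f"r{i}", "c", i * 100, "A" * 50) for i in range(4)]
        pile = build_pileup(recs, {"c": 400})
        assert sensitivity(self.SPANS, pile) == 100.0

    def test_one_dropout(self):
        recs = [_rec(f"r{i}", "c", i * 100, "A" * 50) for i in range(3)]
        pile = build_pileup(recs, {"c": 400})
        assert sensitivity(self.SPANS, pile) == 75.0

    def test_specificity_counts_overlap_by_one_base(self):
        recs = [_rec("in", "c", 40, "A" * 20), _rec("out", "c", 50, "A" * 20)]
        # target t0 spans [0,50): "in" overlaps by 10, "out" by 0
        assert specificity(recs, {"t0": ("c", (0, 50))}) == 50.0

    def test_planted_in_target_fraction(self, rng):
        recs = [_rec(f"i{k}", "c", 0, "A" * 30) for k in range(25)]
        recs += [_rec(f"o{k}", "c", 200, "A" * 30) for k in range(75)]
        assert specificity(recs, {"t": ("c", (0, 100))}) == 25.0

    def test_zero_aligned_reads_is_missing(self):
        assert specificity([], {"t": ("c", (0, 10))}) is None

    def test_invariant_under_permutation(self, rng):
        recs = [_rec(f"r{k}", "c", int(rng.integers(0, 300)), "A" * 30)
                for k in range(50)]
        spans = {"t": ("c", (100, 200))}
        forward = specificity(recs, spans)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert specificity(shuffled, spans) == forward


class TestCoverageSummary:
    def test_threshold_fraction_conventions(self):
        # per-target mean depths 0.5, 6, 12
        spans = {"a": ("c", (0, 10)), "b": ("c", (10, 20)), "d": ("c", (20, 30))}
        recs = [_rec("r0", "c", 0, "AAAAA")]                      # mean 0.5 on a
        recs += [_rec(f"r{k}", "c", 10, "A" * 10) for k in range(1, 7)]   # 6 on b
        recs += [_rec(f"q{k}", "c", 20, "A" * 10) for k in range(12)]     # 12 on d
        pile = build_pileup(recs, {"c": 30})
        metrics = coverage_summary(pile, spans)
        assert metrics.threshold_fractions["ge1X"] == pytest.approx(2 / 3)
        assert metrics.threshold_fractions["gt5X"] == pytest.approx(2 / 3)
        assert metrics.threshold_fractions["gt10X"] == pytest.approx(1 / 3)

    def test_fractions_monotone_in_threshold(self, rng):
        spans = {f"t{i}": ("c", (i * 20, i * 20 + 20)) for i in range(10)}
        recs = [
            _rec(f"r{k}", "c", int(rng.integers(0, 180)), "A" * 20)
            for k in range(60)
        ]
        pile = build_pileup(recs, {"c": 200})
        metrics = coverage_summary(pile, spans, thresholds=(1, 5, 10))
        vals = list(metrics.threshold_fractions.values())
        assert vals == sorted(vals, reverse=True)


class TestEdgeProfile:
    def test_uniform_coverage_is_flat(self):
        spans = {"t": ("c", (0, 300))}
        recs = [_rec(f"r{k}", "c", 0, "A" * 300) for k in range(5)]
        pile = build_pileup(recs, {"c": 300})
        profile = edge_profile(pile, spans)
        assert (profile == 5.0).all()

    def test_depleted_edges_show_lower_first_bin(self):
        # reads cover only the interior [40, 260) of a 300-bp target
        spans = {"t": ("c", (0, 300))}
        recs = [_rec(f"r{k}", "c", 40, "A" * 220) for k in range(5)]
        pile = build_pileup(recs, {"c": 300})
        profile = edge_profile(pile, spans)
        assert profile.iloc[0] < profile.iloc[-1]

    def test_201bp_target_populates_bins_through_midpoint(self):
        spans = {"t": ("c", (0, 201))}
        recs = [_rec("r", "c", 0, "A" * 201)]
        pile = build_pileup(recs, {"c": 201})
        profile = edge_profile(pile, spans)
        assert list(profile.index) == [0, 1, 2, 3, 4, 5]

    def test_length_filter(self):
        spans = {"short": ("c", (0, 100))}
        pile = build_pileup([], {"c": 100})
        with pytest.raises(ValueError):
            edge_profile(pile, spans)


class TestGCRelation:
    def test_single_bin(self):
        cov = pd.Series({"t1": 10.0, "t2": 10.0})
        table = gc_coverage_relation({"t1": 0.51, "t2": 0.52}, cov)
        assert len(table) == 1
        assert table.iloc[0]["mean_coverage"] == 10.0

    def test_planted_quadratic_penalty_peaks_mid_gc(self, rng):
        gcs = {f"t{i}": g for i, g in enumerate(np.linspace(0.2, 0.8, 40))}
        cov = pd.Series(
            {t: 20 * (1 - 2.0 * (g - 0.5) ** 2) for t, g in gcs.items()}
        )
        table = gc_coverage_relation(gcs, cov)
        mid = table[(table.gc_bin >= 0.45) & (table.gc_bin < 0.55)]
        extreme = table[(table.gc_bin < 0.3) | (table.gc_bin >= 0.7)]
        assert mid["mean_coverage"].mean() > extreme["mean_coverage"].mean()


class TestReproducibility:
    def test_identical_libraries(self, rng):
        cov = pd.Series(rng.gamma(4, 3, size=50))
        df = pd.DataFrame({"l1": cov, "l2": cov})
        assert reproducibility(df)[("l1", "l2")] == pytest.approx(1.0)

    def test_independent_coverages_uncorrelated(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"l1": rng.gamma(4, 3, size=1000), "l2": rng.gamma(4, 3, size=1000)}
        )
        assert abs(reproducibility(df)[("l1", "l2")]) < 0.1

    def test_shared_efficiency_plus_noise_correlates(self):
        rng = np.random.default_rng(4)
        eff = rng.gamma(4, 5, size=200)
        df = pd.DataFrame({
            "l1": eff * rng.lognormal(0, 0.2, 200),
            "l2": eff * rng.lognormal(0, 0.2, 200),
        })
        assert reproducibility(df)[("l1", "l2")] > 0.8

    def test_too_few_shared_targets(self):
        df = pd.DataFrame({"l1": [1.0, 2.0], "l2": [1.0, 2.0]})
        with pytest.raises(ValueError):
            reproducibility(df)


class TestDivergenceCoverage:
    def test_single_bin_when_no_divergence(self):
        cov = pd.Series({"t1": 10.0, "t2": 12.0})
        table = divergence_coverage({"t1": 0.0, "t2": 0.005}, cov)
        assert len(table) == 1

    def test_low_support_flagging(self):
        cov = pd.Series({"t1": 10.0, "t2": 8.0, "t3": 9.0, "t4": 2.0})
        table = divergence_coverage(
            {"t1": 0.001, "t2": 0.002, "t3": 0.003, "t4": 0.08}, cov
        )
        by_bin = table.set_index("divergence_bin")
        assert not by_bin.loc[0.0, "low_support"]
        assert bool(by_bin.loc[0.08, "low_support"])


class TestHaploidErrorRate:
    def test_error_free_reads_give_zero(self, rng):
        seq = random_dna(rng, 500)
        recs = [_rec(f"r{k}", "m", 0, seq) for k in range(15)]
        pile = build_pileup(recs, {"m": 500})
        mism, aligned, rate, _ = haploid_error_rate(pile, [("m", (0, 500))])
        assert mism == 0 and rate == 0.0 and aligned == 15 * 500

    def test_planted_error_rate_recovered(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 2000)
        e = 4e-4
        recs = []
        for k in range(100):   # 200k stacked bases
            bases = list(seq)
            for pos in np.nonzero(rng.random(2000) < e)[0]:
                bases[pos] = [b for b in "ACGT" if b != bases[pos]][
                    int(rng.integers(0, 3))
                ]
            recs.append(_rec(f"r{k}", "m", 0, "".join(bases)))
        pile = build_pileup(recs, {"m": 2000})
        mism, aligned, rate, phred = haploid_error_rate(pile, [("m", (0, 2000))])
        sd = np.sqrt(e * (1 - e) / aligned)
        assert abs(rate - e) < 3 * sd
        assert 30 < phred < 38

    def test_no_coverage_is_error(self):
        pile = build_pileup([], {"m": 100})
        with pytest.raises(ValueError):
            haploid_error_rate(pile, [("m", (0, 100))])


class TestSexLinkedControls:
    def test_ratio_window_selection(self):
        cov = pd.DataFrame(
            {"f1": [20.0, 10.0], "f2": [20.0, 10.0],
             "m1": [10.0, 10.0], "m2": [10.0, 10.0]},
            index=["x_target", "auto_target"],
        )
        sexes = {"f1": "F", "f2": "F", "m1": "M", "m2": "M"}
        out = identify_x_linked(cov, sexes)
        assert bool(out.loc["x_target", "x_linked"])
        assert not bool(out.loc["auto_target", "x_linked"])

    def test_zero_male_coverage_skipped(self):
        cov = pd.DataFrame({"f1": [20.0], "m1": [0.0]}, index=["t"])
        out = identify_x_linked(cov, {"f1": "F", "m1": "M"})
        assert bool(out.loc["t", "skipped_zero_male"])
        assert not bool(out.loc["t", "x_linked"])

    def test_sry_flags(self):
        counts = {"f_clean": 0, "f_contam": 6, "m_ok": 40, "m_fail": 0}
        sexes = {"f_clean": "F", "f_contam": "F", "m_ok": "M", "m_fail": "M"}
        table = sry_check(counts, sexes).set_index("sample")
        assert table.loc["f_clean", "flag"] == "pass"
        assert table.loc["f_contam", "flag"] == "possible_contamination"
        assert table.loc["m_ok", "flag"] == "pass"
        assert table.loc["m_fail", "flag"] == "possible_capture_failure"
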