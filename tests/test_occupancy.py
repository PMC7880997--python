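"""Windowed differential ChIP: counting, TMM, NB testing, regions, motifs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insulscope import occupancy as oc
from insulscope import synthdata as sd


def brute_force_window_counts(reads, grid):
    counts = np.zeros(grid.n_windows, dtype=int)
    for k in range(grid.n_windows):
        ws, we = k * grid.spacing, k * grid.spacing + grid.width
        for _, r in reads.iterrows():
            if r["start"] < we and ws < r["end"]:
                counts[k] += 1
    return counts


class TestCountWindows:
    def test_matches_brute_force_overlap(self, rng):
        grid = oc.WindowGrid.over_length(1000)
        reads = pd.DataFrame(
            {
                "start": rng.integers(0, 950, 60),
                "strand": rng.choice(["+", "-"], 60),
            }
        ).assign(end=lambda d: d["start"] + rng.integers(15, 60, 60))
        got = oc.count_windows(reads, grid, dedup=False)
        assert np.array_equal(got, brute_force_window_counts(reads, grid))

    def test_duplicate_reads_counted_once_with_dedup(self):
        grid = oc.WindowGrid.over_length(200)
        reads = pd.DataFrame(
            {"start": [50, 50], "end": [70, 70], "strand": ["+", "+"]}
        )
        assert oc.count_windows(reads, grid, dedup=True).max() == 1
        assert oc.count_windows(reads, grid, dedup=False).max() == 2

    def test_empty_input_gives_zero_table(self):
        grid = oc.WindowGrid.over_length(500)
        out = oc.count_windows(pd.DataFrame(columns=["start", "end"]), grid)
        assert out.shape == (grid.n_windows,) and not out.any()


class TestFilterWindows:
    def test_uniform_coverage_retains_nothing(self):
        table = pd.DataFrame({"s1": np.full(100, 10), "s2": np.full(100, 10)})
        assert not oc.filter_windows(table, fold=3.0).any()

    def test_tenfold_window_retained(self):
        counts = np.full(100, 10)
        counts[7] = 100
        table = pd.DataFrame({"s1": counts, "s2": counts})
        keep = oc.filter_windows(table, fold=3.0)
        assert keep[7] and keep.sum() == 1

    def test_planted_peaks_exactly_recovered(self):
        peaks = np.arange(40, 50)
        conds = [sd.ChipCondition("a", 2, 20.0, fold=8.0), sd.ChipCondition("b", 2, 20.0, fold=8.0)]
        table = sd.simulate_chip_window_counts(peaks, 2000, conds, 0.05, seed=8)
        keep = oc.filter_windows(table, fold=3.0)
        assert set(np.flatnonzero(keep)) == set(peaks)


class TestTmmFactors:
    def test_identical_libraries_give_unit_factors(self):
        table = pd.DataFrame({"a": np.arange(1, 101), "b": np.arange(1, 101)})
        f = oc.tmm_factors(table)
        assert np.allclose(f, 1.0)

    def test_product_is_anchored_to_one(self, rng):
        table = pd.DataFrame(rng.poisson(30, (500, 4)) + 1, columns=list("abcd"))
        f = oc.tmm_factors(table)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-10)

    def test_twofold_library_ratio_recovered(self):
        ratio = __import__("insulscope.experiments", fromlist=["x"]).tmm_library_ratio(seed=5)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_all_zero_sample_raises(self):
        table = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            oc.tmm_factors(table)


class TestTestWindows:
    def test_identical_counts_give_zero_log2fc(self):
        table = pd.DataFrame({"a_rep1": [30], "a_rep2": [32], "b_rep1": [30], "b_rep2": [32]})
        cond = {c: c.split("_")[0] for c in table.columns}
        res = oc.test_windows(table, cond, ("a", "b"), dispersion=0.05)
        assert res["log2fc"][0] == 0.0

    def test_planted_fourfold_log2fc(self):
        peaks = np.arange(100, 200)
        conds = [sd.ChipCondition("a", 2, 50.0, 1.0), sd.ChipCondition("b", 2, 50.0, 4.0)]
        table = sd.simulate_chip_window_counts(peaks, 3000, conds, 0.05, seed=12)
        cond = {c: c.split("_")[0] for c in table.columns}
        res = oc.test_windows(table, cond, ("a", "b"))
        assert np.median(res["log2fc"].to_numpy()[peaks]) == pytest.approx(2.0, abs=0.3)

    def test_missing_condition_raises(self):
        table = pd.DataFrame({"a_rep1": [3]})
        with pytest.raises(ValueError, match="replicate"):
            oc.test_windows(table, {"a_rep1": "a"}, ("a", "b"))

    def test_null_pvalues_roughly_uniform_upper_tail(self):
        rate = __import__("insulscope.experiments", fromlist=["x"]).chip_type_one_rate(
            n_windows=4000, seed=3
        )
        assert 0.02 <= rate <= 0.08


class TestCombineRegions:
    def test_simes_closed_form(self):
        assert oc.simes_p(np.array([0.01, 0.04])) == pytest.approx(0.02)

    def test_single_isolated_window_is_its_own_region(self):
        res = pd.DataFrame({"p": [1e-6], "log2fc": [3.0]})
        out = oc.combine_regions(res, np.array([100]), 20, fdr=0.01, min_fc=2.0)
        assert len(out) == 1
        assert out["start"][0] == 100 and out["end"][0] == 120
        assert out["best_pos"][0] == 110

    def test_reported_regions_satisfy_thresholds(self, rng):
        n = 200
        res = pd.DataFrame(
            {"p": rng.uniform(0, 1, n) ** 3, "log2fc": rng.normal(0, 2, n)}
        )
        starts = np.arange(n) * 10
        out = oc.combine_regions(res, starts, 20, fdr=0.01, min_fc=2.0)
        assert (out["fdr"] < 0.01).all()
        assert (out["occupancy"].abs() > 1.0).all()

    def test_occupancy_is_best_window_log2fc(self):
        res = pd.DataFrame({"p": [0.5, 1e-8, 0.3], "log2fc": [1.0, 4.0, 2.0]})
        out = oc.combine_regions(res, np.array([0, 10, 20]), 20, fdr=0.05, min_fc=2.0)
        assert len(out) == 1
        assert out["occupancy"][0] == 4.0
        assert out["best_pos"][0] == 20.0  # center of the winning window


class TestClassifyDependency:
    def _peaks(self, intervals):
        return pd.DataFrame(intervals, columns=["start", "end"])

    def test_no_mutant_overlap_is_strict(self):
        out = oc.classify_peak_dependency(
            self._peaks([(0, 100)]), self._peaks([]), self._peaks([])
        )
        assert list(out["class"]) == [oc.STRICT_DEP]

    def test_full_overlap_without_reduction_is_independent(self):
        out = oc.classify_peak_dependency(
            self._peaks([(0, 100)]), self._peaks([(0, 100)]), self._peaks([])
        )
        assert list(out["class"]) == [oc.INDEPENDENT]

    def test_overlap_with_reduction_is_partial(self):
        out = oc.classify_peak_dependency(
            self._peaks([(0, 100)]), self._peaks([(0, 100)]), self._peaks([(0, 100)])
        )
        assert list(out["class"]) == [oc.PARTIAL_DEP]

    def test_partial_overlap_splits_fragments(self):
        out = oc.classify_peak_dependency(
            self._peaks([(0, 100)]), self._peaks([(60, 100)]), self._peaks([])
        )
        assert len(out) == 2
        frag = {(r["start"], r["end"]): r["class"] for _, r in out.iterrows()}
        assert frag[(0.0, 60.0)] == oc.STRICT_DEP
        assert frag[(60.0, 100.0)] == oc.INDEPENDENT

    def test_synthetic_three_way_recovery(self):
        """10 strict / 10 partial / 30 independent planted peaks: >= 90% of
        truth peaks receive the right majority label."""
        from insulscope.pipeline import RunConfig, run_chip_scenario

        lab_map = {
            "strict": oc.STRICT_DEP,
            "partial": oc.PARTIAL_DEP,
            "independent": oc.INDEPENDENT,
        }
        correct = tot = 0
        for seed in range(3):
            chip = run_chip_scenario(RunConfig(), seed)
            frags, truth = chip["fragments"], chip["truth"]
            for _, t in truth.iterrows():
                tot += 1
                s, e = t["start"], t["start"] + 70
                over = frags[(frags["start"] < e) & (frags["end"] > s)]
                if len(over):
                    by_len = (
                        over.assign(length=over["end"] - over["start"])
                        .groupby("class")["length"]
                        .sum()
                    )
                    correct += by_len.idxmax() == lab_map[t["label"]]
        assert correct / tot >= 0.9


class TestPwmScan:
    def test_consensus_scores_maximal_on_plus_strand(self):
        pwm = oc.pwm_from_consensus("ACGTAC")
        hits = oc.pwm_scan("ACGTAC", pwm, threshold=-np.inf)
        plus = hits[hits["strand"] == "+"]
        assert plus["score"].max() == hits["score"].max()
        assert plus.loc[plus["score"].idxmax(), "pos"] == 0

    def test_reverse_complement_hits_minus_strand_same_score(self):
        pwm = oc.pwm_from_consensus("ACGTAC")
        fwd = oc.pwm_scan("ACGTAC", pwm, threshold=-np.inf)
        rev = oc.pwm_scan(oc.revcomp("ACGTAC"), pwm, threshold=-np.inf)
        assert (
            rev[rev["strand"] == "-"]["score"].max()
            == fwd[fwd["strand"] == "+"]["score"].max()
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=30))
    def test_strand_symmetry_exact(self, seq):
        pwm = oc.pwm_from_consensus("ACGTACGT")
        fwd = oc.pwm_scan(seq, pwm, threshold=-np.inf)
        rev = oc.pwm_scan(oc.revcomp(seq), pwm, threshold=-np.inf)
        a = np.sort(fwd[fwd["strand"] == "+"]["score"].to_numpy())
        b = np.sort(rev[rev["strand"] == "-"]["score"].to_numpy())
        assert np.allclose(a, b)

    def test_bad_alphabet_raises(self):
        pwm = oc.pwm_from_consensus("ACGT")
        with pytest.raises(ValueError, match="outside"):
            oc.pwm_scan("ACXT", pwm)

    def test_n_scores_as_background(self):
        pwm = oc.pwm_from_consensus("ACGT")
        hits = oc.pwm_scan("ANGT", pwm, threshold=-np.inf)
        full = oc.pwm_scan("ACGT", pwm, threshold=-np.inf)
        top_n = hits[(hits["strand"] == "+") & (hits["pos"] == 0)]["score"].iloc[0]
        top_full = full[(full["strand"] == "+") & (full["pos"] == 0)]["score"].iloc[0]
        assert top_n < top_full


class TestReporterMotifs:
    def test_wildtype_and_mutant_sites_differ_at_two_positions(self):
        assert oc.hamming_distance(oc.REPORTER_MOTIF_WT, oc.REPORTER_MOTIF_MUT) == 2

    def test_mutant_scores_below_wildtype_under_matching_pwm(self):
        """Any PWM whose consensus equals the wildtype site at the mutated
        columns scores the mutant strictly lower."""
        pwm = oc.pwm_from_consensus(oc.REPORTER_MOTIF_WT)
        wt = oc.pwm_scan(oc.REPORTER_MOTIF_WT, pwm, threshold=-np.inf)["score"].max()
        mut = oc.pwm_scan(oc.REPORTER_MOTIF_MUT, pwm, threshold=-np.inf)["score"].max()
        assert mut < wt
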