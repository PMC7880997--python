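"""Distance profiles, controls, category tests, proximity, reporter ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from insulscope import association as ac

def brute_force_profile(anchors, features, bin_width, span, strands=None):
    offsets = np.arange(-span, span, bin_width)
    pct = np.zeros(offsets.size)
    for m, o in enumerate(offsets):
        hits = 0
        for k, a in enumerate(anchors):
            if strands is not None and strands[k] == "-":
                lo, hi = a - (o + bin_width), a - o
            else:
                lo, hi = a + o, a + o + bin_width
            if any(lo <= f < hi for f in features):
                hits += 1
        pct[m] = 100 * hits / len(anchors)
    return pct


def fisher_enumeration(table):
    """Exact two-sided Fisher p by enumerating all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            stats.hypergeom.pmf(x, n, r1, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestDistanceProfile:
    def test_features_at_anchors_give_full_central_bin(self):
        anchors = np.array([10_000.0, 30_000.0, 77_000.0])
        prof = ac.distance_profile(anchors, anchors, 2000, 10_000)
        assert prof.percent[prof.offsets == 0][0] == 100.0

    def test_no_features_gives_zero_everywhere(self):
        prof = ac.distance_profile(np.array([5000.0]), np.array([]), 2000, 10_000)
        assert not prof.percent.any()

    def test_empty_anchors_raise(self):
        with pytest.raises(ValueError, match="anchor"):
            ac.distance_profile(np.array([]), np.array([1.0]))

    def test_matches_brute_force_on_fuzzed_inputs(self, rng):
        for _ in range(10):
            anchors = rng.uniform(0, 100_000, 15)
            feats = rng.uniform(0, 100_000, 40)
            strands = rng.choice(["+", "-"], anchors.size)
            prof = ac.distance_profile(anchors, feats, 2000, 10_000, strands)
            expect = brute_force_profile(anchors, feats, 2000, 10_000, strands)
            assert np.allclose(prof.percent, expect)

    def test_poisson_scatter_matches_closed_form(self):
        """Per-bin percentage ~ 100 * (1 - exp(-lambda * bin)) over 50 seeds."""
        lam = 1 / 4000
        vals = []
        for s in range(50):
            rng = np.random.default_rng(s)
            feats = rng.uniform(0, 1e6, rng.poisson(lam * 1e6))
            anchors = rng.uniform(50_000, 950_000, 100)
            prof = ac.distance_profile(anchors, feats, 2000, 10_000)
            vals.append(prof.percent.mean())
        expect = 100 * (1 - np.exp(-lam * 2000))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 3 * se + 0.5


class TestControls:
    def test_random_control_reproducible_and_sized(self, genome):
        a = ac.random_control(50, genome, "chrSim", seed=9)
        b = ac.random_control(50, genome, "chrSim", seed=9)
        assert np.array_equal(a, b) and a.size == 50

    def test_random_control_respects_mask(self, genome):
        mask = np.zeros(500, dtype=bool)
        mask[100:110] = True
        pos = ac.random_control(200, genome, "chrSim", valid_mask=mask, seed=1)
        assert ((pos >= 200_000) & (pos < 220_000)).all()

    def test_matched_control_preserves_bin_composition(self, rng):
        genes = pd.DataFrame({"expression": rng.normal(4, 2, 3000)})
        cases, pool = genes.iloc[:300], genes.iloc[300:]
        ctrl = ac.matched_control_sample(cases, pool, n_bins=20, seed=2)
        assert len(ctrl) == len(cases)
        edges = np.quantile(
            np.concatenate([cases["expression"], pool["expression"]]),
            np.linspace(0, 1, 21),
        )
        edges[0], edges[-1] = -np.inf, np.inf
        hc = np.histogram(cases["expression"], edges)[0]
        hm = np.histogram(ctrl["expression"], edges)[0]
        assert np.array_equal(hc, hm)

    def test_matched_control_mean_close_over_seeds(self, rng):
        genes = pd.DataFrame({"expression": rng.normal(4, 2, 2000)})
        cases, pool = genes.iloc[:150], genes.iloc[150:]
        diffs = [
            abs(
                ac.matched_control_sample(cases, pool, seed=s)["expression"].mean()
                - cases["expression"].mean()
            )
            for s in range(50)
        ]
        assert np.mean(diffs) < 0.1

    def test_insufficient_pool_bin_raises(self, rng):
        # cases occupy a high-expression stratum the pool never reaches
        cases = pd.DataFrame({"expression": rng.normal(10, 0.1, 20)})
        pool = pd.DataFrame({"expression": rng.normal(0, 0.1, 100)})
        with pytest.raises(ValueError, match="bin"):
            ac.matched_control_sample(cases, pool, n_bins=10, seed=1)


class TestFoldEnrichment:
    def _profile(self, percents):
        offsets = np.arange(-4000, 4000, 2000)
        return ac.DistanceProfile(offsets, np.asarray(percents, float), 10, 2000)

    def test_identical_profiles_give_fold_one(self):
        p = self._profile([5, 10, 10, 5])
        assert ac.fold_enrichment_at_center(p, p) == pytest.approx(1.0)

    def test_simple_ratio(self):
        case = self._profile([0, 10, 10, 0])
        ctrl = self._profile([0, 2, 2, 0])
        assert ac.fold_enrichment_at_center(case, ctrl) == pytest.approx(5.0)

    def test_zero_control_reports_infinite(self):
        case = self._profile([0, 10, 10, 0])
        ctrl = self._profile([0, 0, 0, 0])
        assert np.isinf(ac.fold_enrichment_at_center(case, ctrl))


class TestCategoryTests:
    def test_identical_rows_give_p_one(self):
        _, p = ac.fisher_test(np.array([[5, 5], [5, 5]]))
        assert p == pytest.approx(1.0)

    def test_fisher_matches_enumeration_for_small_margins(self):
        """Exhaustive check over all 2x2 tables with margins <= 12."""
        for a, b, c, d in itertools.product(range(5), repeat=4):
            table = np.array([[a, b], [c, d]])
            if table.sum() == 0 or table.sum() > 12:
                continue
            _, p = ac.fisher_test(table)
            assert p == pytest.approx(fisher_enumeration(table), abs=1e-10)

    def test_wilcoxon_identical_samples(self):
        x = np.arange(30.0)
        _, p = ac.wilcoxon_rank_sum(x, x)
        assert p >= 0.99

    def test_wilcoxon_matches_permutation_oracle(self, rng):
        """Normal-approximation p within 10% of a permutation p at n = 8+8."""
        x = rng.normal(0, 1, 8)
        y = rng.normal(1.0, 1, 8)
        w, p = ac.wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        obs = stats.rankdata(pooled)[:8].sum()
        count = 0
        reps = 20000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            r = stats.rankdata(perm)[:8].sum()
            if abs(r - 68) >= abs(obs - 68):  # 68 = n1*(n+1)/2 null mean
                count += 1
        p_perm = count / reps
        assert p == pytest.approx(p_perm, rel=0.1, abs=0.01)


class TestProximityCount:
    def test_no_small_intervals_counts_zero(self):
        intervals = pd.DataFrame({"start": [0], "end": [10_000]})
        count, frac = ac.proximity_count(np.array([5000.0]), intervals)
        assert count == 0 and frac == 0.0

    def test_small_interval_near_boundary_counted(self):
        intervals = pd.DataFrame({"start": [3000], "end": [6000]})  # 3 kb, center 4500
        count, frac = ac.proximity_count(np.array([5500.0]), intervals)
        assert count == 1 and frac == 1.0

    def test_matches_brute_force_on_fuzzed_inputs(self, rng):
        for _ in range(20):
            boundaries = np.sort(rng.uniform(0, 200_000, rng.integers(1, 15)))
            starts = rng.uniform(0, 200_000, 30)
            lengths = rng.uniform(500, 8000, 30)
            intervals = pd.DataFrame({"start": starts, "end": starts + lengths})
            count, _ = ac.proximity_count(boundaries, intervals)
            expect = 0
            for s, e in zip(starts, starts + lengths):
                if e - s <= 4000 and np.min(np.abs((s + e) / 2 - boundaries)) <= 2000:
                    expect += 1
            assert count == expect


class TestReporterRatio:
    def test_unit_ratios_give_zero_median(self):
        rep = pd.DataFrame({"mcherry": np.ones(101), "egfp": np.ones(101)})
        medians, mean = ac.reporter_ratio_summary([rep])
        assert medians == [0.0] and mean == 0.0

    def test_odd_n_median_is_middle_order_statistic(self):
        mc = np.array([1.0, 2.0, 8.0])
        rep = pd.DataFrame({"mcherry": mc, "egfp": np.ones(3)})
        medians, _ = ac.reporter_ratio_summary([rep])
        assert medians[0] == pytest.approx(1.0)  # log2(2)

    def test_nonpositive_cells_dropped(self):
        rep = pd.DataFrame({"mcherry": [1.0, -1.0, 4.0], "egfp": [1.0, 1.0, 1.0]})
        medians, _ = ac.reporter_ratio_summary([rep])
        assert medians[0] == pytest.approx(1.0)  # median of log2{1, 4} = 1

    def test_lognormal_suppression_recovered(self):
        """EGFP suppressed 4-fold: summary ~ log2(4) = 2 across 20 seeds."""
        summaries = []
        for s in range(20):
            rng = np.random.default_rng(s)
            reps = []
            for _ in range(3):
                egfp = rng.lognormal(0, 0.5, 2000)
                mch = rng.lognormal(0, 0.5, 2000) * 4
                reps.append(pd.DataFrame({"mcherry": mch, "egfp": egfp}))
            summaries.append(ac.reporter_ratio_summary(reps)[1])
        assert np.mean(summaries) == pytest.approx(2.0, abs=0.1)


class TestAveragedControl:
    def test_averaged_control_is_flatter_than_single_draw(self, genome, rng):
        feats = rng.uniform(0, 1_000_000, 300)
        single = ac.distance_profile(
            ac.random_control(100, genome, "chrSim", seed=4), feats, 2000, 20_000
        )
        avg = ac.averaged_random_control_profile(
            100, feats, genome, "chrSim", n_draws=20, seed=4
        )
        assert np.array_equal(avg.offsets, single.offsets)
        assert avg.percent.std() < single.percent.std()
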