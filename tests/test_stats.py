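import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import coralkrige as ck
from coralkrige.pipeline import ProbabilityMap
from coralkrige.stats import BIN_LABELS, dhw_trends_by_subset


def make_map(probs_by_cell, year=2000, provenance="kriged"):
    return ProbabilityMap(year=year, probabilities=probs_by_cell, provenance={"R": provenance})


def row_cells(n, j=1800):
    return [ck.CellIndex(3600 + k, j) for k in range(n)]


class TestWelch:
    def test_hand_example(self):
        res = ck.welch_t_test([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_identical_samples_t_zero_p_one(self):
        res = ck.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_swapping_negates_t_keeps_p(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 4.0, 9.0, 3.0]
        r1, r2 = ck.welch_t_test(a, b), ck.welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_sign_matches_mean_difference(self):
        res = ck.welch_t_test([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert res.t > 0 and res.mean_x > res.mean_y

    def test_agrees_with_scipy_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(2, 40)))
            y = rng.normal(0.3, 2, int(rng.integers(2, 40)))
            mine = ck.welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_both_sides_error(self):
        with pytest.raises(ValueError):
            ck.welch_t_test([1.0, 1.0], [1.0, 1.0])

    def test_too_small_sample_error(self):
        with pytest.raises(ValueError):
            ck.welch_t_test([1.0], [1.0, 2.0])


class TestBinning:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.05, "<=10%"), (0.10, "<=10%"),
            (0.33, ">10-33%"), (0.50, ">33-50%"),
            (0.66, ">50-66%"), (0.90, ">66-90%"),
            (0.901, ">90%"), (1.0, ">90%"), (0.0, "<=10%"),
        ],
    )
    def test_boundaries_upper_inclusive(self, p, label):
        assert ck.probability_bin(p) == label

    def test_partition_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(1)
        cells = row_cells(300)
        pmap = make_map({c: float(v) for c, v in zip(cells, rng.random(300))})
        bins = ck.bin_by_probability(pmap)
        sizes = sum(len(v) for v in bins.values())
        assert sizes == 300
        seen = [c for v in bins.values() for c in v]
        assert len(set(seen)) == len(seen)

    def test_no_data_cells_left_out(self):
        cells = row_cells(2)
        pmap = make_map({cells[0]: 0.5, cells[1]: math.nan})
        bins = ck.bin_by_probability(pmap)
        assert sum(len(v) for v in bins.values()) == 1


class TestDhwByBin:
    def build(self, probs, dhws, year=2000):
        cells = row_cells(len(probs))
        pmap = make_map({c: p for c, p in zip(cells, probs)}, year=year)
        amax = pd.DataFrame([dhws], index=pd.Index([year], name="year"))
        return [pmap], amax, cells

    def test_bin_means_match_brute_force_grouping(self):
        rng = np.random.default_rng(2)
        probs = rng.random(200)
        dhws = rng.exponential(3, 200)
        maps, amax, cells = self.build(probs, dhws)
        table = ck.dhw_by_bin_table(maps, amax, cells).set_index("bin")
        # independent oracle
        for label in BIN_LABELS:
            sel = np.array([ck.probability_bin(p) == label for p in probs])
            if sel.any():
                assert table.loc[label, "mean_dhw"] == pytest.approx(dhws[sel].mean(), abs=1e-12)
                assert table.loc[label, "n"] == sel.sum()
        assert table.loc["all cells", "n"] == 200
        assert table.drop("all cells")["n"].sum() == 200

    def test_all_equal_probabilities_single_occupied_bin(self):
        maps, amax, cells = self.build([0.95] * 10, np.arange(10.0))
        table = ck.dhw_by_bin_table(maps, amax, cells)
        occupied = table[table["n"] > 0]
        assert set(occupied["bin"]) == {"all cells", ">90%"}

    def test_monotone_dhw_link_gives_increasing_bin_means(self):
        rng = np.random.default_rng(3)
        dhws = rng.uniform(0, 12, 500)
        probs = 1 / (1 + np.exp(-(-4 + 1.0 * dhws)))  # noise-free logistic link
        maps, amax, cells = self.build(probs, dhws)
        table = ck.dhw_by_bin_table(maps, amax, cells).set_index("bin")
        means = [table.loc[lab, "mean_dhw"] for lab in BIN_LABELS if table.loc[lab, "n"] > 0]
        assert np.all(np.diff(means) > 0)


class TestExtent:
    def test_all_cells_very_likely(self):
        cells = row_cells(10)
        maps = [make_map({c: 0.95 for c in cells})]
        df = ck.extent_summary(maps, cells).set_index("metric")
        assert df.loc["prob>0.9", "fraction"] == 1.0
        assert df.loc["prob>0.66", "fraction"] == 1.0

    def test_at_least_once_semantics_across_years(self):
        cells = row_cells(4)
        m1 = make_map({cells[0]: 0.7, cells[1]: 0.1, cells[2]: 0.2, cells[3]: 0.1}, year=2000)
        m2 = make_map({cells[0]: 0.1, cells[1]: 0.1, cells[2]: 0.95, cells[3]: 0.1}, year=2001)
        df = ck.extent_summary([m1, m2], cells).set_index("metric")
        assert df.loc["prob>0.66", "n_cells"] == 2   # cells[0] once, cells[2] once
        assert df.loc["prob>0.9", "n_cells"] == 1

    def test_likely_count_at_least_very_likely_count(self, small_world_run):
        result, _ = small_world_run
        cells = list(result.maps[0].probabilities)
        df = ck.extent_summary(result.maps, cells).set_index("metric")
        assert df.loc["prob>0.66", "n_cells"] >= df.loc["prob>0.9", "n_cells"]

    def test_fractions_equal_oracle_recount(self):
        rng = np.random.default_rng(4)
        cells = row_cells(50)
        maps = [make_map({c: float(v) for c, v in zip(cells, rng.random(50))}, year=y)
                for y in (2000, 2001)]
        df = ck.extent_summary(maps, cells).set_index("metric")
        for thr, metric in [(0.66, "prob>0.66"), (0.9, "prob>0.9")]:
            brute = sum(
                1 for c in cells if any(m.probabilities[c] > thr for m in maps)
            )
            assert df.loc[metric, "n_cells"] == brute
            assert df.loc[metric, "fraction"] == pytest.approx(brute / 50)


class TestTrend:
    def test_exact_line_recovered(self):
        vals = {1985 + k: 2.0 + 0.06 * k for k in range(33)}
        res = ck.trend_ols(vals)
        assert res.slope == pytest.approx(0.06, abs=1e-12)
        assert res.p < 1e-12

    def test_white_noise_type_one_error_rate(self):
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            vals = {1985 + k: float(v) for k, v in enumerate(rng.normal(0, 1, 33))}
            if ck.trend_ols(vals).p < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.015

    def test_requires_three_years(self):
        with pytest.raises(ValueError):
            ck.trend_ols({2000: 1.0, 2001: 2.0})

    def test_slope_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        beta = 0.06
        hits = 0
        for _ in range(200):
            noise = rng.normal(0, 0.3, 33)
            vals = {1985 + k: 2.0 + beta * k + noise[k] for k in range(33)}
            res = ck.trend_ols(vals)
            if abs(res.slope - beta) <= 3 * res.stderr:
                hits += 1
        assert hits / 200 >= 0.95


class TestCompareReportsVsAll:
    def test_fallback_map_presence_mean_is_one(self):
        cells = row_cells(20)
        pres = set(cells[:3])
        pmap = make_map({c: (1.0 if c in pres else 0.0) for c in cells}, provenance="fallback")
        res = ck.compare_reports_vs_all(pmap, pres)
        assert res.mean_x == 1.0
        assert res.mean_x > res.mean_y

    def test_constant_map_zero_variance_error(self):
        cells = row_cells(10)
        pmap = make_map({c: 0.4 for c in cells})
        with pytest.raises(ValueError):
            ck.compare_reports_vs_all(pmap, set(cells[:3]))

    def test_kriged_world_contrast_significant(self, small_world, small_world_run):
        result, cfg = small_world_run
        w = small_world
        located, _ = ck.snap_reports(
            ck.parse_reports(w.reports).reports, w.mask, max_snap_km=cfg.max_snap_km
        )
        pooled_pres, pooled_all = [], []
        for m in result.maps:
            pres = ck.presence_cells(located, m.year)
            pooled_pres += [p for c, p in m.probabilities.items() if c in pres and not math.isnan(p)]
            pooled_all += [p for p in m.probabilities.values() if not math.isnan(p)]
        res = ck.welch_t_test(pooled_pres, pooled_all)
        assert res.mean_x > res.mean_y
        assert res.p < 0.05


class TestTrendsBySubset:
    def test_subset_rows_present(self, small_world_run):
        result, _ = small_world_run
        cells = list(result.maps[0].probabilities)
        df = dhw_trends_by_subset(result.maps, result.annual_max, cells)
        assert set(df["subset"]) == {"all cells", "prob>0.66", "prob>0.9"}


class TestRankAuc:
    def test_perfect_separation(self):
        assert ck.rank_auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        auc = ck.rank_auc(rng.random(2000), rng.random(2000))
        assert abs(auc - 0.5) < 0.05

    def test_matches_probability_interpretation(self):
        pos, neg = [0.7, 0.2], [0.5, 0.1]
        # pairs: (0.7>0.5),(0.7>0.1),(0.2<0.5),(0.2>0.1) -> 3/4
        assert ck.rank_auc(pos, neg) == pytest.approx(0.75)
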