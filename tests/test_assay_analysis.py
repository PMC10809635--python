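import numpy as np
import pandas as pd
import pytest

from colonyfit.assay_analysis import (
    AssayDataset,
    AssayPlate,
    ContaminatedPlateError,
    compare_groups,
    lawn_qc,
    recovery_check,
    scale_dauer_count,
    summarize,
    tradeoff_table,
    yield_timecourse,
)

from _oracle import oneway_anova_brute, tukey_brute, twoway_anova_brute_balanced
from conftest import plates_frame


class TestScaleDauerCount:
    @pytest.mark.parametrize(
        "counts, volume, expected",
        [((10, 12, 14), 5.0, 60.0), ((0, 0, 0), 3.0, 0.0), ((7, 8, 9), 2.5, 20.0)],
    )
    def test_mean_count_times_volume(self, counts, volume, expected):
        plate = AssayPlate(3, "r1", 120.0, 72, counts, volume)
        assert scale_dauer_count(plate) == expected

    def test_contaminated_plate_refused_with_reason(self):
        plate = AssayPlate(3, "r9", 120.0, 72, (5, 5, 5), 5.0, contaminated=True)
        with pytest.raises(ContaminatedPlateError, match="r9"):
            scale_dauer_count(plate)


class TestSummarize:
    def test_identical_values_give_zero_sd(self):
        rows = [(3, f"r{i}", 51.0, 72, 10, 10, 10, 5.0, False) for i in range(3)]
        s = summarize(AssayDataset(plates_frame(rows)))
        assert s.bust["mean"].item() == 51.0 and s.bust["sd"].item() == 0.0

    def test_textbook_sample_sd(self):
        rows = [
            (3, f"r{i}", b, 72, c, c, c, 1.0, False)
            for i, (b, c) in enumerate([(100.0, 2), (110.0, 4), (120.0, 6)])
        ]
        s = summarize(AssayDataset(plates_frame(rows)))
        grp = s.dauer_yield.iloc[0]
        assert grp["mean"] == 4.0 and grp["sd"] == 2.0 and grp["n"] == 3

    def test_contaminated_plates_never_counted(self, small_dataset):
        plates = small_dataset.plates.copy()
        extra = plates.iloc[:2].copy()
        extra["count1"] = 99999
        extra["contaminated"] = True
        with_bad = AssayDataset(pd.concat([plates, extra], ignore_index=True))
        clean = summarize(small_dataset)
        dirty = summarize(with_bad)
        pd.testing.assert_frame_equal(clean.dauer_yield, dirty.dauer_yield)

    def test_permutation_invariance(self, small_dataset):
        shuffled = AssayDataset(
            small_dataset.plates.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        a = summarize(small_dataset).dauer_yield.reset_index(drop=True)
        b = summarize(shuffled).dauer_yield.reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_bust_excluded_from_speed_only(self, small_dataset):
        plates = small_dataset.plates.copy()
        plates.loc[plates["founder_number"] == 10, "bust_hr"] = np.nan
        s = summarize(AssayDataset(plates))
        assert 10 not in set(s.bust["founder_number"])
        assert ("bust_hr", 10) in s.missing
        assert 10 in set(s.dauer_yield["founder_number"])  # yields kept


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        rows = [
            (fn, f"F{fn}_r{i}", None, 72, c, c, c, 1.0, False)
            for fn in (1, 3)
            for i, c in enumerate([5, 6, 7])
        ]
        res = compare_groups(AssayDataset(plates_frame(rows)), "dauer_yield")
        assert res.pairwise["p_adj"].item() == pytest.approx(1.0, abs=1e-9)

    def test_oneway_matches_sums_of_squares_oracle(self, small_dataset):
        res = compare_groups(small_dataset, "dauer_yield", "one-way")
        t = small_dataset.with_yields()
        groups = {fn: g["dauer_yield"].to_numpy() for fn, g in t.groupby("founder_number")}
        f_brute, mse, df = oneway_anova_brute(groups)
        f_model = res.anova.loc["C(founder_number)", "F"]
        assert f_model == pytest.approx(f_brute, rel=1e-8)
        expected = tukey_brute(groups, mse, df)
        for _, row in res.pairwise.iterrows():
            q, p = expected[(row["group1"], row["group2"])]
            assert row["q"] == pytest.approx(q, rel=1e-8)
            assert row["p_adj"] == pytest.approx(p, rel=1e-8)

    def test_twoway_matches_balanced_sums_of_squares(self, small_dataset):
        res = compare_groups(small_dataset, "dauer_yield", "two-way")
        t = small_dataset.with_yields()
        cells = {
            key: g["dauer_yield"].to_numpy()
            for key, g in t.groupby(["founder_number", "timepoint_hr"])
        }
        brute = twoway_anova_brute_balanced(cells)
        assert res.anova.loc["C(founder_number)", "sum_sq"] == pytest.approx(
            brute["ss_a"], rel=1e-8
        )
        assert res.anova.loc["C(timepoint_hr)", "sum_sq"] == pytest.approx(
            brute["ss_b"], rel=1e-8
        )
        assert res.anova.loc["C(founder_number):C(timepoint_hr)", "sum_sq"] == pytest.approx(
            brute["ss_int"], rel=1e-8
        )
        assert res.anova.loc["Residual", "sum_sq"] == pytest.approx(
            brute["ss_err"], rel=1e-8
        )
        # within-timepoint Tukey uses the pooled error term
        mse = brute["ss_err"] / brute["df_err"]
        tp72 = t[t["timepoint_hr"] == 72]
        groups = {fn: g["dauer_yield"].to_numpy() for fn, g in tp72.groupby("founder_number")}
        expected = tukey_brute(groups, mse, brute["df_err"])
        got = res.pairwise[res.pairwise["timepoint_hr"] == 72]
        for _, row in got.iterrows():
            q, p = expected[(row["group1"], row["group2"])]
            assert row["q"] == pytest.approx(q, rel=1e-8)
            assert row["p_adj"] == pytest.approx(p, rel=1e-8)

    def test_degenerate_group_named_in_error(self, small_dataset):
        # a founder group left with a single replicate colony cannot enter ANOVA
        plates = small_dataset.plates
        keep = plates[
            (plates["founder_number"] != 10) | (plates["replicate_id"] == "F10_R1")
        ]
        with pytest.raises(ValueError, match="10"):
            compare_groups(AssayDataset(keep.reset_index(drop=True)), "bust_hr")


class TestYieldTimecourse:
    def test_peak_at_maximal_mean(self, small_dataset):
        tc = yield_timecourse(small_dataset, 3)
        assert tc.peak_defined and tc.peak_hr == 144

    def test_peak_ties_break_earlier(self):
        rows = [
            (3, f"r{i}", 100.0, tp, 10, 10, 10, 1.0, False)
            for tp in (72, 96, 144)
            for i in range(2)
        ]
        tc = yield_timecourse(AssayDataset(plates_frame(rows)), 3)
        assert tc.peak_hr == 72

    def test_single_timepoint_flagged_undefined(self):
        rows = [(3, f"r{i}", 100.0, 72, 10, 10, 10, 1.0, False) for i in range(3)]
        tc = yield_timecourse(AssayDataset(plates_frame(rows)), 3)
        assert not tc.peak_defined and tc.peak_hr is None


class TestRecoveryCheck:
    @staticmethod
    def lengths_frame(groups):
        rows = [
            (tp, f"T{tp}_w{i}", v) for tp, vals in groups.items() for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows, columns=["timepoint_hr", "worm_id", "length_um"])

    def test_identical_lengths_no_flag(self):
        g = {72: [400.0] * 16, 144: [400.0] * 16}
        rep = recovery_check(self.lengths_frame(g))
        assert not rep.length_increase and rep.anova_p == 1.0

    def test_late_shift_raises_flag(self):
        rng = np.random.default_rng(0)
        g = {
            72: list(400 + rng.normal(0, 1, 20)),
            144: list(400.2 + rng.normal(0, 1, 20)),
        }
        assert recovery_check(self.lengths_frame(g)).length_increase

    def test_undersized_groups_warn_but_return(self):
        g = {72: [400.0] * 5, 144: [410.0] * 5}
        with pytest.warns(UserWarning, match="fewer than 15"):
            rep = recovery_check(self.lengths_frame(g))
        assert rep.undersized_groups == [72, 144]
        assert rep.length_increase


class TestLawnQC:
    @staticmethod
    def qc_frame(areas, ods):
        return pd.DataFrame(
            {
                "plate_id": [f"p{i}" for i in range(len(areas))],
                "area_cm2": areas,
                "od600": ods,
            }
        )

    def test_summary_statistics(self):
        rep = lawn_qc(self.qc_frame([9.0, 10.0, 11.0], [0.3, 0.35, 0.4]))
        area = rep.stats.set_index("variable").loc["area_cm2"]
        assert area["mean"] == 10.0 and area["min"] == 9.0 and area["max"] == 11.0

    def test_constant_column_zero_sd(self):
        rep = lawn_qc(self.qc_frame([10.0, 10.0], [0.3, 0.3]))
        assert (rep.stats["sd"] == 0.0).all()

    def test_tolerance_band_failures_named(self):
        rep = lawn_qc(
            self.qc_frame([9.0, 14.0], [0.3, 0.3]), area_band=(8.0, 12.0)
        )
        assert not rep.passed and "p1" in rep.failures[0]


class TestTradeoff:
    @staticmethod
    def dataset_from_means(bust_means, yield_means, timepoint=72):
        rows = []
        for fn in bust_means:
            for i in range(2):
                rows.append(
                    (fn, f"F{fn}_r{i}", bust_means[fn], timepoint,
                     yield_means[fn], yield_means[fn], yield_means[fn], 1.0, False)
                )
        return AssayDataset(plates_frame(rows))

    def test_published_group_means_pattern(self):
        # speed rank reverses founder order; yield rank 1 sits at 3 founders
        bust = {1: 159.0, 3: 125.0, 10: 97.0, 50: 69.0, 200: 51.0}
        yld = {1: 1540, 3: 2837, 10: 310, 50: 232, 200: 1050}
        ds = self.dataset_from_means(bust, yld)
        table = tradeoff_table(summarize(ds), 72)
        t = table.table.set_index("founder_number")
        assert list(t["speed_rank"]) == [5, 4, 3, 2, 1]
        assert t.loc[3, "yield_rank"] == 1
        assert table.tradeoff_detected

    def test_monotone_yields_no_tradeoff_flag(self):
        bust = {1: 159.0, 3: 125.0, 10: 97.0}
        yld = {1: 100, 3: 200, 10: 300}
        table = tradeoff_table(summarize(self.dataset_from_means(bust, yld)), 72)
        assert not table.tradeoff_detected

    def test_row_order_invariance(self):
        bust = {1: 159.0, 3: 125.0, 10: 97.0}
        yld = {1: 300, 3: 500, 10: 100}
        ds = self.dataset_from_means(bust, yld)
        shuffled = AssayDataset(
            ds.plates.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        a = tradeoff_table(summarize(ds), 72).table
        b = tradeoff_table(summarize(shuffled), 72).table
        pd.testing.assert_frame_equal(a, b)
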