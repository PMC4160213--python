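"""Boxplot statistics, the notch rule, and threshold sensitivity."""

import numpy as np
import pytest

from wallfibril3d.stats import (boxplot_stats, notch_overlap_test, summarize)


def brute_force_box(values):
    """Order-statistics oracle for the boxplot summary."""
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def quantile(p):  # linear interpolation at position 1 + (n-1)p
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    half = 1.57 * iqr / np.sqrt(n)
    return dict(q1=q1, med=med, q3=q3, wlo=inside.min(), whi=inside.max(),
                nlo=med - half, nhi=med + half,
                out=np.sort(v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]))


class TestBoxplotStats:
    def test_hand_example_notch(self):
        s = boxplot_stats([1, 2, 3, 4, 5])
        assert s.median == 3 and s.q1 == 2 and s.q3 == 4 and s.iqr == 2
        assert s.notch_low == pytest.approx(3 - 1.57 * 2 / np.sqrt(5), abs=1e-9)
        assert s.notch_high == pytest.approx(3 + 1.57 * 2 / np.sqrt(5), abs=1e-9)
        assert s.notch_low == pytest.approx(1.596, abs=5e-4)
        assert s.notch_high == pytest.approx(4.404, abs=5e-4)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 21)
            v = rng.normal(0, rng.uniform(0.5, 3), n)
            s = boxplot_stats(v)
            o = brute_force_box(v)
            assert s.q1 == pytest.approx(o["q1"], abs=1e-12)
            assert s.median == pytest.approx(o["med"], abs=1e-12)
            assert s.q3 == pytest.approx(o["q3"], abs=1e-12)
            assert s.whisker_low == pytest.approx(o["wlo"], abs=1e-12)
            assert s.whisker_high == pytest.approx(o["whi"], abs=1e-12)
            assert s.notch_low == pytest.approx(o["nlo"], abs=1e-12)
            assert s.notch_high == pytest.approx(o["nhi"], abs=1e-12)
            assert np.allclose(s.outliers, o["out"])

    def test_single_value_degenerate(self):
        s = boxplot_stats([7.5])
        assert s.median == s.q1 == s.q3 == 7.5
        assert s.iqr == 0
        assert s.notch_low == s.notch_high == 7.5
        assert s.outliers.size == 0

    def test_constant_list(self):
        s = boxplot_stats([2.0] * 9)
        assert s.outliers.size == 0
        assert s.whisker_low == s.whisker_high == 2.0

    def test_whiskers_are_data_values(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=50)
        s = boxplot_stats(v)
        assert s.whisker_low in v and s.whisker_high in v

    def test_notch_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=40)
        s1 = boxplot_stats(v)
        s2 = boxplot_stats(np.concatenate([v, v]))
        assert s2.median == pytest.approx(s1.median)
        assert s2.iqr == pytest.approx(s1.iqr)
        half1 = (s1.notch_high - s1.notch_low) / 2
        half2 = (s2.notch_high - s2.notch_low) / 2
        assert half2 == pytest.approx(half1 / np.sqrt(2), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats([])


class TestSummarize:
    def test_closed_form(self):
        s = summarize([2, 4])
        assert s["mean"] == 3 and s["sd"] == pytest.approx(np.sqrt(2))
        assert s["min"] == 2 and s["max"] == 4 and s["n"] == 2

    def test_constant_sd_zero(self):
        assert summarize([5, 5, 5])["sd"] == 0

    def test_report_format(self):
        s = summarize([4.0, 5.0, 6.0])
        assert s["report"] == "5.0±1.0 nm (range 4.0–6.0 nm, n = 3)"


class TestNotchOverlap:
    def test_identical_groups_not_significant(self):
        v = [1, 2, 3, 4, 5, 6]
        cmp = notch_overlap_test(v, v)
        assert cmp.verdict == "not_significant"
        assert cmp.notch_overlap

    def test_clearly_separated_groups(self):
        a = np.arange(60) * 0.01 + 5.0
        b = np.arange(60) * 0.01 + 9.0
        cmp = notch_overlap_test(a, b)
        assert cmp.verdict == "significant"

    def test_study_population_discrimination(self):
        # wild-type vs mutant gap populations (printed moments), n = 60:
        # significant in nearly all draws
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(5.2, 2.0, 60)
            b = rng.normal(8.9, 3.8, 60)
            if notch_overlap_test(a, b).verdict == "significant":
                sig += 1
        assert sig >= 18

    def test_study_population_equivalence(self):
        # the diameter populations barely differ: notches overlap
        not_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(4.5, 0.9, 60)
            b = rng.normal(4.6, 0.8, 60)
            if notch_overlap_test(a, b).verdict == "not_significant":
                not_sig += 1
        assert not_sig >= 18


class TestThresholdSensitivity:
    @pytest.fixture(scope="class")
    def sweep_table(self):
        from wallfibril3d.experiments import threshold_robustness

        return threshold_robustness(seed=3, shape=(128, 128, 44))

    def test_zero_delta_shift_is_zero(self, sweep_table):
        row = sweep_table[sweep_table["delta"] == 0.0].iloc[0]
        assert row["shift_diameter"] == 0.0

    def test_small_delta_small_shift(self, sweep_table):
        for d in (-0.05, 0.05):
            row = sweep_table[sweep_table["delta"] == d].iloc[0]
            assert abs(row["shift_diameter"]) < 0.5 * 0.87

    def test_diameter_monotone_non_increasing(self, sweep_table):
        t = sweep_table.sort_values("delta")
        vals = t["mean_diameter"].to_numpy(float)
        assert np.all(np.diff(vals) <= 1e-9)

    def test_deltas_must_include_zero(self):
        from wallfibril3d.metrology import AnalysisConfig, AnalysisROI
        from wallfibril3d.stats import threshold_sensitivity
        from wallfibril3d.volume import DensityVolume

        vol = DensityVolume(np.zeros((16, 16, 16), np.float32), 0.87)
        with pytest.raises(ValueError):
            threshold_sensitivity(vol, AnalysisROI(), AnalysisConfig(),
                                  deltas=(0.1, 0.2))
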