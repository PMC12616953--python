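"""Signal / Noise / SNR metrics, replicate aggregation, group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fretquant.characterize import (
    CharacterizationConfig,
    aggregate_replicates,
    characterize_cells,
    compare_groups,
    dynamic_range,
    noise_variance,
    snr,
)


class TestDynamicRange:
    def test_constant_trace_is_zero(self):
        assert dynamic_range(np.full(10, 0.3)) == 0.0

    def test_simple_arithmetic(self):
        assert dynamic_range(np.array([0.20, 0.35, 0.25])) == pytest.approx(0.15)

    def test_fewer_than_two_frames_is_missing(self):
        assert np.isnan(dynamic_range(np.array([0.3])))
        assert np.isnan(dynamic_range(np.array([0.3, np.nan])))

    def test_zero_noise_cell_recovers_generating_amplitude_exactly(self, ref_ratios):
        from fretquant.simulate import (
            ActivityProfileParams,
            SensorResponseParams,
            activity_to_efa,
            simulate_activity,
        )

        p = ActivityProfileParams()
        _, act = simulate_activity(p, 540.0)
        efa = activity_to_efa(act, SensorResponseParams(efa_min=0.15, efa_max=0.40))
        expected = (act.max() - act.min()) * 0.25
        assert dynamic_range(efa) == pytest.approx(expected, abs=1e-12)


class TestNoiseVariance:
    TIMES = np.arange(0.0, 600.0, 6.0)

    def test_constant_window_is_zero(self):
        est = noise_variance(np.full(self.TIMES.size, 0.2), self.TIMES, 100.0)
        assert est == pytest.approx(0.0, abs=1e-30)

    def test_gaussian_window_estimate_within_three_standard_errors(self):
        # 31 frames in the closed 2-5 h window at 6-min sampling
        rng = np.random.default_rng(8)
        sigma2 = 1e-4
        estimates = []
        for _ in range(200):
            v = rng.normal(0.2, np.sqrt(sigma2), self.TIMES.size)
            estimates.append(noise_variance(v, self.TIMES, 120.0))
        n_frames = 31
        se = sigma2 * np.sqrt(2.0 / (n_frames - 1)) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - sigma2) < 3 * se

    def test_window_tracks_inhibitor_time_one_for_one(self):
        v = self.TIMES.astype(float)  # value == time, so selection is visible
        cfg = CharacterizationConfig()
        a = noise_variance(v, self.TIMES, 60.0, cfg)
        b = noise_variance(v, self.TIMES, 66.0, cfg)
        assert a == b  # same number of frames, shifted values, equal variance of a ramp

        sel_a = self.TIMES[(self.TIMES >= 180.0) & (self.TIMES <= 360.0)]
        sel_b = self.TIMES[(self.TIMES >= 186.0) & (self.TIMES <= 366.0)]
        assert sel_a.size == sel_b.size == 31
        assert sel_b[0] - sel_a[0] == 6.0

    def test_window_boundaries_are_closed(self):
        cfg = CharacterizationConfig(min_frames_in_window=2)
        t = np.array([120.0, 300.0])  # exactly +2 h and +5 h
        assert not np.isnan(noise_variance(np.array([0.1, 0.2]), t, 0.0, cfg))

    def test_too_few_frames_is_missing(self):
        t = np.array([120.0, 126.0])
        assert np.isnan(noise_variance(np.array([0.1, 0.2]), t, 0.0))

    def test_first_difference_mode_agrees_for_iid_noise(self):
        rng = np.random.default_rng(11)
        v = rng.normal(0.0, 0.1, self.TIMES.size)
        a = noise_variance(v, self.TIMES, 60.0, CharacterizationConfig())
        b = noise_variance(
            v, self.TIMES, 60.0, CharacterizationConfig(noise_mode="first_difference")
        )
        assert b == pytest.approx(a, rel=0.6)  # same order; insensitive to drift


class TestSnr:
    def test_published_style_ratio(self):
        assert snr(0.13, 0.009) == pytest.approx(14.44, abs=0.01)

    def test_zero_signal_gives_zero(self):
        assert snr(0.0, 0.01) == 0.0

    def test_doubling_noise_halves_snr(self):
        assert snr(0.2, 0.02) == pytest.approx(snr(0.2, 0.01) / 2)

    def test_zero_noise_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert np.isnan(snr(0.1, 0.0))

    def test_offset_invariance_of_all_metrics(self):
        t = np.arange(0.0, 600.0, 6.0)
        rng = np.random.default_rng(2)
        v = rng.normal(0.3, 0.05, t.size)
        s0, n0 = dynamic_range(v), noise_variance(v, t, 60.0)
        s1, n1 = dynamic_range(v + 0.4), noise_variance(v + 0.4, t, 60.0)
        assert s1 == pytest.approx(s0, abs=1e-12)
        assert n1 == pytest.approx(n0, rel=1e-9)
        assert snr(s1, n1) == pytest.approx(snr(s0, n0), rel=1e-9)


def per_cell_frame(values_by_rep):
    rows = []
    for (exp, tech), values in values_by_rep.items():
        for i, v in enumerate(values):
            rows.append(
                dict(
                    cell_id=f"e{exp}t{tech}c{i}",
                    sensor="S",
                    signal=v,
                    noise=1.0,
                    snr=v,
                    technical_replicate=tech,
                    experimental_replicate=exp,
                )
            )
    return pd.DataFrame(rows)


class TestAggregateReplicates:
    def test_identical_cells_give_their_common_value(self):
        df = per_cell_frame({(1, 1): [0.4, 0.4, 0.4]})
        agg = aggregate_replicates(df)
        assert agg["signal"].tolist() == pytest.approx([0.4])

    def test_pooled_sample_is_replicate_means(self):
        df = per_cell_frame({(1, 1): [1.0, 3.0], (1, 2): [5.0]})
        agg = aggregate_replicates(df)
        assert sorted(agg["signal"]) == [2.0, 5.0]

    def test_pooled_size_equals_nonempty_replicate_pairs(self):
        df = per_cell_frame({(1, 1): [1.0], (1, 2): [2.0], (2, 1): [3.0]})
        assert len(aggregate_replicates(df)) == 3

    def test_grand_mean_equals_cell_weighted_mean(self):
        df = per_cell_frame({(1, 1): [1.0, 3.0], (1, 2): [5.0, 7.0, 9.0]})
        agg = aggregate_replicates(df)
        expected = np.mean([np.mean([1, 3]), np.mean([5, 7, 9])])
        assert agg["signal"].mean() == pytest.approx(expected)


class TestCompareGroups:
    @staticmethod
    def reps(**groups):
        rows = []
        for name, values in groups.items():
            for v in values:
                rows.append({"sensor": name, "signal": v})
        return pd.DataFrame(rows)

    def test_extreme_separation_is_overwhelmingly_significant(self):
        rng = np.random.default_rng(0)
        df = self.reps(a=0.0 + 1e-6 * rng.normal(size=3), b=10.0 + 1e-6 * rng.normal(size=3))
        res = compare_groups(df, "signal")
        assert res["tukey"]["p_adj"].iloc[0] < 1e-6

    def test_type_one_error_rate_calibrated(self):
        rng = np.random.default_rng(202)
        false_pos = 0
        n_sim = 100
        for _ in range(n_sim):
            df = self.reps(a=rng.normal(0, 1, 8), b=rng.normal(0, 1, 8))
            res = compare_groups(df, "signal")
            false_pos += int(res["tukey"]["p_adj"].iloc[0] < 0.05)
        assert n_sim - false_pos >= 94

    def test_adjusted_p_matches_independent_studentized_range_oracle(self):
        rng = np.random.default_rng(7)
        groups = {
            "a": rng.normal(0.0, 1.0, 6),
            "b": rng.normal(0.5, 1.0, 8),
            "c": rng.normal(1.0, 1.0, 7),
        }
        res = compare_groups(self.reps(**groups), "signal")
        oracle = sps.tukey_hsd(groups["a"], groups["b"], groups["c"])
        # map statsmodels pair order (sorted labels) onto scipy indices
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for _, row in res["tukey"].iterrows():
            i, j = pairs[(row["group1"], row["group2"])]
            assert row["p_adj"] == pytest.approx(oracle.pvalue[i, j], abs=1e-6)

    def test_tiny_group_excluded_with_warning(self):
        df = self.reps(a=[1.0, 2.0, 1.5], b=[1.2, 1.8, 2.1], c=[5.0])
        with pytest.warns(UserWarning, match="c"):
            res = compare_groups(df, "signal")
        assert set(res["tukey"]["group1"]) | set(res["tukey"]["group2"]) == {"a", "b"}

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups(self.reps(a=[1.0, 2.0]), "signal")


class TestCharacterizeCells:
    def test_noise_display_scale_enters_squared(self):
        t = np.arange(0.0, 600.0, 6.0)
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            dict(
                cell_id="c1",
                sensor="REKAR67",
                frame=np.arange(t.size),
                time_min=t,
                efa=rng.normal(0.2, 0.01, t.size),
                inhibitor_time_min=60.0,
            )
        )
        plain = characterize_cells(df)
        scaled = characterize_cells(df, noise_display_scale={"REKAR67": 3.0})
        assert scaled["noise"].iloc[0] == pytest.approx(9.0 * plain["noise"].iloc[0])
        assert scaled["signal"].iloc[0] == plain["signal"].iloc[0]  # signal stays raw
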