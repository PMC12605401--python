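import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethoscore import (
    block_average_di,
    cumulative_di,
    di_record,
    discrimination_index,
    early_window_di,
    interaction_times,
    running_di_per_minute,
    score_exploration_table,
)

from helpers import prefix_mean_oracle
from test_behavior_classifier import series_of


def minutes_series(per_minute_specs, fps=25.0):
    """Build a label series from [(cage, label, seconds), ...] per minute.

    Each minute is padded with 'none' frames to exactly 60 s.
    """
    labels, cages = [], []
    for specs in per_minute_specs:
        used = 0
        for cage, label, seconds in specs:
            n = int(round(seconds * fps))
            labels += [label] * n
            cages += [cage] * n
            used += n
        pad = int(round(60 * fps)) - used
        assert pad >= 0
        labels += ["none"] * pad
        cages += ["none"] * pad
    return pd.DataFrame({
        "frame": np.arange(len(labels)),
        "cage_context": cages,
        "label": labels,
        "source_landmark": "snout",
        "tie_flag": False,
    })


class TestInteractionTimes:
    def test_250_sniff_frames_is_10_seconds(self):
        s = series_of(["sniff"] * 250)
        summary = interaction_times(s, 25.0)
        assert summary.seconds("A", "sniff") == pytest.approx(10.0)

    def test_empty_series_all_zero(self):
        s = series_of([])
        summary = interaction_times(s, 25.0)
        assert summary.totals.to_numpy().sum() == 0.0

    def test_total_is_class_sum(self):
        s = series_of(["sniff"] * 250 + ["rear"] * 125 + ["other"] * 50)
        summary = interaction_times(s, 25.0)
        assert summary.seconds("A", "total") == pytest.approx(17.0)
        assert summary.seconds("A", "total") == pytest.approx(
            sum(summary.seconds("A", m) for m in ("sniff", "rear", "other")))

    def test_per_minute_binning(self):
        s = minutes_series([
            [("A", "sniff", 4.0), ("B", "sniff", 1.0)],
            [("A", "sniff", 2.0), ("B", "sniff", 3.0)],
        ])
        summary = interaction_times(s, 25.0)
        assert summary.per_minute.loc[(1, "A"), "sniff"] == pytest.approx(4.0)
        assert summary.per_minute.loc[(2, "B"), "sniff"] == pytest.approx(3.0)
        assert summary.cumulative_seconds("A", 2) == pytest.approx(6.0)
        assert summary.cumulative_seconds("B", 2) == pytest.approx(4.0)


class TestDiscriminationIndex:
    def test_formula(self):
        assert discrimination_index(30.0, 10.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("t", [0.5, 3.0, 120.0])
    def test_symmetry_equal_times_zero(self, t):
        assert discrimination_index(t, t) == 0.0

    def test_one_sided_exploration_saturates(self):
        rec = di_record("m1", "trial_1", "total", 12.0, 0.0)
        assert rec.di == 1.0
        assert rec.excluded
        assert rec.exclusion_reason == "saturated_plus1"

    def test_other_side_saturates_minus(self):
        rec = di_record("m1", "trial_1", "total", 0.0, 7.5)
        assert rec.di == -1.0
        assert rec.exclusion_reason == "saturated_minus1"

    def test_zero_total_flagged_not_imputed(self):
        rec = di_record("m1", "trial_1", "total", 0.0, 0.0)
        assert np.isnan(rec.di)
        assert rec.exclusion_reason == "zero_total"

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            discrimination_index(-1.0, 5.0)

    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_bounds(self, a, b):
        d1 = discrimination_index(a, b)
        d2 = discrimination_index(b, a)
        if a + b == 0:
            assert np.isnan(d1) and np.isnan(d2)
        else:
            assert d1 == pytest.approx(-d2)
            assert -1.0 <= d1 <= 1.0


class TestCumulativeDI:
    def test_running_mean(self):
        np.testing.assert_allclose(cumulative_di([0.2, 0.4]), [0.2, 0.3])

    def test_constant_is_identity(self):
        np.testing.assert_allclose(cumulative_di([0.3] * 6), [0.3] * 6)

    def test_saturated_sequence(self):
        np.testing.assert_allclose(cumulative_di([1.0, -1.0, 0.0]),
                                   [1.0, 0.0, 0.0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cumulative_di([])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            cumulative_di([0.2, 1.5])

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_prefix_mean_oracle(self, dis):
        np.testing.assert_allclose(cumulative_di(dis),
                                   prefix_mean_oracle(dis), atol=1e-12)


class TestRunningDIPerMinute:
    def test_two_minute_example(self):
        # cumulative novel/familiar: minute 1 (4, 1), minute 2 (6, 4)
        s = minutes_series([
            [("A", "sniff", 4.0), ("B", "sniff", 1.0)],
            [("A", "sniff", 2.0), ("B", "sniff", 3.0)],
        ])
        summary = interaction_times(s, 25.0)
        out = running_di_per_minute(summary, "total")
        np.testing.assert_allclose(out["di"], [0.6, 0.2])
        assert not out["undefined"].any()

    def test_all_novel_saturates(self):
        s = minutes_series([[("A", "sniff", 5.0)], [("A", "rear", 3.0)]])
        summary = interaction_times(s, 25.0)
        out = running_di_per_minute(summary, "total")
        np.testing.assert_allclose(out["di"], [1.0, 1.0])

    def test_zero_minute_flagged_undefined(self):
        s = minutes_series([[], [("A", "sniff", 5.0)]])
        summary = interaction_times(s, 25.0)
        out = running_di_per_minute(summary, "total")
        assert out["undefined"].iloc[0]
        assert np.isnan(out["di"].iloc[0])
        assert out["di"].iloc[1] == pytest.approx(1.0)


class TestBlockAverageDI:
    def test_linear_dis(self):
        dis = {k: k / 20 for k in range(1, 12)}
        early, late = block_average_di(dis)
        assert early == pytest.approx(0.125)
        assert late == pytest.approx(0.475)

    def test_constant(self):
        early, late = block_average_di([0.3] * 11)
        assert (early, late) == (pytest.approx(0.3), pytest.approx(0.3))

    def test_missing_trial_in_block_errors(self):
        dis = {k: 0.1 for k in range(1, 12)}
        del dis[2]
        with pytest.raises(ValueError, match="missing trial"):
            block_average_di(dis)

    def test_fewer_than_11_trials_errors(self):
        with pytest.raises(ValueError, match="at least 11"):
            block_average_di([0.1] * 7)

    def test_blocks_can_be_overridden(self):
        early, late = block_average_di([0.1, 0.2, 0.3, 0.4],
                                       early=(1, 2), late=(3, 4))
        assert early == pytest.approx(0.15)
        assert late == pytest.approx(0.35)


class TestEarlyWindowDI:
    def test_formula(self):
        s = minutes_series([[("A", "sniff", 20.0), ("B", "sniff", 10.0)], []])
        rec = early_window_di(interaction_times(s, 25.0), "total",
                              subject_id="m1")
        assert rec.di == pytest.approx(1 / 3)
        assert not rec.excluded

    def test_saturation_excluded(self):
        s = minutes_series([[("A", "sniff", 8.0)], []])
        rec = early_window_di(interaction_times(s, 25.0), "total")
        assert rec.di == 1.0
        assert rec.excluded
        assert rec.exclusion_reason == "saturated_plus1"

    def test_zero_total_flagged(self):
        s = minutes_series([[], []])
        rec = early_window_di(interaction_times(s, 25.0), "total")
        assert rec.exclusion_reason == "zero_total"

    def test_requires_two_minutes(self):
        s = minutes_series([[("A", "sniff", 5.0)]])
        with pytest.raises(ValueError):
            early_window_di(interaction_times(s, 25.0), "total")


class TestScoreExplorationTable:
    def test_di_and_cdi_per_trial(self):
        table = pd.DataFrame({
            "subject_id": ["m1"] * 2,
            "group": ["control"] * 2,
            "trial": [1, 2],
            "time_novel_s": [30.0, 14.0],
            "time_familiar_s": [10.0, 6.0],
        })
        out = score_exploration_table(table)
        np.testing.assert_allclose(out["di"], [0.5, 0.4])
        np.testing.assert_allclose(out["cdi"], [0.5, 0.45])
        assert not out["excluded"].any()
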