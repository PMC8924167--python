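"""Trait derivation: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import series_from_values
from lobsterresp.metabolic_metrics import (
    MetricError,
    compute_epoc,
    compute_mmr,
    compute_recovery_rate,
    compute_recovery_time,
    compute_rmr,
    compute_smr,
    summarize_metabolism,
)


def brute_force_recovery_time(times, values, threshold, rule="cumulative"):
    """Independent scan: time of the third sub-threshold cycle."""
    count = 0
    run = 0
    for t, v in zip(times, values):
        hit = v < threshold
        count += hit
        run = run + 1 if hit else 0
        if (rule == "cumulative" and count == 3) or (
            rule == "consecutive" and run == 3
        ):
            return t
    return None


def sorted_decile_mean(values, q=0.10):
    """Sort-based SMR oracle."""
    vals = sorted(values)
    k = int(np.ceil(q * len(vals)))
    return float(np.mean(vals[:k]))


class TestSmr:
    def test_mean_of_lowest_decile(self):
        vals = [30.0, 32.0] + [50.0] * 18
        series = series_from_values(np.arange(20.0), vals)
        assert compute_smr(series) == pytest.approx(31.0)

    def test_constant_series_returns_the_constant(self):
        series = series_from_values(np.arange(12.0), [47.0] * 12)
        assert compute_smr(series) == pytest.approx(47.0)

    def test_too_few_cycles_rejected(self):
        series = series_from_values(np.arange(9.0), np.arange(9.0) + 40.0)
        with pytest.raises(MetricError, match="10"):
            compute_smr(series)


class TestMmrRmr:
    def test_mmr_is_single_highest(self):
        series = series_from_values([0.0, 1.0, 2.0], [45.0, 110.0, 80.0])
        assert compute_mmr(series) == 110.0

    def test_single_cycle_mmr(self):
        series = series_from_values([0.5], [66.0])
        assert compute_mmr(series) == 66.0

    def test_rmr_window_mean_and_sd(self):
        times = [1.0, 2.0, 17.0, 20.0, 30.0]
        vals = [110.0, 90.0, 50.0, 52.0, 48.0]
        rmr, sd = compute_rmr(series_from_values(times, vals))
        assert rmr == pytest.approx(50.0)
        assert sd == pytest.approx(2.0)

    def test_rmr_without_post_window_cycles_rejected(self):
        series = series_from_values([1.0, 2.0], [100.0, 90.0])
        with pytest.raises(MetricError, match="16"):
            compute_rmr(series)


class TestRecoveryTime:
    def test_third_subthreshold_cycle_example(self):
        series = series_from_values(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [100.0, 90.0, 60.0, 55.0, 58.0, 52.0],
        )
        # threshold 59: below at t=4,5,6 -> third at 6 h
        assert compute_recovery_time(series, rmr=58.0, rmr_sd=1.0) == 6.0

    def test_threshold_above_everything_recovers_at_third_cycle(self):
        series = series_from_values(np.arange(1.0, 7.0), [100.0] * 6)
        assert compute_recovery_time(series, rmr=1000.0, rmr_sd=0.0) == 3.0

    def test_monotone_series_makes_rules_agree(self):
        times = np.arange(1.0, 11.0)
        vals = np.linspace(110.0, 40.0, 10)
        series = series_from_values(times, vals)
        cum = compute_recovery_time(series, 50.0, 5.0, rule="cumulative")
        con = compute_recovery_time(series, 50.0, 5.0, rule="consecutive")
        assert cum == con

    def test_not_recovered_returns_none(self):
        series = series_from_values(np.arange(1.0, 7.0), [100.0] * 6)
        assert compute_recovery_time(series, rmr=10.0, rmr_sd=0.0) is None

    @given(
        values=st.lists(st.floats(20.0, 120.0), min_size=3, max_size=40),
        rmr=st.floats(30.0, 80.0),
        sd=st.floats(0.0, 10.0),
        rule=st.sampled_from(["cumulative", "consecutive"]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_scan(self, values, rmr, sd, rule):
        times = np.arange(1.0, len(values) + 1.0)
        series = series_from_values(times, values)
        expected = brute_force_recovery_time(times, values, rmr + sd, rule)
        assert compute_recovery_time(series, rmr, sd, rule=rule) == expected


class TestEpoc:
    def test_null_excess_when_flat_at_rmr(self):
        series = series_from_values(np.arange(0.0, 6.0), [50.0] * 6)
        assert compute_epoc(series, 5.0, "rmr", rmr=50.0) == 0.0

    def test_triangle_area(self):
        series = series_from_values([0.0, 2.0], [110.0, 50.0])
        assert compute_epoc(series, 2.0, "rmr", rmr=50.0) == pytest.approx(60.0)

    def test_negative_excess_clipped_not_subtracted(self):
        series = series_from_values([0.0, 1.0, 2.0], [110.0, 30.0, 30.0])
        epoc = compute_epoc(series, 2.0, "rmr", rmr=50.0)
        # 0-1 h trapezoid of clipped excess (60 -> 0), nothing after
        assert epoc == pytest.approx(np.trapezoid([60.0, 0.0, 0.0], [0.0, 1.0, 2.0]))

    def test_baseline_modes_ordered(self):
        series = series_from_values(np.arange(0.0, 5.0), [110.0, 90.0, 70.0, 60.0, 55.0])
        e_rmr = compute_epoc(series, 4.0, "rmr", rmr=50.0)
        e_smr = compute_epoc(series, 4.0, "smr", smr=40.0)
        e_none = compute_epoc(series, 4.0, "none")
        assert e_rmr < e_smr < e_none

    def test_undefined_recovery_propagates(self):
        series = series_from_values(np.arange(0.0, 5.0), [100.0] * 5)
        with pytest.raises(MetricError, match="recovery"):
            compute_epoc(series, None, "rmr", rmr=50.0)

    @given(
        rec_a=st.floats(2.0, 10.0),
        extra=st.floats(0.0, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_recovery_time(self, rec_a, extra):
        times = np.arange(0.0, 25.0)
        rng = np.random.default_rng(0)
        vals = 50.0 + 60.0 * np.exp(-times / 3.0) + rng.normal(0, 1, times.size)
        series = series_from_values(times, vals)
        a = compute_epoc(series, rec_a, "rmr", rmr=50.0)
        b = compute_epoc(series, rec_a + extra, "rmr", rmr=50.0)
        assert b >= a - 1e-12


class TestRecoveryRateAndSummary:
    def test_rate_is_epoc_over_time(self):
        assert compute_recovery_rate(180.0, 6.0) == pytest.approx(30.0)
        assert compute_recovery_rate(0.0, 6.0) == 0.0
        with pytest.raises(MetricError):
            compute_recovery_rate(180.0, 0.0)

    def test_summary_identities_and_ordering(self, synthetic_series):
        truth, chamber, series = synthetic_series
        s = summarize_metabolism(series)
        assert s.aerobic_scope == pytest.approx(s.mmr - s.smr)
        assert s.factorial_scope == pytest.approx(s.mmr / s.smr)
        assert s.factorial_scope >= 1.0
        assert s.smr <= s.rmr <= s.mmr
        assert s.qc_violations == []
        assert s.recovered
        # recovery_rate * recovery_time == epoc exactly
        assert s.recovery_rate * s.recovery_time_h == pytest.approx(s.epoc)
        assert s.settings["baseline_mode"] == "rmr"

    def test_summary_parameter_recovery(self, synthetic_series):
        """Pipeline estimates land near the generator truth for one trial."""
        truth, chamber, series = synthetic_series
        s = summarize_metabolism(series)
        assert s.smr == pytest.approx(truth.smr_true, rel=0.05)
        assert s.mmr == pytest.approx(truth.mmr_true, rel=0.05)
        assert s.rmr == pytest.approx(truth.rmr_true, rel=0.05)
        assert s.epoc == pytest.approx(truth.epoc_true, rel=0.10)
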