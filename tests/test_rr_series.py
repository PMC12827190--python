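"""RR computation, outlier flagging, correction, tachogram resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mecg
from mecg.exceptions import (
    InsufficientBeatsError,
    InsufficientDataError,
    UnusableSeriesError,
)
from mecg.rpeak_detect import PeakSet
from mecg.rr_series import RRSeries, correct_rr, flag_rr_outliers


def series_from(rr, mask=None):
    rr = np.asarray(rr, float)
    mask = (np.zeros(rr.size, bool) if mask is None
            else np.asarray(mask, bool))
    return RRSeries(rr=rr, x=np.cumsum(rr), outlier_mask=mask)


class TestComputeRR:
    @pytest.mark.parametrize("times, rr, x", [
        ([0.5, 1.3, 2.1], [0.8, 0.8], [0.8, 1.6]),
        ([0.0, 1.0, 3.0], [1.0, 2.0], [1.0, 3.0]),
    ])
    def test_differences_and_cumulative(self, times, rr, x):
        out = mecg.compute_rr(PeakSet.from_times(times))
        np.testing.assert_allclose(out.rr, rr, atol=1e-9)
        np.testing.assert_allclose(out.x, x, atol=1e-9)
        assert not out.corrected and not out.outlier_mask.any()

    def test_two_peaks_insufficient(self):
        with pytest.raises(InsufficientBeatsError):
            mecg.compute_rr(PeakSet.from_times([0.0, 1.0]))

    def test_conservation_of_total_time(self):
        rng = np.random.default_rng(11)
        times = np.cumsum(rng.uniform(0.6, 1.0, size=50))
        peaks = PeakSet.from_times(times, rate=10_000.0)
        out = mecg.compute_rr(peaks)
        span = peaks.times[-1] - peaks.times[0]
        assert out.rr.sum() == pytest.approx(span, abs=1e-9)


class TestFlagOutliers:
    def test_doubled_interval_flagged(self):
        # mu=0.88, sigma=0.24 (population), band [0.52, 1.24] at n=1.5
        rr = [0.8] * 4 + [1.6] + [0.8] * 5
        out = flag_rr_outliers(series_from(rr), n=1.5)
        assert out.stats["mu_rr"] == pytest.approx(0.88)
        assert out.stats["sigma_rr"] == pytest.approx(0.24)
        expected = np.zeros(10, bool)
        expected[4] = True
        np.testing.assert_array_equal(out.outlier_mask, expected)

    def test_constant_series_unflagged(self):
        out = flag_rr_outliers(series_from([0.8] * 10))
        assert not out.outlier_mask.any()

    def test_huge_multiplier_unflagged(self):
        rng = np.random.default_rng(2)
        out = flag_rr_outliers(series_from(rng.uniform(0.5, 1.5, 30)), n=100)
        assert not out.outlier_mask.any()


class TestCorrect:
    def test_interpolates_between_equal_neighbors(self):
        rr = [0.8, 0.8, 1.6, 0.8, 0.8]
        mask = [False, False, True, False, False]
        out = correct_rr(series_from(rr, mask))
        assert out.rr[2] == pytest.approx(0.8)
        assert out.corrected
        np.testing.assert_array_equal(out.rr_original, rr)

    def test_boundary_flag_constant_extension(self):
        rr = [1.9, 0.8, 0.85, 0.8]
        mask = [True, False, False, False]
        out = correct_rr(series_from(rr, mask))
        assert out.rr[0] == pytest.approx(0.8)

    def test_flag_run_gets_one_linear_segment(self):
        rr = [0.8, 1.6, 1.6, 1.0]
        mask = [False, True, True, False]
        s = series_from(rr, mask)
        out = correct_rr(s)
        # linear in x between (x_0, 0.8) and (x_3, 1.0)
        expect = np.interp(s.x[1:3], [s.x[0], s.x[3]], [0.8, 1.0])
        np.testing.assert_allclose(out.rr[1:3], expect, atol=1e-12)

    def test_no_flags_identity(self):
        rr = [0.8, 0.9, 0.85]
        out = correct_rr(series_from(rr))
        np.testing.assert_array_equal(out.rr, rr)

    def test_x_not_recomputed_and_length_preserved(self):
        rr = [0.8, 0.8, 1.6, 0.8, 0.8]
        s = series_from(rr, [False, False, True, False, False])
        out = correct_rr(s)
        np.testing.assert_array_equal(out.x, s.x)
        assert len(out) == len(s)

    def test_all_flagged_unusable(self):
        with pytest.raises(UnusableSeriesError):
            correct_rr(series_from([1.0, 1.0], [True, True]))


class TestParameterRecovery:
    def test_missed_beats_corrected_recovers_statistics(self):
        """Deleting 5% of beats doubles intervals; flag+correct restores
        mean RR to ~truth and SDNN to within 10%, while the uncorrected
        series grossly inflates SDNN."""
        gt = mecg.simulate_rr(mecg.SyntheticSpec(duration_s=300, seed=9))
        damaged = gt.drop_peaks(0.05, seed=1)
        raw = mecg.compute_rr(PeakSet.from_times(damaged.peak_times_s,
                                                 rate=10_000.0))
        corrected = correct_rr(flag_rr_outliers(raw, n=1.5))
        true_mean = gt.rr_s.mean()
        true_sdnn = gt.rr_s.std()
        assert abs(corrected.rr.mean() - true_mean) / true_mean < 0.01
        assert abs(corrected.rr.std() - true_sdnn) / true_sdnn < 0.10
        assert abs(raw.rr.std() - true_sdnn) / true_sdnn > 0.50


class TestCorrectionProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.4, 2.0), min_size=3, max_size=60),
           st.floats(0.5, 3.0))
    def test_flag_and_correct_invariants(self, rr, n):
        """For any positive RR series and threshold: correction preserves
        the interval count and x, leaves unflagged values untouched, and
        produces only positive values (no zeros remain)."""
        s = flag_rr_outliers(series_from(rr), n=n)
        if s.outlier_mask.all():
            with pytest.raises(UnusableSeriesError):
                correct_rr(s)
            return
        out = correct_rr(s)
        assert len(out) == len(s)
        np.testing.assert_array_equal(out.x, s.x)
        keep = ~s.outlier_mask
        np.testing.assert_array_equal(out.rr[keep], s.rr[keep])
        assert np.all(out.rr > 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.4, 2.0), min_size=2, max_size=40))
    def test_corrected_values_within_valid_range(self, rr):
        """Interpolated replacements never leave the range spanned by the
        surviving (non-flagged) intervals."""
        s = flag_rr_outliers(series_from(rr), n=1.5)
        if s.outlier_mask.all() or len(s) < 2:
            return
        out = correct_rr(s)
        valid = s.rr[~s.outlier_mask]
        assert np.all(out.rr >= valid.min() - 1e-12)
        assert np.all(out.rr <= valid.max() + 1e-12)


class TestTachogram:
    def test_constant_series(self):
        s = series_from([0.8] * 10)
        s.corrected = True
        tach = mecg.resample_tachogram(s)
        assert tach.n_points == 850
        np.testing.assert_allclose(tach.values, 0.8, atol=1e-12)

    def test_linear_series_reproduced(self):
        # rr values linear in x: a natural cubic spline is exact
        x = np.cumsum(np.random.default_rng(1).uniform(0.6, 1.0, 20))
        rr = 0.6 + 0.01 * x
        s = mecg.RRSeries(rr=rr, x=x, outlier_mask=np.zeros(20, bool),
                          corrected=True)
        tach = mecg.resample_tachogram(s)
        expect = 0.6 + 0.01 * tach.times
        assert np.max(np.abs(tach.values - expect)) < 1e-9

    def test_sinusoidal_modulation_closed_form(self):
        # rr = 0.8 + 0.05 sin(2 pi 0.1 x) evaluated at self-consistent times
        gt = mecg.simulate_rr(mecg.SyntheticSpec(
            duration_s=300, lf_amp_s=0.05, hf_amp_s=0.0, jitter_sd_s=0.0))
        s = series_from(gt.rr_s)
        # each interval carries the modulation value at its *starting* beat
        s.x = gt.peak_times_s[:-1]
        s.corrected = True
        tach = mecg.resample_tachogram(s)
        closed = 0.8 + 0.05 * np.sin(2 * np.pi * 0.1 * tach.times
                                     + gt.lf_phase)
        assert np.max(np.abs(tach.values - closed)) < 0.005

    def test_rate_matches_span(self):
        s = series_from(np.random.default_rng(0).uniform(0.7, 0.9, 30))
        s.corrected = True
        tach = mecg.resample_tachogram(s, n_points=100)
        assert tach.rate == pytest.approx(99 / (s.x[-1] - s.x[0]))

    def test_too_short_for_spline(self):
        s = series_from([0.8, 0.8, 0.8])
        s.corrected = True
        with pytest.raises(InsufficientDataError):
            mecg.resample_tachogram(s)
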