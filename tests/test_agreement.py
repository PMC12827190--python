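"""Peak pairing, quality gate, detection benchmark, DTW, statistics."""

import numpy as np
import pytest

import mecg
from mecg.agreement import (
    benchmark_detection,
    comparison_stats,
    dtw_distance,
    lin_ccc,
    pair_peaks_sequential,
)
from mecg.exceptions import UndefinedStatisticError
from mecg.rpeak_detect import PeakSet
from mecg.rr_series import RRSeries

from oracles import exhaustive_dtw, naive_bland_altman, naive_mae, naive_rmse


def peaks(times):
    return PeakSet.from_times(times, rate=10_000.0)


def series(rr):
    rr = np.asarray(rr, float)
    return RRSeries(rr=rr, x=np.cumsum(rr),
                    outlier_mask=np.zeros(rr.size, bool), corrected=True)


class TestPairing:
    def test_offsets_and_misalignment(self):
        rep = pair_peaks_sequential(peaks([1.01, 2.00, 3.05]),
                                    peaks([1.0, 2.0, 3.0]))
        offsets = [p[2] for p in rep.pairs]
        np.testing.assert_allclose(offsets, [0.01, 0.0, 0.05], atol=1e-9)
        assert rep.n_misaligned == 1
        assert rep.pct_misaligned == pytest.approx(100 / 3)
        assert not rep.passes_gate

    def test_identical_sets_pass(self):
        t = np.arange(1, 100, 0.8)
        rep = pair_peaks_sequential(peaks(t), peaks(t))
        assert rep.n_misaligned == 0
        assert rep.beat_count_agreement == 100.0
        assert rep.passes_gate

    def test_98_percent_beat_agreement_is_pass_boundary(self):
        t = np.arange(100) * 0.8 + 1
        rep = pair_peaks_sequential(peaks(t[:98]), peaks(t))
        assert rep.beat_count_agreement == pytest.approx(98.0)
        assert rep.passes_gate  # "below 98%" fails; 98% exactly passes

    def test_each_reference_peak_used_once(self):
        rep = pair_peaks_sequential(peaks([1.0, 1.01, 3.0]),
                                    peaks([1.0, 2.0, 3.0]))
        used = [p[1] for p in rep.pairs]
        assert len(used) == len(set(used))


class TestGateBoundaries:
    def build(self, n_pairs, n_bad, m_extra=0):
        """n_pairs beats, n_bad of them offset by 0.03 s (> 0.02 s)."""
        t = 1 + np.arange(n_pairs) * 0.8
        m = t.copy()
        m[:n_bad] += 0.03
        return peaks(np.sort(m)[: n_pairs - m_extra]), peaks(t)

    def test_exactly_3_percent_misaligned_fails(self):
        m, i = self.build(1000, 30)
        rep = pair_peaks_sequential(m, i)
        assert rep.pct_misaligned == pytest.approx(3.0)
        assert not rep.passes_gate

    def test_just_under_3_percent_passes(self):
        m, i = self.build(1000, 29)
        rep = pair_peaks_sequential(m, i)
        assert rep.pct_misaligned == pytest.approx(2.9)
        assert rep.passes_gate

    def test_belief_count_979_of_1000_fails(self):
        t = 1 + np.arange(1000) * 0.8
        rep = pair_peaks_sequential(peaks(t[:979]), peaks(t))
        assert rep.beat_count_agreement == pytest.approx(97.9)
        assert not rep.passes_gate

    def test_gate_monotone_in_misalignment(self):
        # adding one more misaligned pair can never turn fail into pass
        for bad in range(28, 35):
            m, i = self.build(1000, bad)
            rep = pair_peaks_sequential(m, i)
            if not rep.passes_gate:
                m2, i2 = self.build(1000, bad + 1)
                assert not pair_peaks_sequential(m2, i2).passes_gate


class TestBenchmark:
    def test_worked_example(self):
        rep = benchmark_detection(peaks([1.0, 2.0, 3.0, 4.2]),
                                  peaks([1.0, 2.0, 3.0, 4.0]))
        assert (rep.tp, rep.fp, rep.fn) == (3, 1, 1)
        assert rep.sensitivity == rep.ppv == rep.f1 == pytest.approx(0.75)

    def test_identical_sets_perfect(self):
        t = np.arange(1, 50, 0.8)
        rep = benchmark_detection(peaks(t), peaks(t))
        assert rep.sensitivity == rep.ppv == rep.f1 == 1.0

    def test_disjoint_sets_zero(self):
        rep = benchmark_detection(peaks([1.0, 2.0]), peaks([1.5, 2.5]))
        assert rep.tp == 0 and rep.f1 == 0.0

    def test_tolerance_window_edges(self):
        assert benchmark_detection(peaks([1.049]), peaks([1.0])).tp == 1
        assert benchmark_detection(peaks([1.051]), peaks([1.0])).tp == 0


class TestDtw:
    def test_identical_series_zero(self):
        s = series([0.8, 0.9, 0.7, 0.85])
        assert dtw_distance(s, s) == 0.0

    def test_warping_absorbs_length_difference(self):
        assert dtw_distance(series([0.8, 0.8]),
                            series([0.8, 0.8, 0.8])) == 0.0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.5, 1.2, size=int(rng.integers(2, 9)))
        b = rng.uniform(0.5, 1.2, size=int(rng.integers(2, 9)))
        got = dtw_distance(series(a), series(b))
        assert got == pytest.approx(exhaustive_dtw(list(a), list(b)),
                                    rel=1e-12)

    def test_nonnegative_and_symmetric(self, rng):
        a = series(rng.uniform(0.5, 1.2, 20))
        b = series(rng.uniform(0.5, 1.2, 25))
        d1, d2 = dtw_distance(a, b), dtw_distance(b, a)
        assert d1 >= 0 and d1 == pytest.approx(d2, rel=1e-12)


class TestComparisonStats:
    def test_identity_comparison(self, rng):
        rr = rng.uniform(0.7, 0.9, size=90)
        st = comparison_stats(series(rr), series(rr))
        assert st.spearman_rho == pytest.approx(1.0)
        assert st.rmse == 0.0 and st.mae == 0.0
        ba = st.bland_altman
        assert (ba["mean_diff_s"], ba["loa_upper_s"], ba["loa_lower_s"]) \
            == (0.0, 0.0, 0.0)
        assert st.ccc_mean_rr == pytest.approx(1.0)
        assert st.ccc_rmssd == pytest.approx(1.0)
        assert st.dtw_distance == 0.0

    def test_mwu_on_identical_triplets(self):
        st = comparison_stats(series([1.0, 2.0, 3.0]),
                              series([1.0, 2.0, 3.0]))
        assert st.mwu_rr["statistic"] == pytest.approx(4.5)
        assert st.mwu_rr["p"] == pytest.approx(1.0)

    def test_constant_shift_bland_altman(self, rng):
        rr = rng.uniform(0.7, 0.9, size=50)
        st = comparison_stats(series(rr), series(rr + 0.01))
        assert st.bland_altman["mean_diff_s"] == pytest.approx(-0.01)
        assert st.bland_altman["loa_upper_s"] == pytest.approx(-0.01)
        assert st.spearman_rho == pytest.approx(1.0)

    def test_rmse_mae_ba_match_naive_oracles(self, rng):
        a = rng.uniform(0.6, 1.1, 40)
        b = a + rng.normal(0, 0.02, 40)
        st = comparison_stats(series(a), series(b))
        assert st.rmse == pytest.approx(naive_rmse(a, b), rel=1e-12)
        assert st.mae == pytest.approx(naive_mae(a, b), rel=1e-12)
        mean, up, lo = naive_bland_altman(a, b)
        assert st.bland_altman["mean_diff_s"] == pytest.approx(mean, rel=1e-12)
        assert st.bland_altman["loa_upper_s"] == pytest.approx(up, rel=1e-12)
        assert st.bland_altman["loa_lower_s"] == pytest.approx(lo, rel=1e-12)

    def test_constant_series_undefined_statistic(self):
        with pytest.raises(UndefinedStatisticError, match="Spearman"):
            comparison_stats(series([0.8] * 10), series([0.8] * 10))


class TestLinCcc:
    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(10):
            x = rng.normal(1.0, 0.1, size=12)
            y = 0.7 * x + rng.normal(0.1, 0.05, size=12)
            ccc = lin_ccc(x, y)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-12

    def test_perfect_agreement(self):
        x = np.array([0.7, 0.8, 0.9, 1.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_bias_penalized(self):
        x = np.array([0.7, 0.8, 0.9, 1.0])
        assert lin_ccc(x, x + 0.5) < 0.1
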