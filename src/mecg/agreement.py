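"""M-ECG vs I-ECG comparison: peak pairing, quality gate, benchmarks, stats.

Signal quality is judged by temporal alignment of detected R-peaks rather
than by field-variance or SNR metrics: each M-ECG peak is paired with its
nearest I-ECG peak in sequence, offsets above 0.02 s count as misaligned,
and a recording passes the quality gate only if fewer than 3% of peaks are
misaligned *and* beat count agreement is at least 98%. Detector performance
against the reference uses the conventional sensitivity / PPV / F1 with a
+/-0.05 s tolerance window.

RR-series similarity uses Spearman rank correlation, RMSE/MAE, Bland-Altman
limits of agreement, two-sided Mann-Whitney U tests (on the RR distributions
and on the Welch PSD values), Lin's concordance correlation coefficient on
mean RR and RMSSD in non-overlapping 30-interval windows, and dynamic time
warping of the RR sequences (which tolerates unequal lengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .exceptions import EmptyInputError, InsufficientDataError, UndefinedStatisticError
from .hrv_metrics import SpectralResult
from .rpeak_detect import PeakSet
from .rr_series import RRSeries

MISALIGN_THRESHOLD_S = 0.02
GATE_MAX_PCT_MISALIGNED = 3.0  # fail at >= 3%
GATE_MIN_BEAT_AGREEMENT = 98.0  # fail below 98%
BENCHMARK_TOLERANCE_S = 0.05
CCC_WINDOW = 30


@dataclass
class AlignmentReport:
    pairs: list  # (m_time, i_time, offset_s)
    n_misaligned: int
    pct_misaligned: float
    offset_mean: float
    offset_sd: float
    beat_count_agreement: float  # percent
    passes_gate: bool

    def as_dict(self) -> dict:
        return {"n_pairs": len(self.pairs), "n_misaligned": self.n_misaligned,
                "pct_misaligned": self.pct_misaligned,
                "offset_mean_s": self.offset_mean, "offset_sd_s": self.offset_sd,
                "beat_count_agreement_pct": self.beat_count_agreement,
                "passes_gate": self.passes_gate}


@dataclass
class BenchmarkReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    ppv: float
    f1: float
    tolerance_s: float

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "sensitivity": self.sensitivity, "ppv": self.ppv,
                "f1": self.f1, "tolerance_s": self.tolerance_s}


@dataclass
class ComparisonStats:
    spearman_rho: float
    rmse: float  # s
    mae: float  # s
    bland_altman: dict  # {"mean_diff_s", "loa_upper_s", "loa_lower_s"}
    mwu_rr: dict  # {"statistic", "p"}
    mwu_psd: dict | None
    ccc_mean_rr: float | None
    ccc_rmssd: float | None
    dtw_distance: float  # s

    def as_dict(self) -> dict:
        return {"spearman_rho": self.spearman_rho, "rmse_s": self.rmse,
                "mae_s": self.mae, "bland_altman": self.bland_altman,
                "mwu_rr": self.mwu_rr, "mwu_psd": self.mwu_psd,
                "ccc_mean_rr": self.ccc_mean_rr, "ccc_rmssd": self.ccc_rmssd,
                "dtw_distance_s": self.dtw_distance}


def _gate(pct_misaligned: float, beat_count_agreement: float) -> bool:
    return (pct_misaligned < GATE_MAX_PCT_MISALIGNED
            and beat_count_agreement >= GATE_MIN_BEAT_AGREEMENT)


def pair_peaks_sequential(m: PeakSet, i: PeakSet,
                          misalign_threshold_s: float = MISALIGN_THRESHOLD_S,
                          ) -> AlignmentReport:
    """Order-preserving greedy pairing of M-ECG peaks to I-ECG peaks.

    Each M-peak pairs with its nearest I-peak at or after the previously
    consumed one (each I-peak used at most once; equidistant candidates take
    the earlier peak). Beat count agreement is
    ``100 * min(count_m, count_i) / max(count_m, count_i)``.
    """
    if len(m) == 0 or len(i) == 0:
        raise EmptyInputError("both peak sets must be non-empty")
    mt, it = m.times, i.times
    pairs = []
    j = 0
    for t in mt:
        if j >= it.size:
            break
        # nearest remaining i-peak; |t - it| is unimodal in the sorted array
        best = j + int(np.argmin(np.abs(it[j:] - t)))
        pairs.append((float(t), float(it[best]), float(abs(t - it[best]))))
        j = best + 1
    offsets = np.array([p[2] for p in pairs])
    n_mis = int(np.sum(offsets > misalign_threshold_s))
    pct = 100.0 * n_mis / len(pairs)
    bca = 100.0 * min(len(m), len(i)) / max(len(m), len(i))
    return AlignmentReport(
        pairs=pairs, n_misaligned=n_mis, pct_misaligned=pct,
        offset_mean=float(offsets.mean()), offset_sd=float(offsets.std()),
        beat_count_agreement=bca, passes_gate=_gate(pct, bca))


def benchmark_detection(m: PeakSet, i: PeakSet,
                        tolerance_s: float = BENCHMARK_TOLERANCE_S,
                        ) -> BenchmarkReport:
    """Sensitivity / PPV / F1 of M-ECG peaks against the I-ECG reference.

    Greedy in-order matching within the +/- tolerance window: a matched pair
    is a true positive, an unmatched M-peak a false positive, an unmatched
    I-peak a false negative. Undefined ratios are reported as 0.
    """
    if len(i) == 0:
        raise EmptyInputError("reference peak set must be non-empty")
    mt, it = m.times, i.times
    tp = 0
    j = 0
    for t in mt:
        while j < it.size and it[j] < t - tolerance_s:
            j += 1
        if j < it.size and abs(it[j] - t) <= tolerance_s:
            tp += 1
            j += 1
    fp = len(m) - tp
    fn = len(i) - tp
    sens = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * sens * ppv / (sens + ppv) if sens + ppv else 0.0
    return BenchmarkReport(tp=tp, fp=fp, fn=fn, sensitivity=sens, ppv=ppv,
                           f1=f1, tolerance_s=tolerance_s)


def dtw_distance(a, b) -> float:
    """Dynamic time warping distance between two RR sequences, in seconds.

    Classic dynamic programming with squared local cost, no warping-window
    constraint; the accumulated optimal-path cost is returned as its square
    root (Euclidean-style), so identical series give 0 and the value is in
    the units of the inputs.
    """
    sa = np.asarray(a.rr if isinstance(a, RRSeries) else a, dtype=float)
    sb = np.asarray(b.rr if isinstance(b, RRSeries) else b, dtype=float)
    if sa.size == 0 or sb.size == 0:
        raise EmptyInputError("DTW inputs must be non-empty")
    n, m = sa.size, sb.size
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for ii in range(1, n + 1):
        cost_row = (sa[ii - 1] - sb) ** 2
        for jj in range(1, m + 1):
            acc[ii, jj] = cost_row[jj - 1] + min(
                acc[ii - 1, jj], acc[ii, jj - 1], acc[ii - 1, jj - 1])
    return float(np.sqrt(acc[n, m]))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("CCC needs two equal-length series, n >= 2")
    vx, vy = np.var(x), np.var(y)
    if vx == 0 and vy == 0 and np.mean(x) == np.mean(y):
        raise UndefinedStatisticError("CCC undefined for two constant equal series")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise UndefinedStatisticError("CCC undefined (zero denominator)")
    return float(2 * sxy / denom)


def bland_altman(m, i) -> dict:
    """Mean difference (m - i) and 1.96-SD limits of agreement."""
    m = np.asarray(m, dtype=float)
    i = np.asarray(i, dtype=float)
    d = m - i
    mean = float(d.mean())
    sd = float(d.std())  # population SD, package-wide convention
    return {"mean_diff_s": mean, "loa_upper_s": mean + 1.96 * sd,
            "loa_lower_s": mean - 1.96 * sd}


def _windowed_metrics(rr: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean RR and RMSSD over non-overlapping complete windows."""
    n_win = rr.size // window
    means, rmssds = [], []
    for w in range(n_win):
        seg = rr[w * window: (w + 1) * window]
        means.append(seg.mean())
        rmssds.append(np.sqrt(np.mean(np.diff(seg) ** 2)))
    return np.asarray(means), np.asarray(rmssds)


def comparison_stats(rr_m: RRSeries, rr_i: RRSeries,
                     psd_m: SpectralResult | None = None,
                     psd_i: SpectralResult | None = None,
                     ccc_window: int = CCC_WINDOW) -> ComparisonStats:
    """The full statistical comparison suite for two RR series.

    Element-wise statistics (Spearman, RMSE, MAE, Bland-Altman) truncate both
    series to the common length; DTW is the designated length-tolerant
    comparison. The Mann-Whitney U test is two-sided, applied to the RR
    distributions and, when PSDs are supplied, to the PSD values over the
    common frequency grid. Lin's CCC is computed on per-window mean RR and
    per-window RMSSD over non-overlapping windows of ``ccc_window`` intervals
    (trailing partial window dropped); it needs >= 2 complete windows.
    """
    a, b = rr_m.rr, rr_i.rr
    n = min(a.size, b.size)
    if n < 2:
        raise InsufficientDataError("need >= 2 paired intervals")
    am, ai = a[:n], b[:n]
    if np.all(am == am[0]) or np.all(ai == ai[0]):
        raise UndefinedStatisticError("Spearman undefined for a constant series")
    rho = float(sstats.spearmanr(am, ai).statistic)
    rmse = float(np.sqrt(np.mean((am - ai) ** 2)))
    mae = float(np.mean(np.abs(am - ai)))
    ba = bland_altman(am, ai)
    u = sstats.mannwhitneyu(a, b, alternative="two-sided")
    mwu_rr = {"statistic": float(u.statistic), "p": float(u.pvalue)}
    mwu_psd = None
    if psd_m is not None and psd_i is not None:
        k = min(psd_m.psd.size, psd_i.psd.size)
        up = sstats.mannwhitneyu(psd_m.psd[:k], psd_i.psd[:k],
                                 alternative="two-sided")
        mwu_psd = {"statistic": float(up.statistic), "p": float(up.pvalue)}
    ccc_mean = ccc_rmssd = None
    if n // ccc_window >= 2:
        mean_m, rmssd_m = _windowed_metrics(am, ccc_window)
        mean_i, rmssd_i = _windowed_metrics(ai, ccc_window)
        ccc_mean = lin_ccc(mean_m, mean_i)
        ccc_rmssd = lin_ccc(rmssd_m, rmssd_i)
    return ComparisonStats(
        spearman_rho=rho, rmse=rmse, mae=mae, bland_altman=ba,
        mwu_rr=mwu_rr, mwu_psd=mwu_psd,
        ccc_mean_rr=ccc_mean, ccc_rmssd=ccc_rmssd,
        dtw_distance=dtw_distance(rr_m, rr_i))
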