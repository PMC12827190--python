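"""Time-domain HRV indices and spectral / time-frequency analysis.

Time domain: SDNN (population SD of RR — note many HRV tools use the 1/(N-1)
sample SD; the population convention is used consistently across this
package), RMSSD, mean RR, coefficient of variation, and a percentile 95% CI
of the RR values (2.5th/97.5th percentiles).

Frequency domain: Welch PSD of the evenly resampled tachogram (Hamming
window, 256-point segments, constant detrending, no overlap), with band
powers integrated by trapezoid over the standard HRV bands —
VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz. VLF is always reported
but marked non-interpretable on short recordings (it needs on the order of
ten cycles of its lowest frequency, ~50 min).

Time-frequency: a Morlet continuous wavelet transform of the cardiac trace
itself, where QRS complexes appear as recurrent broadband power bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import welch

from .exceptions import InsufficientDataError, MecgError
from .recording_io import CardiacTrace
from .rpeak_detect import PeakSet
from .rr_series import RRSeries, Tachogram

HRV_BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}
#: Minimum recording span for interpretable VLF: ~10 cycles of 0.0033 Hz.
VLF_MIN_SPAN_S = 10.0 / HRV_BANDS["vlf"][0]
DEFAULT_WELCH_SEGMENT = 256
#: Analytic Morlet with centre frequency 6 rad/s, the standard choice; in
#: PyWavelets' cmorB-C parametrisation C = 6 / (2*pi).
CWT_WAVELET = f"cmor1.0-{6.0 / (2.0 * np.pi):.6f}"


@dataclass(frozen=True)
class HRVTimeMetrics:
    mean_rr: float  # s
    sdnn: float  # s, population SD
    rmssd: float  # s
    sd: float  # s, identical to sdnn; reported separately by convention
    cv: float  # dimensionless, sd / mean_rr
    ci95: tuple[float, float]  # 2.5th / 97.5th percentile of RR values, s

    def as_dict(self) -> dict:
        return {"mean_rr_s": self.mean_rr, "sdnn_s": self.sdnn,
                "rmssd_s": self.rmssd, "sd_s": self.sd, "cv": self.cv,
                "ci95_low_s": self.ci95[0], "ci95_high_s": self.ci95[1]}


@dataclass
class SpectralResult:
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # s^2 / Hz
    band_powers: dict  # {"vlf": ..., "lf": ..., "hf": ...}
    vlf_interpretable: bool

    def as_dict(self) -> dict:
        return {"vlf_power": self.band_powers["vlf"],
                "lf_power": self.band_powers["lf"],
                "hf_power": self.band_powers["hf"],
                "vlf_interpretable": self.vlf_interpretable}


def time_domain_metrics(series: RRSeries) -> HRVTimeMetrics:
    """SDNN, RMSSD, CV and percentile CI of a corrected RR series."""
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 intervals for time-domain HRV")
    rr = series.rr
    mean = float(np.mean(rr))
    sd = float(np.sqrt(np.mean((rr - mean) ** 2)))
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    lo, hi = np.percentile(rr, [2.5, 97.5])
    return HRVTimeMetrics(mean_rr=mean, sdnn=sd, rmssd=rmssd, sd=sd,
                          cv=sd / mean, ci95=(float(lo), float(hi)))


def band_power(freqs: np.ndarray, psd: np.ndarray,
               band: tuple[float, float]) -> float:
    """Trapezoid integral of the PSD over [band_low, band_high]."""
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def welch_psd(tach: Tachogram, window: str = "hamming",
              segment: int = DEFAULT_WELCH_SEGMENT,
              detrend: str = "constant", overlap: int = 0) -> SpectralResult:
    """One-sided Welch PSD of the tachogram with HRV band powers."""
    v = np.asarray(tach.values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty tachogram")
    nperseg = min(segment, v.size)
    if nperseg < segment:
        import logging
        logging.getLogger(__name__).warning(
            "tachogram shorter than segment (%d < %d); shrinking segment",
            v.size, segment)
    freqs, psd = welch(v, fs=tach.rate, window=window, nperseg=nperseg,
                       noverlap=overlap, detrend=detrend)
    powers = {name: band_power(freqs, psd, b) for name, b in HRV_BANDS.items()}
    span = tach.span[1] - tach.span[0]
    return SpectralResult(freqs=freqs, psd=psd, band_powers=powers,
                          vlf_interpretable=bool(span >= VLF_MIN_SPAN_S))


def cwt_spectrogram(trace: CardiacTrace,
                    freq_range: tuple[float, float] = (0.5, 45.0),
                    n_scales: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Morlet CWT magnitude of a cardiac trace.

    Returns ``(freqs, magnitude)`` with ``magnitude`` of shape
    (n_scales, n_times) and ``freqs`` log-spaced (descending scale order ==
    ascending frequency). QRS complexes show up as recurrent high-power
    bursts across the mid frequencies.
    """
    lo, hi = freq_range
    nyq = trace.rate / 2
    if not (0 < lo < hi < nyq):
        raise MecgError(f"freq_range {freq_range} outside (0, {nyq}) Hz")
    freqs = np.logspace(np.log10(lo), np.log10(hi), n_scales)
    scales = pywt.frequency2scale(CWT_WAVELET, freqs / trace.rate)
    coeffs, out_freqs = pywt.cwt(trace.values, scales, CWT_WAVELET,
                                 sampling_period=1.0 / trace.rate)
    return out_freqs, np.abs(coeffs)


def peak_averaged_waveform(trace: CardiacTrace, peaks: PeakSet,
                           half_window_s: float = 0.4
                           ) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean waveform across R-peak-centred windows of identical length.

    Returns ``(lags_s, average, n_skipped)`` where windows truncated by the
    trace edges are skipped (and counted). The default half-window of 0.4 s
    spans a full P-QRS-T at normal heart rates.
    """
    half = int(round(half_window_s * trace.rate))
    n = trace.values.size
    segments = [trace.values[i - half: i + half + 1]
                for i in peaks.indices if i - half >= 0 and i + half + 1 <= n]
    n_skipped = len(peaks) - len(segments)
    if len(segments) < 3:
        raise InsufficientDataError(
            f"only {len(segments)} full windows; >= 3 required")
    avg = np.mean(np.stack(segments), axis=0)
    lags = (np.arange(-half, half + 1)) / trace.rate
    return lags, avg, n_skipped
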