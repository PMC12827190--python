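"""RR intervals: computation, outlier flagging, correction, and resampling.

RR_i = t_{i+1} - t_i for consecutive valid R-peaks. Each interval is paired
with its cumulative position x_i = sum_{k<=i} RR_k, measured from the first
detected peak; x is fixed *before* any correction so the cardiac timeline
stays physiologically accurate even where interval values are replaced.

Outliers (missed/spurious beats show up as roughly doubled/halved intervals)
are flagged with a mean +/- n * population-SD band (default n = 1.5),
conceptually zeroed, and restored by linear interpolation of RR against x
between the nearest valid neighbours — no data points are trimmed. For
spectral work the unevenly sampled corrected series is converted to an
evenly sampled tachogram with a natural cubic spline at a fixed number of
points (850), giving a uniform rate of roughly 2.4 Hz on 5-6 min recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import InsufficientBeatsError, InsufficientDataError, UnusableSeriesError
from .rpeak_detect import PeakSet

DEFAULT_N_RR = 1.5
DEFAULT_TACHOGRAM_POINTS = 850


@dataclass
class RRSeries:
    """RR intervals with cumulative times, outlier mask, and corrected values."""

    rr: np.ndarray  # seconds; corrected values once corrected=True
    x: np.ndarray  # cumulative time of each interval's end, from first peak
    outlier_mask: np.ndarray  # bool per interval
    corrected: bool = False
    rr_original: np.ndarray | None = None  # pre-correction values
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if not (self.rr.size == self.x.size == self.outlier_mask.size):
            raise ValueError("rr, x and outlier_mask must have equal length")
        if self.x.size > 1 and np.any(np.diff(self.x) <= 0):
            raise ValueError("cumulative times must be strictly increasing")

    def __len__(self) -> int:
        return self.rr.size

    @classmethod
    def from_intervals(cls, rr, corrected: bool = True) -> "RRSeries":
        """Build directly from interval values (x reconstructed by cumsum)."""
        rr = np.asarray(rr, dtype=float)
        return cls(rr=rr, x=np.cumsum(rr),
                   outlier_mask=np.zeros(rr.size, dtype=bool),
                   corrected=corrected)


@dataclass
class Tachogram:
    """Evenly resampled RR series ready for spectral analysis."""

    values: np.ndarray  # RR in seconds
    rate: float  # Hz, = (n_points - 1) / span
    span: tuple[float, float]  # [x_first, x_last] in seconds

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.span[0], self.span[1], self.n_points)


def compute_rr(peaks: PeakSet) -> RRSeries:
    """RR_i = t_{i+1} - t_i and the cumulative timeline x_i."""
    if len(peaks) < 3:
        raise InsufficientBeatsError(
            f"{len(peaks)} peaks; >= 3 needed to form an RR series")
    t = peaks.times
    rr = np.diff(t)
    return RRSeries(rr=rr, x=np.cumsum(rr),
                    outlier_mask=np.zeros(rr.size, dtype=bool), corrected=False)


def flag_rr_outliers(series: RRSeries, n: float = DEFAULT_N_RR) -> RRSeries:
    """Flag intervals outside mu_RR +/- n*sigma_RR (population statistics).

    Statistics are computed once, on the uncorrected series; flagging is a
    single evaluation, never iterated after correction.
    """
    if series.corrected:
        raise ValueError("flagging operates on the uncorrected series")
    rr = series.rr
    mu = float(np.mean(rr))
    sigma = float(np.sqrt(np.mean((rr - mu) ** 2)))
    mask = (rr < mu - n * sigma) | (rr > mu + n * sigma)
    return replace(series, outlier_mask=mask,
                   stats={"mu_rr": mu, "sigma_rr": sigma, "n_multiplier": n})


def correct_rr(series: RRSeries) -> RRSeries:
    """Replace flagged intervals by linear interpolation of RR against x.

    Flagged values are conceptually set to zero, then continuity is restored
    from the nearest non-flagged neighbours; a run of consecutive flags gets
    one linear segment across the gap. Boundary flags take the nearest valid
    value (constant extension). x is *not* recomputed, and the interval count
    never changes.
    """
    mask = series.outlier_mask
    if mask.all():
        raise UnusableSeriesError("every interval is flagged; series unusable")
    rr = series.rr.copy()
    if mask.any():
        rr[mask] = np.interp(series.x[mask], series.x[~mask], rr[~mask])
    return replace(series, rr=rr, rr_original=series.rr.copy(), corrected=True)


def resample_tachogram(series: RRSeries,
                       n_points: int = DEFAULT_TACHOGRAM_POINTS) -> Tachogram:
    """Natural cubic spline through (x_i, RR_i), evaluated on an even grid.

    The grid spans [x_1, x_last] (the first interval's cumulative time to the
    last), so the reported uniform rate is (n_points - 1) / span.
    """
    if not series.corrected:
        raise ValueError("resample the corrected series")
    if len(series) < 4:
        raise InsufficientDataError("cubic spline needs >= 4 intervals")
    spline = CubicSpline(series.x, series.rr, bc_type="natural")
    grid = np.linspace(series.x[0], series.x[-1], n_points)
    span = float(series.x[-1] - series.x[0])
    return Tachogram(values=spline(grid), rate=(n_points - 1) / span,
                     span=(float(series.x[0]), float(series.x[-1])))
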