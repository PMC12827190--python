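"""Two-stage threshold-based R-peak detection.

Stage one finds candidate local maxima with a physiological minimum
inter-peak distance (0.5 s, i.e. at most 120 bpm of candidates). Stage two
computes the candidate-amplitude mean and population standard deviation,

    mu_A = (1/N) sum A_i,    sigma_A = sqrt((1/N) sum (A_i - mu_A)^2),

and keeps only peaks with mu_A - n*sigma_A <= A_i <= mu_A + n*sigma_A
(default n = 2). Both multipliers are user-adjustable; the gate is applied
once, not iterated.

Spacing enforcement is greedy by amplitude: candidates are considered from
largest to smallest and accepted if no already-accepted peak lies within the
minimum distance. Equal amplitudes break ties toward the earlier sample, and
plateau maxima report their first sample, so detection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import EmptyResultError, InsufficientBeatsError
from .recording_io import CardiacTrace

DEFAULT_MIN_DISTANCE_S = 0.5
DEFAULT_N_AMP = 2.0


@dataclass
class PeakSet:
    """Detected R-peaks with the parameters and statistics that produced them."""

    indices: np.ndarray  # 0-based sample positions, strictly increasing
    rate: float
    amplitudes: np.ndarray  # trace value at each index
    params: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)  # {"mu_a": ..., "sigma_a": ...}

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds (= index / rate)."""
        return self.indices / self.rate

    def __len__(self) -> int:
        return self.indices.size

    @classmethod
    def from_times(cls, times, rate: float = 1000.0) -> "PeakSet":
        """Build a PeakSet from peak times in seconds (unit amplitudes)."""
        times = np.asarray(times, dtype=float)
        idx = np.round(times * rate).astype(int)
        return cls(indices=idx, rate=rate, amplitudes=np.ones(times.size))


def _local_maxima(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima; plateaus report their first sample."""
    idx, props = find_peaks(values, plateau_size=1)
    left = props["left_edges"]
    return left, values[left]


def _enforce_spacing(idx: np.ndarray, amps: np.ndarray,
                     min_dist: int) -> np.ndarray:
    """Greedy largest-first spacing; ties keep the earlier candidate.

    Returns positions (into idx) of retained candidates, in time order.
    """
    order = sorted(range(idx.size), key=lambda k: (-amps[k], idx[k]))
    kept: list[int] = []
    kept_pos: list[int] = []
    for k in order:
        if all(abs(int(idx[k]) - p) >= min_dist for p in kept):
            kept.append(int(idx[k]))
            kept_pos.append(k)
    kept_pos.sort(key=lambda k: idx[k])
    return np.asarray(kept_pos, dtype=int)


def find_candidate_peaks(trace: CardiacTrace,
                         min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
                         ) -> PeakSet:
    """Stage one: local maxima with the minimum inter-peak distance enforced.

    The candidate-amplitude statistics (population mean/SD) are computed here,
    over the spacing-enforced candidate set, and carried in ``stats``.
    """
    values = trace.values
    if values.size < 2:
        raise InsufficientBeatsError("trace too short for peak detection")
    idx, amps = _local_maxima(values)
    min_dist = max(int(round(min_distance_s * trace.rate)), 1)
    keep = _enforce_spacing(idx, amps, min_dist)
    idx, amps = idx[keep], amps[keep]
    if idx.size:
        mu = float(np.mean(amps))
        sigma = float(np.sqrt(np.mean((amps - mu) ** 2)))
    else:
        mu = sigma = float("nan")
    return PeakSet(indices=idx, rate=trace.rate, amplitudes=amps,
                   params={"min_distance_s": min_distance_s},
                   stats={"mu_a": mu, "sigma_a": sigma, "n_candidates": int(idx.size)})


def filter_peaks_by_amplitude(peaks: PeakSet, n: float = DEFAULT_N_AMP) -> PeakSet:
    """Stage two: keep candidates inside mu_A +/- n*sigma_A (single pass)."""
    if len(peaks) == 0:
        raise EmptyResultError("candidate set is empty")
    mu, sigma = peaks.stats["mu_a"], peaks.stats["sigma_a"]
    lo, hi = mu - n * sigma, mu + n * sigma
    mask = (peaks.amplitudes >= lo) & (peaks.amplitudes <= hi)
    if not mask.any():
        raise EmptyResultError(
            f"amplitude gate [{lo:.4g}, {hi:.4g}] rejected every candidate; "
            "consider increasing the n multiplier")
    return PeakSet(indices=peaks.indices[mask], rate=peaks.rate,
                   amplitudes=peaks.amplitudes[mask],
                   params={**peaks.params, "n_amp": n},
                   stats=dict(peaks.stats))


def detect_rpeaks(trace: CardiacTrace,
                  min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
                  n: float = DEFAULT_N_AMP,
                  polarity: str = "auto") -> PeakSet:
    """Full two-stage detection with polarity correction.

    ICA component sign is arbitrary, so with ``polarity="auto"`` the trace is
    negated before detection whenever |min| > |max|; detection is therefore
    sign-invariant. ``polarity`` may be forced to ``"positive"`` or
    ``"negative"``. At least 3 retained peaks are required for RR work.
    """
    values = trace.values
    if polarity == "auto":
        flip = values.size > 0 and abs(values.min()) > abs(values.max())
    elif polarity in ("positive", "negative"):
        flip = polarity == "negative"
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    work = trace if not flip else CardiacTrace(
        values=-values, rate=trace.rate, source=trace.source, meta=trace.meta)
    cand = find_candidate_peaks(work, min_distance_s)
    if len(cand) == 0:
        raise InsufficientBeatsError("no candidate peaks found")
    peaks = filter_peaks_by_amplitude(cand, n)
    if len(peaks) < 3:
        raise InsufficientBeatsError(
            f"only {len(peaks)} peaks retained; >= 3 required")
    peaks.params["polarity_flipped"] = bool(flip)
    return peaks
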