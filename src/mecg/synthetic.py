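"""Ground-truth generator: RR series, ECG-like traces, MEG-like mixtures.

The beat model is sinusoid-plus-jitter rather than integral pulse frequency
modulation: each RR interval is

    RR_k = mean_rr + lf_amp * sin(2*pi*lf_freq*x_k)
                   + hf_amp * sin(2*pi*hf_freq*x_k) + N(0, jitter_sd),

generated iteratively so the cumulative time x_k is self-consistent. This
keeps closed-form expectations (e.g. the RR standard deviation of a pure
sinusoidal modulation is amp/sqrt(2)) for verification. LF (~0.1 Hz) and HF
(~0.25 Hz) modulation emulate the statistical structure of sympathetic and
respiratory heart-rate modulation without claiming physiological mechanism.

The ECG-like trace renders a unit-amplitude Gaussian bump per beat (SD =
qrs_width/4) plus an optional smaller, wider T-wave bump. The MEG-like
mixture spreads that trace linearly across noisy channels named in the
MRT/MLT temporal style, adds two reference sensors (one carrying the cardiac
source strongly, one noise-only) and a clean bipolar ECG channel, so every
pipeline stage — channel selection, ICA, reference selection, I-ECG
comparison — is exercisable with known ground truth.

Everything is driven by one integer seed; the same spec and seed reproduce
outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import MecgError
from .recording_io import CardiacTrace, MultichannelRecording


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults emulate a 5-minute resting recording at 75 bpm with mild LF/HF
    modulation, beat-timing jitter of 5 ms, and channel noise giving roughly
    10 dB SNR at unit mixing weight.
    """

    duration_s: float = 300.0
    mean_rr_s: float = 0.8
    lf_freq_hz: float = 0.1
    lf_amp_s: float = 0.03
    hf_freq_hz: float = 0.25
    hf_amp_s: float = 0.02
    jitter_sd_s: float = 0.005
    rate_hz: float = 600.0
    qrs_width_s: float = 0.08
    t_wave_amp: float = 0.2  # relative to the R bump; 0 disables
    #: Fractional respiratory modulation of R-bump amplitude (sinusoidal at
    #: hf_freq). Real R-peak amplitude varies with respiration by ~10%; a
    #: constant-amplitude train is degenerate for amplitude-threshold
    #: detectors (its amplitude spread is then pure sensor noise).
    r_amp_mod: float = 0.1
    noise_sd: float = 0.07  # channel noise, trace units
    n_channels: int = 27
    weight_range: tuple[float, float] = (0.5, 1.5)
    ref_weight: float = 2.0  # cardiac weight of the strong reference sensor
    drift_amp: float = 0.0  # optional low-frequency channel drift
    seed: int = 0

    def validate(self) -> None:
        margin = self.mean_rr_s - (self.lf_amp_s + self.hf_amp_s
                                   + 4 * self.jitter_sd_s)
        if margin <= 0.3:
            raise MecgError(
                f"spec leaves physiological margin {margin:.3f} s <= 0.3 s; "
                "RR intervals could become implausibly short")
        if not 0.04 <= self.lf_freq_hz < 0.15:
            raise MecgError("lf_freq must lie in [0.04, 0.15) Hz")
        if not 0.15 <= self.hf_freq_hz <= 0.4:
            raise MecgError("hf_freq must lie in [0.15, 0.4] Hz")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    peak_times_s: np.ndarray
    rr_s: np.ndarray
    clean_trace: np.ndarray | None = None
    rate_hz: float | None = None
    mixing_weights: np.ndarray | None = None
    spec: SyntheticSpec | None = None
    lf_phase: float = 0.0  # modulation phases drawn per seed (radians)
    hf_phase: float = 0.0

    def drop_peaks(self, fraction: float, seed: int = 0) -> "GroundTruth":
        """Delete a random fraction of interior peaks (emulating missed
        beats, which merge adjacent RR intervals into doubled outliers)."""
        rng = np.random.default_rng(seed)
        n = self.peak_times_s.size
        n_drop = int(round(fraction * n))
        candidates = np.arange(1, n - 1)  # keep the endpoints
        drop = rng.choice(candidates, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        t = self.peak_times_s[keep]
        return replace(self, peak_times_s=t, rr_s=np.diff(t))


def simulate_rr(spec: SyntheticSpec = SyntheticSpec()) -> GroundTruth:
    """Generate self-consistent beat times and RR intervals.

    The first beat sits at mean_rr/2, not at t = 0: a recording never starts
    exactly on an R-peak, and a beat cut by the trace edge would leave a
    boundary transient after filtering. The LF/HF modulation phases are drawn
    uniformly per seed (recorded in the returned GroundTruth): respiration
    and baroreflex phase are arbitrary relative to recording onset, and
    independent realizations must differ in more than their jitter to form a
    genuine distributional null.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lf_phase, hf_phase = rng.uniform(0.0, 2 * np.pi, size=2)
    t = spec.mean_rr_s / 2.0
    times = [t]
    while True:
        rr = (spec.mean_rr_s
              + spec.lf_amp_s * np.sin(2 * np.pi * spec.lf_freq_hz * t
                                       + lf_phase)
              + spec.hf_amp_s * np.sin(2 * np.pi * spec.hf_freq_hz * t
                                       + hf_phase)
              + (rng.normal(0.0, spec.jitter_sd_s) if spec.jitter_sd_s else 0.0))
        if t + rr >= spec.duration_s:
            break
        t += rr
        times.append(t)
    times = np.asarray(times)
    return GroundTruth(peak_times_s=times, rr_s=np.diff(times), spec=spec,
                       lf_phase=float(lf_phase), hf_phase=float(hf_phase))


def synthesize_ecg(gt: GroundTruth, rate: float = 600.0,
                   qrs_width_s: float | None = None) -> CardiacTrace:
    """Render an ECG-like trace with a Gaussian QRS bump at each beat."""
    spec = gt.spec or SyntheticSpec()
    qrs_width_s = qrs_width_s if qrs_width_s is not None else spec.qrs_width_s
    if qrs_width_s * rate < 4:
        raise MecgError(f"rate {rate} Hz too low to render a {qrs_width_s} s QRS")
    duration = spec.duration_s if gt.spec else (
        float(gt.peak_times_s[-1]) + 1.0 if gt.peak_times_s.size else 1.0)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    values = np.zeros(n)
    sd = qrs_width_s / 4.0
    t_sd = qrs_width_s  # T wave: wider and smaller
    for tp in gt.peak_times_s:
        # amplitude modulation shares the respiratory (HF) phase
        amp = 1.0 + spec.r_amp_mod * np.sin(
            2 * np.pi * spec.hf_freq_hz * tp + gt.hf_phase)
        lo = max(0, int((tp - 5 * sd) * rate))
        hi = min(n, int((tp + 5 * sd) * rate) + 1)
        values[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tp) / sd) ** 2)
        if spec.t_wave_amp:
            tc = tp + 0.25  # T wave ~250 ms after R
            lo2 = max(0, int((tc - 4 * t_sd) * rate))
            hi2 = min(n, int((tc + 4 * t_sd) * rate) + 1)
            values[lo2:hi2] += spec.t_wave_amp * np.exp(
                -0.5 * ((t[lo2:hi2] - tc) / t_sd) ** 2)
    gt.clean_trace = values
    gt.rate_hz = rate
    return CardiacTrace(values=values, rate=rate, source="I-ECG")


def mix_into_channels(trace: CardiacTrace, spec: SyntheticSpec
                      ) -> tuple[MultichannelRecording, GroundTruth]:
    """Linearly mix the cardiac trace into noisy MEG-like channels.

    Channel j = w_j * trace + N(0, noise_sd) (+ optional drift). Channels are
    named in the temporal MRT/MLT style with role ``meg_gradiometer``; two
    reference sensors are appended (``BR1`` with elevated cardiac weight,
    ``BR2`` noise-only), plus a clean bipolar ``ECG`` channel for the I-ECG
    comparison path.
    """
    if spec.n_channels < 2:
        raise MecgError("need at least 2 channels")
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from RR jitter
    w = rng.uniform(*spec.weight_range, size=spec.n_channels)
    if np.all(w == 0):
        raise MecgError("all-zero mixing weights")
    v = trace.values
    n = v.size
    names, roles, rows, weights = [], [], [], []
    for j in range(spec.n_channels):
        side = "R" if j % 2 == 0 else "L"
        names.append(f"M{side}T{31 + j // 2}")
        roles.append("meg_gradiometer")
        row = w[j] * v + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.drift_amp:
            row = row + spec.drift_amp * np.sin(
                2 * np.pi * 0.05 * np.arange(n) / trace.rate + j)
        rows.append(row)
        weights.append(w[j])
    rows.append(spec.ref_weight * v
                + rng.normal(0.0, spec.noise_sd, size=n))
    names.append("BR1")
    roles.append("reference")
    weights.append(spec.ref_weight)
    rows.append(rng.normal(0.0, spec.noise_sd, size=n))
    names.append("BR2")
    roles.append("reference")
    weights.append(0.0)
    rows.append(v.copy())
    names.append("ECG")
    roles.append("ecg_bipolar")
    weights.append(1.0)
    rec = MultichannelRecording(samples=np.vstack(rows), rate=trace.rate,
                                channel_names=tuple(names),
                                channel_roles=tuple(roles))
    gt = GroundTruth(peak_times_s=np.array([]), rr_s=np.array([]),
                     clean_trace=v.copy(), rate_hz=trace.rate,
                     mixing_weights=np.asarray(weights), spec=spec)
    return rec, gt


def make_dataset(spec: SyntheticSpec = SyntheticSpec()
                 ) -> tuple[MultichannelRecording, GroundTruth]:
    """Full synthetic study: beats -> ECG trace -> multichannel mixture.

    Returns the recording and a GroundTruth carrying true peak times, true RR
    intervals, the clean cardiac trace, and the mixing weights.
    """
    gt = simulate_rr(spec)
    trace = synthesize_ecg(gt, rate=spec.rate_hz)
    rec, mix_gt = mix_into_channels(trace, spec)
    gt.mixing_weights = mix_gt.mixing_weights
    return rec, gt
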