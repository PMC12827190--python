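"""Produce M-ECG candidate traces from a preprocessed recording.

Two routes exist. The ICA route decomposes the temporal-channel subset with
FastICA and exposes the cardiac independent component (C-IC). The reference
route picks the MEG reference (noise-cancellation) sensor that carries the
strongest cardiac signature (REF), bypassing ICA entirely — faster, and
usable when ICA separation is noisy.

Component/channel choice in the original workflow is visual. Here an
*advisory* ranking scores each candidate by beat-band periodicity (the
autocorrelation peak in the 0.5-1.5 s lag range, i.e. 40-120 bpm) and by
excess kurtosis (spiky QRS morphology). The final choice remains a user
parameter; "auto" simply takes the top-ranked candidate and records it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .exceptions import DecompositionError, SelectionError
from .recording_io import CardiacTrace, MultichannelRecording

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 15
DEFAULT_ICA_SEED = 0
#: Advisory score = 0.7 * periodicity + 0.3 * squashed kurtosis. Periodicity
#: is the stronger cardiac signature; kurtosis k is squashed as k/(k+10).
RANK_WEIGHT_PERIODICITY = 0.7
RANK_WEIGHT_KURTOSIS = 0.3
BEAT_LAG_RANGE_S = (0.5, 1.5)


@dataclass
class ComponentSet:
    """FastICA sources plus the mixing that maps components back to channels."""

    sources: np.ndarray  # (n_components, n_times), unit variance
    mixing: np.ndarray  # (n_channels, n_components)
    n_components: int
    seed: int
    rate: float


@dataclass(frozen=True)
class CandidateRanking:
    component_index: int
    score: float  # in [0, 1]
    periodicity: float
    kurtosis: float
    beat_rate_hz: float


def run_ica(rec: MultichannelRecording, n_components: int = DEFAULT_N_COMPONENTS,
            seed: int = DEFAULT_ICA_SEED) -> ComponentSet:
    """FastICA decomposition of a (bandpassed) recording.

    Deterministic for a fixed ``seed``; sources are unit-variance. Sign and
    order of components are arbitrary, as always with ICA.
    """
    if n_components > rec.n_channels:
        raise DecompositionError(
            f"n_components={n_components} exceeds channel count {rec.n_channels}")
    # A near-Gaussian noise subspace has no unique ICA rotation, so the
    # iteration can cycle indefinitely there while the (super-Gaussian)
    # cardiac component stabilizes within a few tens of iterations; a modest
    # cap keeps runtime bounded without affecting the component of interest.
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=200, tol=1e-3)
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            sources = ica.fit_transform(rec.samples.T).T
    except Exception as exc:
        raise DecompositionError(f"FastICA failed: {exc}") from exc
    if not np.all(np.isfinite(sources)):
        raise DecompositionError("FastICA produced non-finite sources "
                                 "(rank-deficient data?)")
    return ComponentSet(sources=sources, mixing=ica.mixing_,
                        n_components=n_components, seed=seed, rate=rec.rate)


def _periodicity_and_rate(x: np.ndarray, rate: float) -> tuple[float, float]:
    """Peak of the normalized autocorrelation within the beat-lag band."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0, 0.0
    lo = int(round(BEAT_LAG_RANGE_S[0] * rate))
    hi = int(round(BEAT_LAG_RANGE_S[1] * rate))
    hi = min(hi, x.size - 1)
    if lo >= hi:
        return 0.0, 0.0
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(X * np.conj(X), nfft)[: n] / denom
    band = ac[lo: hi + 1]
    k = int(np.argmax(band))
    best_lag_s = (lo + k) / rate
    return float(np.clip(band[k], 0.0, 1.0)), 1.0 / best_lag_s


def _score_candidates(traces: np.ndarray, rate: float) -> list[CandidateRanking]:
    out = []
    for i, row in enumerate(traces):
        per, beat = _periodicity_and_rate(row, rate)
        kurt = float(sstats.kurtosis(row, fisher=True)) if row.size > 3 else 0.0
        ksq = max(kurt, 0.0) / (max(kurt, 0.0) + 10.0)
        score = RANK_WEIGHT_PERIODICITY * per + RANK_WEIGHT_KURTOSIS * ksq
        out.append(CandidateRanking(component_index=i, score=score,
                                    periodicity=per, kurtosis=kurt,
                                    beat_rate_hz=beat))
    out.sort(key=lambda r: (-r.score, r.component_index))
    return out


def rank_cardiac_candidates(comps: ComponentSet,
                            rate: float | None = None) -> list[CandidateRanking]:
    """Advisory ranking of ICA components by cardiac likelihood (descending)."""
    if comps.sources.shape[0] == 0:
        return []
    return _score_candidates(comps.sources, rate or comps.rate)


def extract_component_trace(comps: ComponentSet,
                            choice: int | str = "auto") -> CardiacTrace:
    """Return the chosen (or top-ranked) component as a C-IC cardiac trace."""
    if choice == "auto":
        ranking = rank_cardiac_candidates(comps)
        idx = ranking[0].component_index
        logger.info("auto-selected ICA component %d (score %.3f)",
                    idx, ranking[0].score)
    else:
        idx = int(choice)
        if not 0 <= idx < comps.n_components:
            raise SelectionError(f"component index {idx} out of range")
    return CardiacTrace(values=comps.sources[idx].copy(), rate=comps.rate,
                        source="C-IC",
                        meta={"component_index": idx, "ica_seed": comps.seed})


def select_reference_trace(rec: MultichannelRecording,
                           name: str = "auto") -> CardiacTrace:
    """Pick the reference sensor carrying the most robust cardiac activity.

    ``"auto"`` ranks all reference-role channels with the same advisory score
    used for ICA components and takes the best; an explicit channel label
    overrides the ranking.
    """
    ref_idx = [i for i, r in enumerate(rec.channel_roles) if r == "reference"]
    if not ref_idx:
        raise SelectionError("recording has no channels with role 'reference'")
    if name == "auto":
        ranking = _score_candidates(rec.samples[ref_idx], rec.rate)
        chosen = ref_idx[ranking[0].component_index]
        logger.info("auto-selected reference channel %s (score %.3f)",
                    rec.channel_names[chosen], ranking[0].score)
    else:
        if name not in rec.channel_names:
            raise SelectionError(f"no channel named {name!r}")
        chosen = rec.channel_names.index(name)
    return CardiacTrace(values=rec.samples[chosen].copy(), rate=rec.rate,
                        source="REF", meta={"channel": rec.channel_names[chosen]})
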