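"""Multichannel recording container and readers/writers.

A :class:`MultichannelRecording` holds sensor-by-time data with a single
sampling rate, ordered channel names and a physiological role per channel
(MEG gradiometer, reference sensor, bipolar ECG, or other). Native MEG
formats (FIF, CTF ``.ds``) are read through MNE-Python; a plain CSV dialect
and a NumPy ``.npz`` container cover fixtures and intermediates.

All internal times are seconds and all indices 0-based.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AmbiguousChannelError,
    EmptyInputError,
    FormatError,
    SelectionError,
)

#: Channel roles understood by the pipeline.
ROLES = ("meg_gradiometer", "reference", "ecg_bipolar", "other")

#: Default temporal-channel pattern: right/left temporal gradiometers 31-58,
#: the region where the cardiac field signature is strongest.
TEMPORAL_PATTERN = tuple(
    f"M{side}T{num}*" for side in ("R", "L") for num in range(31, 59)
)


@dataclass
class MultichannelRecording:
    """Sensor x time samples with rate, channel names, and channel roles."""

    samples: np.ndarray  # (n_channels, n_times), physical units per channel
    rate: float  # Hz
    channel_names: tuple[str, ...]
    channel_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise EmptyInputError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] == 0:
            raise EmptyInputError("recording has zero channels")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length does not match samples")
        if len(self.channel_roles) != len(self.channel_names):
            raise ValueError("channel_roles length does not match channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for r in self.channel_roles:
            if r not in ROLES:
                raise ValueError(f"unknown channel role {r!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise SelectionError(f"no channel named {name!r}") from None
        return self.samples[idx]


@dataclass
class CardiacTrace:
    """One-dimensional cardiac signal with a provenance label.

    ``source`` records where the trace came from: ``"I-ECG"`` (the
    independently recorded bipolar ECG), ``"C-IC"`` (cardiac independent
    component), or ``"REF"`` (MEG reference sensor).
    """

    values: np.ndarray
    rate: float
    source: str  # one of {"I-ECG", "C-IC", "REF"}
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.source not in ("I-ECG", "C-IC", "REF"):
            raise ValueError(f"unknown trace source {self.source!r}")
        if self.normalized and self.values.size:
            if abs(np.max(np.abs(self.values)) - 1.0) > 1e-9:
                raise ValueError("normalized trace must have max |value| == 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


def _roles_from_mne(raw) -> tuple[str, ...]:
    mapping = {"mag": "meg_gradiometer", "grad": "meg_gradiometer",
               "ref_meg": "reference", "ecg": "ecg_bipolar"}
    return tuple(mapping.get(t, "other") for t in raw.get_channel_types())


def _load_mne(path: Path, fmt: str) -> MultichannelRecording:
    import mne

    try:
        if fmt == "fif":
            raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_ctf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted IO errors
        raise FormatError(f"could not read {fmt} file {path}: {exc}") from exc
    return MultichannelRecording(
        samples=raw.get_data(),
        rate=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        channel_roles=_roles_from_mne(raw),
    )


def _load_csv(path: Path, rate: float | None,
              roles: Mapping[str, str] | None) -> MultichannelRecording:
    with open(path) as fh:
        header = fh.readline().strip()
    raw_cols = [c.strip() for c in header.split(",") if c.strip()]
    if len(set(raw_cols)) != len(raw_cols):
        # pandas would silently mangle duplicates to "a", "a.1"
        raise FormatError(f"CSV {path} has duplicate channel names")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse CSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise EmptyInputError("CSV has no columns")
    cols = list(df.columns)
    if cols[0].strip().lower() in ("t", "time", "time_s"):
        t = df[cols[0]].to_numpy(dtype=float)
        if t.size < 2:
            raise FormatError("time column needs >= 2 rows to infer a rate")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise FormatError("time column must be strictly increasing")
        rate = 1.0 / dt
        df = df.drop(columns=cols[0])
        cols = list(df.columns)
    if rate is None:
        raise FormatError("CSV has no time column; a sampling rate is required")
    if not cols:
        raise EmptyInputError("CSV contains a time column but no channels")
    if len(set(cols)) != len(cols):
        raise FormatError("CSV has duplicate channel names")
    roles = dict(roles or {})
    return MultichannelRecording(
        samples=df.to_numpy(dtype=float).T,
        rate=float(rate),
        channel_names=tuple(cols),
        channel_roles=tuple(roles.get(c, "other") for c in cols),
    )


def load_recording(path, format: str | None = None, *, rate: float | None = None,
                   roles: Mapping[str, str] | None = None) -> MultichannelRecording:
    """Load a recording from FIF, CTF ``.ds``, CSV, or the npz container.

    Parameters
    ----------
    path
        File (or ``.ds`` directory) to read.
    format
        One of ``{"fif", "ctf_ds", "csv", "array_container"}``; inferred from
        the suffix when omitted.
    rate
        Sampling rate in Hz, required for CSV files without a time column.
    roles
        Optional ``{channel_name: role}`` overrides for formats without role
        metadata (CSV).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = {".fif": "fif", ".ds": "ctf_ds", ".csv": "csv",
                  ".npz": "array_container"}.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path}")
    if format in ("fif", "ctf_ds"):
        rec = _load_mne(path, format)
    elif format == "csv":
        rec = _load_csv(path, rate, roles)
    elif format == "array_container":
        with np.load(path, allow_pickle=False) as z:
            try:
                rec = MultichannelRecording(
                    samples=z["samples"], rate=float(z["rate"]),
                    channel_names=tuple(str(n) for n in z["channel_names"]),
                    channel_roles=tuple(str(r) for r in z["channel_roles"]),
                )
            except KeyError as exc:
                raise FormatError(f"container {path} is missing key {exc}") from exc
    else:
        raise FormatError(f"unsupported format {format!r}")
    if roles and format != "csv":
        names = rec.channel_names
        rec = replace(rec, channel_roles=tuple(
            roles.get(n, r) for n, r in zip(names, rec.channel_roles)))
    return rec


def save_recording(rec: MultichannelRecording, path) -> Path:
    """Write a recording as CSV (``.csv``) or the npz container (``.npz``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        t = np.arange(rec.n_times) / rec.rate
        df = pd.DataFrame({"t": t})
        for name, row in zip(rec.channel_names, rec.samples):
            df[name] = row
        df.to_csv(path, index=False)
    elif path.suffix.lower() == ".npz":
        np.savez(path, samples=rec.samples, rate=rec.rate,
                 channel_names=np.array(rec.channel_names),
                 channel_roles=np.array(rec.channel_roles))
    else:
        raise FormatError("save_recording writes only .csv or .npz")
    return path


def select_channels(rec: MultichannelRecording,
                    pattern: str | Sequence[str] = TEMPORAL_PATTERN,
                    ) -> MultichannelRecording:
    """Subset channels by a name glob (or list of globs / explicit names).

    The default pattern selects the right/left temporal gradiometers
    (MRT/MLT 31-58) where cardiac contamination is strongest. Order and rate
    are preserved; the operation is idempotent.
    """
    patterns = [pattern] if isinstance(pattern, str) else list(pattern)
    keep = [i for i, name in enumerate(rec.channel_names)
            if any(fnmatch.fnmatchcase(name, p) or name == p for p in patterns)]
    if not keep:
        raise SelectionError(f"no channel matches pattern {pattern!r}")
    return MultichannelRecording(
        samples=rec.samples[keep],
        rate=rec.rate,
        channel_names=tuple(rec.channel_names[i] for i in keep),
        channel_roles=tuple(rec.channel_roles[i] for i in keep),
    )


def extract_ecg_channel(rec: MultichannelRecording,
                        name: str | None = None) -> CardiacTrace:
    """Extract the independently recorded bipolar ECG channel (I-ECG).

    With no ``name``, exactly one channel must carry the ``ecg_bipolar`` role.
    """
    if name is None:
        idx = [i for i, r in enumerate(rec.channel_roles) if r == "ecg_bipolar"]
        if len(idx) == 0:
            raise AmbiguousChannelError("no channel has role ecg_bipolar")
        if len(idx) > 1:
            names = [rec.channel_names[i] for i in idx]
            raise AmbiguousChannelError(
                f"multiple ECG channels {names}; pass an explicit name")
        values = rec.samples[idx[0]]
    else:
        values = rec.channel(name)
    return CardiacTrace(values=values.copy(), rate=rec.rate,
                        source="I-ECG", normalized=False)
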