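"""Exception hierarchy for the M-ECG pipeline.

Every error the pipeline raises deliberately derives from :class:`MecgError`,
so callers (and the CLI) can distinguish pipeline conditions from bugs.
"""


class MecgError(Exception):
    """Base class for all deliberate pipeline errors."""


class FormatError(MecgError):
    """A file could not be read in the requested format."""


class EmptyInputError(MecgError):
    """An input contained no channels or no samples."""


class SelectionError(MecgError):
    """A channel pattern or role selection matched nothing."""


class AmbiguousChannelError(MecgError):
    """More than one channel fits a role and no explicit name was given."""


class FilterSpecError(MecgError):
    """A filter specification is invalid for the signal's sampling rate."""


class DegenerateSignalError(MecgError):
    """A signal is constant (or otherwise unusable) where variation is required."""


class DecompositionError(MecgError):
    """Wavelet or ICA decomposition failed (too-short signal, rank deficiency...)."""


class InsufficientBeatsError(MecgError):
    """Fewer detected beats than the downstream computation needs."""


class EmptyResultError(MecgError):
    """A filtering step rejected every item; thresholds likely need adjustment."""


class UnusableSeriesError(MecgError):
    """An RR series cannot be corrected (e.g. every interval is flagged)."""


class InsufficientDataError(MecgError):
    """Not enough data points for a statistic or spline."""


class UndefinedStatisticError(MecgError):
    """A statistic is mathematically undefined for the given input (names the metric)."""
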