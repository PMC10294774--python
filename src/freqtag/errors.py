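"""Exception taxonomy for the freqtag pipeline.

All package errors derive from :class:`FreqTagError`; parameter-domain
violations additionally derive from :class:`ValueError` so that callers can
catch them generically.
"""


class FreqTagError(Exception):
    """Base class for all freqtag errors."""


class InvalidParameterError(FreqTagError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientPoolError(InvalidParameterError):
    """Sentence pool smaller than the number of sentences requested."""


class InconsistentInputError(InvalidParameterError):
    """Inputs that must agree (e.g. sequence durations) do not."""


class InsufficientTrialsError(InvalidParameterError):
    """Fewer than two trials: coherence over trials is undefined."""


class MissingBaselineError(FreqTagError):
    """Epoch window contains no pre-onset samples to baseline against."""


class InvalidWindowError(InvalidParameterError):
    """Analysis window does not lie within the epoch window."""


class UndefinedPhaseError(FreqTagError):
    """A Fourier coefficient has (near-)zero magnitude: its phase is undefined."""


class OffGridError(InvalidParameterError):
    """Requested frequency does not fall on the analysis grid."""


class MontageError(InvalidParameterError):
    """A channel label is not present in the montage."""


class PairedDataError(InvalidParameterError):
    """Paired samples have mismatched lengths or too few pairs."""


class DegenerateInputError(FreqTagError):
    """Zero-variance input where a scale estimate is required."""


class ConfigError(FreqTagError):
    """A run configuration failed validation."""
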