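"""Exception hierarchy for the radar-HRV pipeline.

Every stage raises a subclass of :class:`RadarHrvError` so that the cohort
runner can isolate per-subject failures without masking programming errors.
"""


class RadarHrvError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(RadarHrvError, ValueError):
    """Malformed or inconsistent input data (length mismatch, NaN, ...)."""


class InvalidConfigurationError(RadarHrvError, ValueError):
    """A configuration value is outside its admissible range."""


class LowSignalError(RadarHrvError):
    """The complex baseband magnitude is too small to demodulate phase."""


class SyncFailureError(RadarHrvError):
    """Synchronisation sequences could not be matched with confidence."""


class InsufficientOverlapError(SyncFailureError):
    """Aligned records overlap for less time than the required minimum."""


class InvalidTrainingDataError(RadarHrvError, ValueError):
    """Training labels do not cover the model's state space."""


class HeartRateOutOfRangeError(RadarHrvError, ValueError):
    """Estimated heart rate lies outside the segmenter's admissible range."""
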