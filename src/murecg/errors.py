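"""Exceptions shared across the analysis stages."""


class MurecgError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(MurecgError):
    """Raised when a record holds too few beats/intervals for the requested statistic."""


class NotEvaluableError(MurecgError):
    """Raised when a detector cannot run at all (e.g. no atrial annotations).

    Distinct from a clean negative result: 'could not look' is not 'nothing found'.
    """


class DegenerateSpectrumError(MurecgError):
    """Raised when band percentages are requested from a zero-power spectrum."""


class SchemaError(MurecgError):
    """Raised by file readers on malformed input; message names the offending column/line."""
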