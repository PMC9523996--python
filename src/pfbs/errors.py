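"""Exception hierarchy with stable CLI exit codes.

Exit-code contract: 0 success, 2 configuration error, 3 data error,
4 model error. Unexpected exceptions propagate (exit code 1).
"""


class PfbsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(PfbsError):
    """Invalid or contradictory configuration (bad flags, unknown keys)."""

    exit_code = 2


class DataError(PfbsError):
    """Malformed input data (missing cells, missing label column, <2 classes)."""

    exit_code = 3


class ResamplingError(DataError):
    """Bootstrap could not produce a class-covering draw within the retry budget."""


class StratificationError(DataError):
    """A class is too small for the requested number of folds."""


class ModelError(PfbsError):
    """An estimator failed to fit or evaluate."""

    exit_code = 4
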