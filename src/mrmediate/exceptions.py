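"""Exception hierarchy for mrmediate."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """A column map, threshold, or run configuration is invalid."""


class EmptyInputError(MRMediateError):
    """No valid records remain after ingestion or filtering."""


class EmptyInstrumentsError(MRMediateError):
    """Every candidate instrument was removed by a filter."""


class InsufficientInstrumentsError(MRMediateError):
    """An estimator requires more instruments than were supplied."""


class UndefinedRatioError(MRMediateError):
    """Wald ratio requested for an instrument with zero exposure effect."""


class CollinearityError(MRMediateError):
    """The multivariable exposure design matrix is rank deficient."""


class ConvergenceError(MRMediateError):
    """An iterative estimator failed to converge."""
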