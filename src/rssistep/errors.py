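"""Exception hierarchy for the rssistep package."""


class RSSIStepError(Exception):
    """Base class for all rssistep errors."""


class FormatError(RSSIStepError, ValueError):
    """An input file does not have the expected layout (e.g. missing columns)."""


class ParseError(RSSIStepError, ValueError):
    """A cell in an input file could not be parsed; the message names the row."""


class EmptyInputError(RSSIStepError, ValueError):
    """An operation received no usable samples."""


class EmptySeriesError(RSSIStepError, ValueError):
    """Converting a trace left no valid path-loss samples."""


class EmptyFilterError(RSSIStepError, ValueError):
    """Threshold filtering removed every sample."""


class DomainError(RSSIStepError, ValueError):
    """A numeric argument is outside the physical domain (e.g. distance <= 0)."""


class ConfigError(RSSIStepError, ValueError):
    """An invalid configuration value or combination."""


class InsufficientDataError(RSSIStepError, ValueError):
    """Too few data points to constrain the model being fitted."""


class FitError(RSSIStepError, RuntimeError):
    """Nonlinear fit failed to converge.

    Carries the last iterate in ``last_params`` for diagnosis.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class InvalidFitError(RSSIStepError, ValueError):
    """A downstream operation was handed an unconverged fit."""


class GridError(RSSIStepError, ValueError):
    """Every cell of a threshold grid search was empty after filtering."""
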