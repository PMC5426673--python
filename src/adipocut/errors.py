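"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`AdipocutError`,
so callers can catch one type at the CLI boundary.
"""


class AdipocutError(Exception):
    """Base class for all errors raised by adipocut."""


class ConfigurationError(AdipocutError, ValueError):
    """A synthetic-cohort configuration field is invalid; the message names it."""


class InputDataError(AdipocutError, ValueError):
    """A cohort file or record violates the schema; includes the row where known."""


class DomainError(AdipocutError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(AdipocutError, ValueError):
    """Too few observations for the requested fit or summary."""


class DegenerateDesignError(AdipocutError, ValueError):
    """Predictor has zero variance; a slope cannot be estimated."""


class PerfectFitError(AdipocutError, ValueError):
    """Residual sum of squares is (numerically) zero; SEE and AIC are undefined."""
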